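"""CpG-site extraction and the segment-vs-background methylation chi-square.

The depletion test asks whether CpG methylation sites are under-represented
in a candidate segment relative to the rest of a background region (here, the
rest of the intron).  The unit of observation is the base pair and success is
a CpG-site start, giving a 2x2 contingency table tested with Pearson's
chi-square on 1 df (Yates continuity correction off by default; both options
exposed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy import stats

from .intervals import GenomicInterval
from .io import FeatureTrack


def cpg_site_positions(seq: str) -> list[int]:
    """0-based start positions of every CG dinucleotide (overlap-free by nature)."""
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains non-ACGTN characters: {sorted(bad)}")
    out = []
    start = seq.find("CG")
    while start != -1:
        out.append(start)
        start = seq.find("CG", start + 1)
    return out


@dataclass(frozen=True)
class ContingencyTable2x2:
    """(sites, non-site bp) in segment vs background."""

    a: int  # sites in segment
    b: int  # non-site bp in segment
    c: int  # sites in background
    d: int  # non-site bp in background

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def rows(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return (self.a, self.b), (self.c, self.d)


def chi_square_2x2(table: ContingencyTable2x2, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square statistic and p-value (1 df) for a 2x2 table."""
    (a, b), (c, d) = table.rows
    if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
        raise ValueError("chi-square undefined: zero marginal")
    stat, p, dof, _ = stats.chi2_contingency(table.rows, correction=yates)
    assert dof == 1
    return float(stat), float(p)


@dataclass(frozen=True)
class DepletionReport:
    table: ContingencyTable2x2
    statistic: float
    p_value: float
    direction: str  # "depleted" | "enriched" | "equal"
    segment_rate: float
    background_rate: float

    def to_dict(self) -> dict:
        return {
            "table": {"a": self.table.a, "b": self.table.b, "c": self.table.c, "d": self.table.d},
            "statistic": self.statistic,
            "p_value": self.p_value,
            "direction": self.direction,
            "segment_rate": self.segment_rate,
            "background_rate": self.background_rate,
        }


def _count_sites_in(track: FeatureTrack, regions: Sequence[GenomicInterval]) -> int:
    return sum(
        1
        for iv in track.intervals
        if any(r.seq_id == iv.seq_id and r.start <= iv.start < r.end for r in regions)
    )


def depletion_test(
    methylation_track: FeatureTrack,
    segment: GenomicInterval,
    background: Sequence[GenomicInterval] | GenomicInterval,
    yates: bool = False,
) -> DepletionReport:
    """Chi-square test of methylation-site frequency in segment vs background.

    ``background`` must be disjoint from ``segment`` (e.g. intron minus
    segment); a site is counted where its interval starts.
    """
    if isinstance(background, GenomicInterval):
        background = [background]
    background = list(background)
    if not background or all(iv.is_empty for iv in background):
        raise ValueError("empty background")
    for iv in background:
        if iv.intersects(segment):
            raise ValueError("segment and background must be disjoint")
    a = _count_sites_in(methylation_track, [segment])
    c = _count_sites_in(methylation_track, background)
    seg_bp = segment.length
    bg_bp = sum(iv.length for iv in background)
    table = ContingencyTable2x2(a, seg_bp - a, c, bg_bp - c)
    stat, p = chi_square_2x2(table, yates=yates)
    seg_rate = a / seg_bp
    bg_rate = c / bg_bp
    if seg_rate < bg_rate:
        direction = "depleted"
    elif seg_rate > bg_rate:
        direction = "enriched"
    else:
        direction = "equal"
    return DepletionReport(table, stat, p, direction, seg_rate, bg_rate)


def subtract(region: GenomicInterval, segment: GenomicInterval) -> list[GenomicInterval]:
    """``region`` minus ``segment`` ("rest of the intron")."""
    if region.seq_id != segment.seq_id or not region.intersects(segment):
        return [region]
    out = []
    if segment.start > region.start:
        out.append(GenomicInterval(region.seq_id, region.start, segment.start, region.strand))
    if segment.end < region.end:
        out.append(GenomicInterval(region.seq_id, segment.end, region.end, region.strand))
    return out
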