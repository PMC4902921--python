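"""Sequence-based CpG island detection as a maximal-segment search.

A segment *qualifies* as CpG-island-like when it satisfies all three classic
criteria simultaneously: GC fraction > 0.5, length > 200 bp, and
observed/expected CpG ratio > 0.6, where obs/exp = (#CG dinucleotides x L) /
(#C x #G) over the segment (Gardiner-Garden/Frommer form).  Thresholds are
strict inequalities, and N bases are excluded from all counts (no CG
dinucleotide spans an N).

Detection scores the sequence one base at a time: a base is *covered* iff it
lies inside at least one qualifying segment (of any length), which equals an
exhaustive enumeration over all (start, end) pairs; the implementation does
this in O(n^2) with vectorised prefix sums.  Each reported island is a
maximal run of covered bases, and its statistics are those of the maximally
scoring segment inside it — the longest single qualifying segment (the
``core``) — so every reported statistic passes the three thresholds even
when the merged run as a whole is diluted by its flanks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .intervals import GenomicInterval
from .io import FeatureTrack


@dataclass(frozen=True)
class CpGIsland:
    """A maximal covered run with the statistics of its core segment."""

    interval: GenomicInterval      # maximal covered run
    core: GenomicInterval          # longest single qualifying segment inside
    gc_fraction: float             # of the core
    obs_exp: float                 # of the core
    n_cpg: int                     # CG dinucleotides in the full run

    def __post_init__(self) -> None:
        if not self.interval.contains(self.core):
            raise ValueError("core must lie inside the island interval")
        if not (self.gc_fraction > 0.5 and self.core.length > 200 and self.obs_exp > 0.6):
            raise ValueError(
                f"core {self.core.start}-{self.core.end} fails island criteria "
                f"(gc={self.gc_fraction:.3f}, len={self.core.length}, oe={self.obs_exp:.3f})"
            )


def _validate_seq(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains non-ACGTN characters: {sorted(bad)}")
    return seq


def gc_content(seq: str) -> float:
    """(#G + #C) / (#A + #C + #G + #T); N excluded from both counts."""
    seq = _validate_seq(seq)
    denom = sum(seq.count(b) for b in "ACGT")
    if denom == 0:
        raise ValueError("GC content undefined: no A/C/G/T bases")
    return (seq.count("G") + seq.count("C")) / denom


def obs_exp_cpg(seq: str) -> float:
    """Observed/expected CpG ratio; 0 when the segment has no C or no G."""
    seq = _validate_seq(seq)
    c, g = seq.count("C"), seq.count("G")
    if c == 0 or g == 0:
        return 0.0
    length = sum(seq.count(b) for b in "ACGT")
    return seq.count("CG") * length / (c * g)


def _prefix_counts(seq: str) -> tuple[np.ndarray, ...]:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_c = arr == ord("C")
    is_g = arr == ord("G")
    is_n = arr == ord("N")
    is_cg = np.zeros(len(seq), dtype=bool)
    if len(seq) > 1:
        is_cg[:-1] = is_c[:-1] & is_g[1:]

    def cum(x):  # cum[i] = count in seq[:i]
        out = np.zeros(len(seq) + 1, dtype=np.int64)
        np.cumsum(x, out=out[1:])
        return out

    return cum(is_c), cum(is_g), cum(~is_n), cum(is_cg)


def find_cpg_islands(
    seq: str,
    min_gc: float = 0.5,
    min_len: int = 201,
    min_oe: float = 0.6,
    seq_id: str = "seq",
    offset: int = 0,
) -> list[CpGIsland]:
    """CpG islands as maximal covered runs, sorted and non-overlapping.

    The union of the returned intervals equals the union of **all**
    qualifying (start, end) segments — the exhaustive-enumeration semantics.
    ``offset`` shifts reported coordinates (useful when ``seq`` is a slice
    of a larger contig).
    """
    seq = _validate_seq(seq)
    n = len(seq)
    if n < min_len:
        return []
    cum_c, cum_g, cum_len, cum_cg = _prefix_counts(seq)

    # For each start s, the furthest end e such that [s, e) qualifies; the
    # union of [s, max_e(s)) over all s equals the union over ALL qualifying
    # (s, e) pairs, because any qualifying [s, e) lies inside [s, max_e(s)).
    max_e = np.full(n, -1, dtype=np.int64)
    best_len = np.zeros(n, dtype=np.int64)  # longest qualifying segment per start
    ends_all = np.arange(n + 1)
    for s in range(0, n - min_len + 1):
        ends = ends_all[s + min_len:]
        c = cum_c[ends] - cum_c[s]
        g = cum_g[ends] - cum_g[s]
        eff = cum_len[ends] - cum_len[s]
        # CG dinucleotide starts strictly inside [s, e)
        cg = cum_cg[ends - 1] - cum_cg[s]
        ok = (eff > 0) & ((c + g) > min_gc * eff)
        cxg = c * g
        ok &= (cxg > 0) & (cg * eff > min_oe * cxg)
        if ok.any():
            idx = np.nonzero(ok)[0]
            max_e[s] = ends[idx[-1]]
            best_len[s] = int((ends[idx] - s).max())

    covered = np.zeros(n + 1, dtype=np.int64)
    for s in range(n):
        if max_e[s] >= 0:
            covered[s] += 1
            covered[max_e[s]] -= 1
    covered = np.cumsum(covered[:-1]) > 0
    if not covered.any():
        return []

    # maximal runs of covered bases
    edges = np.flatnonzero(np.diff(np.concatenate(([0], covered.view(np.int8), [0]))))
    islands: list[CpGIsland] = []
    for run_start, run_end in zip(edges[::2], edges[1::2]):
        run_start, run_end = int(run_start), int(run_end)
        starts = np.arange(run_start, run_end)
        starts = starts[max_e[run_start:run_end] >= 0]
        core_s = int(starts[np.argmax(best_len[starts])])
        core_e = core_s + int(best_len[core_s])
        core_seq = seq[core_s:core_e]
        islands.append(
            CpGIsland(
                interval=GenomicInterval(seq_id, run_start + offset, run_end + offset),
                core=GenomicInterval(seq_id, core_s + offset, core_e + offset),
                gc_fraction=gc_content(core_seq),
                obs_exp=obs_exp_cpg(core_seq),
                n_cpg=seq[run_start:run_end].count("CG"),
            )
        )
    return islands


def islands_to_track(islands: list[CpGIsland], source: str = "regmap-cpg") -> FeatureTrack:
    """Emit islands as a BED5-style track; score = round(1000 x obs/exp), capped."""
    return FeatureTrack(
        "cpg_island",
        [isl.interval for isl in islands],
        scores=[min(1000.0, round(1000 * isl.obs_exp)) for isl in islands],
        labels=[f"CpG_{i + 1}" for i in range(len(islands))],
        source=source,
    )
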