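"""Allele-aware miRNA seed-match scanning, site context, and site clustering.

The seed is miRNA nucleotides 2-8 (a 7-mer, configurable) and a target site
is a UTR/CDS window whose mRNA-sense sequence is the reverse complement of
the seed; "no mismatches" means perfect Watson-Crick pairing over the seed
(G:U wobble does not count as a match).  A variant inside the seed-pairing
window is *seed-disruptive* when the per-allele mismatch counts differ.

Multi-tool predictions (one row per miRNA x tool) are clustered into binding
regions by merging overlapping/nearby target intervals on the mRNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .intervals import GeneModel, GenomicInterval, RegionContext, classify_region, reverse_complement


@dataclass(frozen=True)
class SiteContext:
    """Positional/sequence context features of a target site on the mRNA."""

    dist_from_stop: int
    dist_to_utr_end: int
    au_fraction: float

    def __post_init__(self) -> None:
        if self.dist_from_stop < 0 or self.dist_to_utr_end < 0:
            raise ValueError("context distances must be >= 0")
        if not 0.0 <= self.au_fraction <= 1.0:
            raise ValueError("au_fraction must be in [0,1]")


@dataclass
class MiRNASite:
    """A predicted miRNA target site on the mRNA sense strand."""

    mirna_id: str
    target: GenomicInterval  # mRNA coordinates (seq_id e.g. "mRNA")
    seed_window: Optional[GenomicInterval] = None  # mRNA coords of seed pairing
    seed_mismatches: dict[str, int] = field(default_factory=dict)  # allele -> count
    predicting_tools: set[str] = field(default_factory=set)
    context: Optional[SiteContext] = None


def _norm_rna(seq: str, name: str) -> str:
    seq = seq.upper().replace("U", "T")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"{name}: non-ACGU/T characters {sorted(bad)}")
    return seq


def seed_of(mirna_seq: str, seed_positions: tuple[int, int] = (2, 8)) -> str:
    """Seed subsequence of a 5'->3' miRNA (1-based inclusive positions)."""
    mirna = _norm_rna(mirna_seq, "miRNA")
    lo, hi = seed_positions
    if hi > len(mirna):
        raise ValueError(f"miRNA shorter than seed span {seed_positions}")
    if not 1 <= lo <= hi:
        raise ValueError(f"bad seed positions {seed_positions}")
    return mirna[lo - 1 : hi]


def _hamming(x: str, y: str) -> int:
    return sum(1 for cx, cy in zip(x, y) if cx != cy)


def seed_match(
    mirna_seq: str,
    utr_seq: str,
    seed_positions: tuple[int, int] = (2, 8),
    max_mismatches: int = 1,
) -> list[tuple[int, int]]:
    """Scan a UTR (mRNA-sense 5'->3') for seed-complementary windows.

    Returns ``(site_start, mismatch_count)`` for every window whose Hamming
    distance to the reverse complement of the seed is <= ``max_mismatches``.
    """
    utr = _norm_rna(utr_seq, "UTR")
    motif = reverse_complement(seed_of(mirna_seq, seed_positions))
    k = len(motif)
    out = []
    for start in range(0, len(utr) - k + 1):
        mm = _hamming(utr[start : start + k], motif)
        if mm <= max_mismatches:
            out.append((start, mm))
    return out


def seed_mismatch_at(
    mirna_seq: str,
    seq: str,
    window_start: int,
    seed_positions: tuple[int, int] = (2, 8),
) -> int:
    """Seed mismatch count for a fixed window start in ``seq``."""
    motif = reverse_complement(seed_of(mirna_seq, seed_positions))
    window = _norm_rna(seq, "seq")[window_start : window_start + len(motif)]
    if len(window) < len(motif):
        raise ValueError("seed window extends past the sequence end")
    return _hamming(window, motif)


@dataclass(frozen=True)
class AlleleEffect:
    applicable: bool
    mismatches: dict[str, int]  # allele label -> seed mismatch count

    @property
    def seed_disruptive(self) -> bool:
        return self.applicable and len(set(self.mismatches.values())) > 1


def allele_effect(
    site: MiRNASite,
    mirna_seq: str,
    mrna_seq: str,
    variant_mrna_pos: int,
    alleles: Mapping[str, str],
    seed_positions: tuple[int, int] = (2, 8),
) -> AlleleEffect:
    """Per-allele seed mismatch counts for a substitution inside the seed window.

    A variant outside the site's seed-pairing window yields a not-applicable
    result with equal counts on the unmodified sequence.  Only single-base
    substitutions are supported (the alleles replace one mRNA base).
    """
    if site.seed_window is None:
        raise ValueError("site has no seed window; run the seed scan first")
    w = site.seed_window
    if not w.contains_point(variant_mrna_pos):
        base = seed_mismatch_at(mirna_seq, mrna_seq, w.start, seed_positions)
        return AlleleEffect(False, {label: base for label in alleles})
    counts = {}
    for label, allele in alleles.items():
        if len(allele) != 1 or allele not in "ACGTU":
            raise ValueError(f"allele {label}={allele!r}: only single-base substitutions supported")
        mutated = mrna_seq[:variant_mrna_pos] + allele.replace("U", "T") + mrna_seq[variant_mrna_pos + 1 :]
        counts[label] = seed_mismatch_at(mirna_seq, mutated, w.start, seed_positions)
    return AlleleEffect(True, counts)


def site_context(
    site: MiRNASite,
    gene_model: GeneModel,
    mrna_seq: str,
    au_window: int = 30,
) -> SiteContext:
    """Distances from the stop codon / 3'UTR end and AU fraction of the flank.

    ``au_fraction`` is computed over the site +/- ``au_window`` nt clipped to
    the 3'UTR (or to the mRNA when the site lies in the CDS).
    """
    stop_mrna, utr_end = gene_model.utr3_mrna()
    dist_from_stop = max(0, site.target.start - stop_mrna)
    dist_to_utr_end = max(0, utr_end - site.target.end)
    clip_lo, clip_hi = (stop_mrna, utr_end) if site.target.start >= stop_mrna else (0, len(mrna_seq))
    lo = max(clip_lo, site.target.start - au_window)
    hi = min(clip_hi, site.target.end + au_window)
    flank = mrna_seq[lo:hi]
    au = sum(1 for c in flank if c in "ATU") / len(flank) if flank else 0.0
    return SiteContext(dist_from_stop, dist_to_utr_end, au)


@dataclass
class SiteCluster:
    """A merged binding-site region with per-cluster consensus counts."""

    interval: GenomicInterval  # mRNA coordinates
    mirna_ids: set[str]
    tools: set[str]
    n_predictions: int
    context_label: RegionContext

    @property
    def n_mirnas(self) -> int:
        return len(self.mirna_ids)

    @property
    def n_tools(self) -> int:
        return len(self.tools)


def cluster_predictions(
    predictions: pd.DataFrame,
    gene_model: GeneModel,
    gap: int = 10,
    seq_id: str = "mRNA",
) -> list[SiteCluster]:
    """Merge predicted target intervals within ``gap`` nt into clusters.

    ``predictions`` carries columns (mirna_id, tool, mrna_start, mrna_end).
    Clusters are ordered 5'->3' on the mRNA and labelled with their genomic
    region context (utr3, exon, ... or boundary when spanning).
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    if len(predictions) == 0:
        return []
    rows = predictions.sort_values(["mrna_start", "mrna_end"]).reset_index(drop=True)
    clusters: list[dict] = []
    for _, row in rows.iterrows():
        start, end = int(row["mrna_start"]), int(row["mrna_end"])
        if clusters and start - clusters[-1]["end"] <= gap:
            cur = clusters[-1]
            cur["end"] = max(cur["end"], end)
            cur["mirnas"].add(str(row["mirna_id"]))
            cur["tools"].add(str(row["tool"]))
            cur["n"] += 1
        else:
            clusters.append(
                {
                    "start": start,
                    "end": end,
                    "mirnas": {str(row["mirna_id"])},
                    "tools": {str(row["tool"])},
                    "n": 1,
                }
            )
    out = []
    for c in clusters:
        pieces = gene_model.mrna_interval_to_genomic(c["start"], c["end"])
        labels = {classify_region(piece, gene_model) for piece in pieces}
        label = labels.pop() if len(labels) == 1 else RegionContext.BOUNDARY
        out.append(
            SiteCluster(
                interval=GenomicInterval(seq_id, c["start"], c["end"]),
                mirna_ids=c["mirnas"],
                tools=c["tools"],
                n_predictions=c["n"],
                context_label=label,
            )
        )
    return out


def predictions_to_genomic_track(predictions: pd.DataFrame, gene_model: GeneModel):
    """Project per-tool mRNA predictions onto the locus as a mirna_site track."""
    from .io import FeatureTrack

    intervals = []
    labels = []
    for _, row in predictions.iterrows():
        for piece in gene_model.mrna_interval_to_genomic(int(row["mrna_start"]), int(row["mrna_end"])):
            intervals.append(piece)
            labels.append(f"{row['mirna_id']}|{row['tool']}")
    return FeatureTrack("mirna_site", intervals, labels=labels, source="predictions")
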