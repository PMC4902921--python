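"""Call high-priority regulatory regions from overlaid tracks and tier variants.

A high-priority regulatory region requires (a) at least one evolutionary
constrained element and (b) at least two *distinct other* regulatory feature
types (open chromatin, TFBS, histone modification, RNA polymerase binding,
DNA methylation evidence, CpG island, miRNA site) within a window around the
element.  Multiple TFBS predictions count once: the criterion is
type-distinctness, not instance count.  Methylation participates as a feature
type through depletion-flagged segments, not raw per-CpG sites.

Variants are tiered against the map:
  tier 1 - overlaps a constrained element, or is seed-disruptive in a miRNA site
  tier 2 - inside a called high-priority region
  tier 3 - overlaps any single regulatory feature
  tier 4 - none of the above
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .intervals import GeneModel, GenomicInterval, RegionContext, classify_region, merge
from .io import FeatureTrack
from .mirna import MiRNASite
from .variants import Variant

SUPPORTING_TYPES = (
    "open_chromatin",
    "tfbs",
    "histone",
    "rnapol",
    "methylation",
    "cpg_island",
    "mirna_site",
)


@dataclass
class RegulatoryRegion:
    interval: GenomicInterval
    anchor_elements: list[GenomicInterval]
    supporting_types: set[str]
    context: list[RegionContext] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.anchor_elements:
            raise ValueError("a regulatory region needs >=1 constrained anchor")
        bad = set(self.supporting_types) - set(SUPPORTING_TYPES)
        if bad:
            raise ValueError(f"unknown supporting feature types {sorted(bad)}")
        if len(self.supporting_types) < 2:
            raise ValueError("a regulatory region needs >=2 supporting feature types")


def _types_overlapping(window: GenomicInterval, tracks: Sequence[FeatureTrack]) -> set[str]:
    found = set()
    for track in tracks:
        if track.feature_type == "constrained":
            continue
        if any(window.intersects(iv) for iv in track.intervals):
            found.add(track.feature_type)
    return found


def call_high_priority_regions(
    tracks: Sequence[FeatureTrack],
    window: int = 500,
    merge_gap: int = 200,
    gene_model: Optional[GeneModel] = None,
) -> list[RegulatoryRegion]:
    """Apply the two-criterion rule per constrained element and merge windows.

    For each constrained element the candidate window is the element padded
    by ``window`` bp on both sides; windows meeting criterion (b) are merged
    when within ``merge_gap`` bp.  Each merged region re-verifies both
    criteria on its final interval.  Output is ordered 5'->3' (ascending).
    """
    constrained = [t for t in tracks if t.feature_type == "constrained"]
    if not constrained:
        raise ValueError(
            "no constrained-element track: criterion (a) cannot be evaluated"
        )
    elements = [iv for t in constrained for iv in t.intervals]
    others = [t for t in tracks if t.feature_type != "constrained"]

    qualifying: list[tuple[GenomicInterval, GenomicInterval]] = []  # (window, element)
    for element in sorted(elements):
        cand = element.padded(window)
        types = _types_overlapping(cand, others)
        if len(types) >= 2:
            qualifying.append((cand, element))
    if not qualifying:
        return []

    merged = merge([w for w, _ in qualifying], gap=merge_gap)
    regions: list[RegulatoryRegion] = []
    for region_iv in merged:
        anchors = [e for w, e in qualifying if w.intersects(region_iv) or w.contains(region_iv)]
        support = _types_overlapping(region_iv, others)
        # re-verify both criteria on the final merged interval
        assert anchors and any(region_iv.intersects(e) for e in anchors)
        assert len(support) >= 2
        context: list[RegionContext] = []
        if gene_model is not None:
            label = classify_region(region_iv, gene_model)
            if label is RegionContext.BOUNDARY:
                seen: list[RegionContext] = []
                for cut in sorted({region_iv.start, *[p for p in gene_model._breakpoints() if region_iv.start < p < region_iv.end]}):
                    lab = gene_model.label_at(cut)
                    if lab not in seen:
                        seen.append(lab)
                context = seen
            else:
                context = [label]
        regions.append(
            RegulatoryRegion(
                interval=region_iv,
                anchor_elements=sorted(anchors),
                supporting_types=support,
                context=context,
            )
        )
    return regions


def variant_span(v: Variant) -> GenomicInterval:
    lo, hi = v.affected_span
    return GenomicInterval(v.seq_id, lo, hi)


def overlap_with_constrained(
    variants: Sequence[Variant], constrained_track: FeatureTrack
) -> list[Variant]:
    """Variants whose position (SNP) or affected span (indel) hits a constrained element."""
    out = []
    for v in variants:
        span = variant_span(v)
        if any(span.intersects(e) for e in constrained_track.intervals):
            out.append(v)
    return out


EVIDENCE_ORDER = (
    "constrained_overlap",
    "seed_disruptive",
    "in_high_priority_region",
    "single_feature_overlap",
    "none",
)


@dataclass
class PrioritisedVariant:
    variant: Variant
    tier: int
    evidence: list[str]

    def __post_init__(self) -> None:
        if self.tier not in (1, 2, 3, 4):
            raise ValueError("tier must be 1..4")
        tier1 = {"constrained_overlap", "seed_disruptive"} & set(self.evidence)
        if (self.tier == 1) != bool(tier1):
            raise ValueError("tier 1 iff constrained_overlap or seed_disruptive evidence")


def prioritise_variants(
    variants: Sequence[Variant],
    regions: Sequence[RegulatoryRegion],
    constrained_track: FeatureTrack,
    mirna_sites: Sequence[MiRNASite] = (),
    gene_model: Optional[GeneModel] = None,
    feature_tracks: Sequence[FeatureTrack] = (),
    line_names: Sequence[str] = ("F", "L"),
) -> list[PrioritisedVariant]:
    """Assign each variant exactly one tier with its evidence tags.

    Seed disruption is read from ``mirna_sites`` whose ``seed_mismatches``
    (per line allele) differ and whose seed window, mapped through the gene
    model, contains the variant.  ``feature_tracks`` feeds the tier-3
    single-feature check (constrained tracks are skipped there; they are
    tier-1 evidence).
    """
    constrained_hits = {id(v) for v in overlap_with_constrained(variants, constrained_track)}

    seed_windows_genomic: list[tuple[GenomicInterval, MiRNASite]] = []
    if gene_model is not None:
        for site in mirna_sites:
            if site.seed_window is None or len(set(site.seed_mismatches.values())) <= 1:
                continue
            for piece in gene_model.mrna_interval_to_genomic(site.seed_window.start, site.seed_window.end):
                seed_windows_genomic.append((piece, site))

    out: list[PrioritisedVariant] = []
    for v in variants:
        span = variant_span(v)
        evidence: list[str] = []
        if id(v) in constrained_hits:
            evidence.append("constrained_overlap")
        if any(span.intersects(w) for w, _ in seed_windows_genomic):
            evidence.append("seed_disruptive")
        in_region = any(span.intersects(r.interval) for r in regions)
        single = any(
            span.intersects(iv)
            for t in feature_tracks
            if t.feature_type != "constrained"
            for iv in t.intervals
        )
        if evidence:
            tier = 1
            if in_region:
                evidence.append("in_high_priority_region")
        elif in_region:
            tier = 2
            evidence.append("in_high_priority_region")
        elif single:
            tier = 3
            evidence.append("single_feature_overlap")
        else:
            tier = 4
            evidence.append("none")
        out.append(PrioritisedVariant(v, tier, evidence))
    out.sort(key=lambda pv: (pv.tier, pv.variant.position))
    return out


def classify_strain_snps(
    strain_snp_track: FeatureTrack,
    constrained_track: FeatureTrack,
    core_promoter: GenomicInterval,
) -> tuple[list[list[str]], Counter]:
    """Tag each cross-strain SNP as in_constrained / in_core_promoter / other.

    Returns per-SNP tag lists (a SNP may carry both positional tags) and the
    aggregate tag counts.
    """
    per_snp: list[list[str]] = []
    counts: Counter = Counter()
    for iv in strain_snp_track.intervals:
        tags = []
        if any(iv.intersects(e) for e in constrained_track.intervals):
            tags.append("in_constrained")
        if iv.intersects(core_promoter):
            tags.append("in_core_promoter")
        if not tags:
            tags.append("other")
        per_snp.append(tags)
        counts.update(tags)
    return per_snp, counts
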