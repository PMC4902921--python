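"""Region calling against a brute-force checker; variant tiering; SNP tags."""

from __future__ import annotations

import pytest

from regmap.intervals import GenomicInterval
from regmap.io import FeatureTrack
from regmap.integrate import (
    SUPPORTING_TYPES,
    call_high_priority_regions,
    classify_strain_snps,
    overlap_with_constrained,
    prioritise_variants,
)
from regmap.synth import generate_random_tracks
from regmap.variants import Variant


def brute_force_qualifying(tracks, window):
    """Independent checker: for each constrained element, count distinct other
    feature types with any interval within [start-window, end+window)."""
    constrained = [iv for t in tracks if t.feature_type == "constrained" for iv in t.intervals]
    out = []
    for e in constrained:
        lo, hi = e.start - window, e.end + window
        types = set()
        for t in tracks:
            if t.feature_type == "constrained":
                continue
            for iv in t.intervals:
                if iv.seq_id == e.seq_id and iv.start < hi and iv.end > lo:
                    types.add(t.feature_type)
        if len(types) >= 2:
            out.append(e)
    return out


def _fixture_evidence(paper_fixture):
    from regmap.cpg import find_cpg_islands, islands_to_track
    from regmap.mirna import predictions_to_genomic_track

    fx = paper_fixture
    tracks = [fx.tracks[k] for k in ("constrained", "open_chromatin", "tfbs", "histone", "rnapol")]
    tracks.append(islands_to_track(find_cpg_islands(fx.ref_seq, seq_id="locus")))
    tracks.append(predictions_to_genomic_track(fx.mirna_predictions, fx.gene_model))
    tracks.append(FeatureTrack("methylation", [fx.methylation_segment], source="depletion"))
    return tracks


@pytest.fixture(scope="module")
def fixture_evidence(paper_fixture):
    return _fixture_evidence(paper_fixture)


def test_fixture_yields_three_regions(paper_fixture, fixture_evidence):
    regions = call_high_priority_regions(fixture_evidence, gene_model=paper_fixture.gene_model)
    assert len(regions) == 3
    promoter, intron, utr = regions
    assert "upstream" in [c.value for c in promoter.context]
    assert [c.value for c in intron.context] == ["intron"]
    assert "utr3" in [c.value for c in utr.context]
    for r in regions:
        assert len(r.supporting_types) >= 2
        assert r.anchor_elements


def test_single_supporting_feature_is_not_enough():
    tracks = [
        FeatureTrack("constrained", [GenomicInterval("c", 1000, 1100)]),
        FeatureTrack("tfbs", [GenomicInterval("c", 1010, 1030)]),
    ]
    assert call_high_priority_regions(tracks, window=500) == []


def test_missing_constrained_track_is_an_error():
    tracks = [FeatureTrack("tfbs", [GenomicInterval("c", 0, 10)])]
    with pytest.raises(ValueError, match="criterion \\(a\\)"):
        call_high_priority_regions(tracks)


@pytest.mark.parametrize("seed", range(12))
def test_region_anchors_match_brute_force(seed):
    case = generate_random_tracks(seed, n_elements=7, window=200)
    expected = brute_force_qualifying(case.tracks, window=200)
    assert sorted(case.qualifying) == sorted(expected)  # generator truth agrees
    regions = call_high_priority_regions(case.tracks, window=200, merge_gap=100)
    got = sorted({e for r in regions for e in r.anchor_elements})
    assert got == sorted(expected)


def test_fixture_anchor_set_matches_brute_force(paper_fixture, fixture_evidence):
    regions = call_high_priority_regions(fixture_evidence, gene_model=paper_fixture.gene_model)
    got = sorted({e for r in regions for e in r.anchor_elements})
    assert got == sorted(brute_force_qualifying(fixture_evidence, window=500))


def test_qualifying_anchors_monotone_in_window(fixture_evidence):
    anchor_sets = []
    for window in (100, 300, 500, 800):
        regions = call_high_priority_regions(fixture_evidence, window=window)
        anchor_sets.append({e for r in regions for e in r.anchor_elements})
    for small, large in zip(anchor_sets, anchor_sets[1:]):
        assert small <= large


def test_region_count_monotone_in_merge_gap(fixture_evidence):
    counts = [
        len(call_high_priority_regions(fixture_evidence, merge_gap=g))
        for g in (0, 100, 200, 500, 2000)
    ]
    assert counts == sorted(counts, reverse=True)


# ---------------------------------------------------------------------------
# constrained-overlap and tiering
# ---------------------------------------------------------------------------

def test_fixture_exactly_one_variant_in_constrained(paper_fixture):
    hits = overlap_with_constrained(paper_fixture.variants, paper_fixture.tracks["constrained"])
    assert [v.id for v in hits] == ["rs251994838-like"]


def test_half_open_exclusion_one_bp_outside():
    track = FeatureTrack("constrained", [GenomicInterval("ref", 100, 200)])
    inside = Variant(199, "A", "T", {})
    outside = Variant(200, "A", "T", {})
    assert overlap_with_constrained([inside, outside], track) == [inside]


@pytest.mark.parametrize("seed", range(5))
def test_constrained_overlap_matches_position_check(seed):
    import numpy as np

    rng = np.random.default_rng(seed)
    elements = [GenomicInterval("ref", int(s), int(s) + 30) for s in rng.integers(0, 2000, 8)]
    track = FeatureTrack("constrained", sorted(elements))
    variants = [Variant(int(p), "A", "T", {}) for p in rng.integers(0, 2030, 40)]
    got = overlap_with_constrained(variants, track)
    expected = [
        v for v in variants
        if any(e.start <= v.position < e.end for e in elements)
    ]
    assert got == expected


def test_fixture_prioritisation_two_tier1(paper_fixture, fixture_evidence):
    fx = paper_fixture
    regions = call_high_priority_regions(fixture_evidence, gene_model=fx.gene_model)
    from regmap.mirna import MiRNASite

    seed_lo = fx.gene_model.genomic_to_mrna(fx.spec.seed_window_genomic[0])
    site = MiRNASite(
        "syn-miR-338-like",
        target=GenomicInterval("mRNA", seed_lo - 10, seed_lo + 22),
        seed_window=GenomicInterval("mRNA", seed_lo, seed_lo + 7),
        seed_mismatches={"L": 0, "F": 1},
    )
    tiers = prioritise_variants(
        fx.variants, regions, fx.tracks["constrained"], [site], fx.gene_model,
        feature_tracks=fixture_evidence,
    )
    assert [pv.tier for pv in tiers] == sorted(pv.tier for pv in tiers)
    tier1 = [pv for pv in tiers if pv.tier == 1]
    assert {pv.variant.id for pv in tier1} == {"rs251994838-like", "rs31534689-like"}
    evid = {pv.variant.id: pv.evidence[0] for pv in tier1}
    assert evid["rs251994838-like"] == "constrained_overlap"
    assert evid["rs31534689-like"] == "seed_disruptive"
    # exactly one tier per variant; total function
    assert len(tiers) == len(fx.variants)


def test_tier1_set_invariant_to_window(paper_fixture, fixture_evidence):
    fx = paper_fixture
    from regmap.mirna import MiRNASite

    seed_lo = fx.gene_model.genomic_to_mrna(fx.spec.seed_window_genomic[0])
    site = MiRNASite(
        "syn-miR-338-like",
        target=GenomicInterval("mRNA", seed_lo - 10, seed_lo + 22),
        seed_window=GenomicInterval("mRNA", seed_lo, seed_lo + 7),
        seed_mismatches={"L": 0, "F": 1},
    )
    tier1_sets = []
    for window in (100, 400, 700, 1000):
        regions = call_high_priority_regions(fixture_evidence, window=window)
        tiers = prioritise_variants(
            fx.variants, regions, fx.tracks["constrained"], [site], fx.gene_model,
            feature_tracks=fixture_evidence,
        )
        tier1_sets.append({pv.variant.id for pv in tiers if pv.tier == 1})
    assert all(s == tier1_sets[0] for s in tier1_sets)


def test_variant_in_region_without_tier1_evidence_is_tier2():
    regions_tracks = [
        FeatureTrack("constrained", [GenomicInterval("ref", 1000, 1100)]),
        FeatureTrack("tfbs", [GenomicInterval("ref", 950, 970)]),
        FeatureTrack("histone", [GenomicInterval("ref", 1150, 1300)]),
    ]
    regions = call_high_priority_regions(regions_tracks, window=300, merge_gap=100)
    assert len(regions) == 1
    v_in = Variant(1200, "A", "T", {})       # inside the region, no tier-1 evidence
    v_feat = Variant(2000, "A", "T", {})     # outside; overlaps nothing
    tracks_for_t3 = regions_tracks + [FeatureTrack("rnapol", [GenomicInterval("ref", 1995, 2010)])]
    tiers = prioritise_variants([v_in, v_feat], regions, regions_tracks[0],
                                feature_tracks=tracks_for_t3)
    by_pos = {pv.variant.position: pv for pv in tiers}
    assert by_pos[1200].tier == 2 and by_pos[1200].evidence == ["in_high_priority_region"]
    assert by_pos[2000].tier == 3 and by_pos[2000].evidence == ["single_feature_overlap"]


def test_empty_variant_list():
    assert prioritise_variants([], [], FeatureTrack("constrained", [])) == []


# ---------------------------------------------------------------------------
# cross-strain promoter SNPs
# ---------------------------------------------------------------------------

def test_fixture_strain_snp_tags(paper_fixture):
    gm = paper_fixture.gene_model
    per_snp, counts = classify_strain_snps(
        paper_fixture.tracks["strain_snp"], paper_fixture.tracks["constrained"], gm.core_promoter
    )
    assert len(per_snp) == 14
    assert counts["in_constrained"] == 1
    assert counts["in_core_promoter"] == 1
    assert counts["other"] == 12


def test_snps_outside_both_are_other():
    snps = FeatureTrack("strain_snp", [GenomicInterval("c", 10, 11), GenomicInterval("c", 20, 21)])
    constrained = FeatureTrack("constrained", [GenomicInterval("c", 100, 200)])
    _, counts = classify_strain_snps(snps, constrained, GenomicInterval("c", 300, 359))
    assert counts == {"other": 2}
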