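"""Seed matching vs a brute-force oracle, allele effects, context, clustering."""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Seq import Seq

from regmap.intervals import GenomicInterval
from regmap.mirna import (
    MiRNASite,
    allele_effect,
    cluster_predictions,
    seed_match,
    seed_mismatch_at,
    seed_of,
    site_context,
)


def brute_force_matches(mirna, utr, seed_positions=(2, 8), max_mm=1):
    """Oracle: Biopython reverse complement + direct per-window comparison."""
    lo, hi = seed_positions
    seed = mirna.upper().replace("U", "T")[lo - 1:hi]
    motif = str(Seq(seed).reverse_complement())
    out = []
    for s in range(len(utr) - len(motif) + 1):
        mm = sum(1 for x, y in zip(utr[s:s + len(motif)], motif) if x != y)
        if mm <= max_mm:
            out.append((s, mm))
    return out


def test_exact_seed_complement_is_found():
    mirna = "AUGGAGUACAUCAUCAUCAUCA"  # seed (2-8) = UGGAGUA -> target TACTCCA
    utr = "AAAA" + "TACTCCA" + "AAAA"
    assert seed_match(mirna, utr) == [(4, 0)]


def test_one_substitution_gives_one_mismatch():
    mirna = "AUGGAGUACAUCAUCAUCAUCA"
    utr = "AAAA" + "TACTGCA" + "AAAA"
    matches = seed_match(mirna, utr)
    assert (4, 1) in matches


def test_short_mirna_rejected():
    with pytest.raises(ValueError, match="shorter"):
        seed_match("AUGGA", "ACGTACGT")


@pytest.mark.parametrize("seed", range(25))
def test_seed_match_equals_brute_force(seed):
    rng = np.random.default_rng(seed)
    mirna = "".join("ACGU"[i] for i in rng.integers(0, 4, 22))
    utr = "".join("ACGT"[i] for i in rng.integers(0, 4, int(rng.integers(10, 51))))
    for max_mm in (0, 1, 2):
        assert seed_match(mirna, utr, max_mismatches=max_mm) == brute_force_matches(
            mirna, utr, max_mm=max_mm
        )


def test_seed_span_configurable():
    mirna = "AUGGAGUACAUCAUCAUCAUCA"
    utr = "AA" + str(Seq(mirna.replace("U", "T")[1:7]).reverse_complement()) + "AA"
    assert seed_match(mirna, utr, seed_positions=(2, 7))[0] == (2, 0)


# ---------------------------------------------------------------------------
# allele effects
# ---------------------------------------------------------------------------

def _site(seed_lo, length=22):
    return MiRNASite(
        "m1",
        target=GenomicInterval("mRNA", seed_lo - 5, seed_lo + 17),
        seed_window=GenomicInterval("mRNA", seed_lo, seed_lo + 7),
    )


def test_fixture_utr_snp_discriminates_alleles(paper_fixture):
    """The seed pairs perfectly with the lean allele, mismatching the fat one."""
    fx = paper_fixture
    gm = fx.gene_model
    mrna = gm.mrna_sequence(fx.ref_seq)
    v = next(v for v in fx.variants if v.id == "rs31534689-like")
    seed_lo = gm.genomic_to_mrna(fx.spec.seed_window_genomic[0])
    effect = allele_effect(
        _site(seed_lo), fx.mirna_seqs["syn-miR-338-like"], mrna,
        gm.genomic_to_mrna(v.position), v.line_alleles,
    )
    assert effect.applicable
    assert effect.mismatches == {"L": 0, "F": 1}
    assert effect.seed_disruptive


def test_variant_outside_seed_window_is_not_applicable(paper_fixture):
    fx = paper_fixture
    gm = fx.gene_model
    mrna = gm.mrna_sequence(fx.ref_seq)
    seed_lo = gm.genomic_to_mrna(fx.spec.seed_window_genomic[0])
    effect = allele_effect(
        _site(seed_lo), fx.mirna_seqs["syn-miR-338-like"], mrna,
        seed_lo + 100, {"F": "A", "L": "C"},
    )
    assert not effect.applicable
    assert len(set(effect.mismatches.values())) == 1


def test_every_substitution_at_seed_base_breaks_pairing():
    mirna = "AUGGAGUACAUCAUCAUCAUCA"
    mrna = "A" * 10 + "TACTCCA" + "A" * 10
    site = _site(10)
    ref_base = mrna[13]
    for alt in set("ACGT") - {ref_base}:
        effect = allele_effect(site, mirna, mrna, 13, {"ref": ref_base, "alt": alt})
        assert effect.mismatches == {"ref": 0, "alt": 1}


def test_allele_effect_consistent_with_rescanning():
    """Substituting the allele and re-running the scan gives the same count."""
    mirna = "AUGGAGUACAUCAUCAUCAUCA"
    mrna = "A" * 10 + "TACTCCA" + "A" * 10
    site = _site(10)
    effect = allele_effect(site, mirna, mrna, 12, {"x": "G"})
    mutated = mrna[:12] + "G" + mrna[13:]
    assert effect.mismatches["x"] == seed_mismatch_at(mirna, mutated, 10)


# ---------------------------------------------------------------------------
# site context
# ---------------------------------------------------------------------------

def test_site_context_distances(paper_fixture):
    gm = paper_fixture.gene_model
    mrna = gm.mrna_sequence(paper_fixture.ref_seq)
    stop, utr_end = gm.utr3_mrna()
    site = MiRNASite("m", GenomicInterval("mRNA", stop + 15, stop + 37))
    ctx = site_context(site, gm, mrna)
    assert ctx.dist_from_stop == 15
    site_end = MiRNASite("m", GenomicInterval("mRNA", utr_end - 22, utr_end))
    assert site_context(site_end, gm, mrna).dist_to_utr_end == 0


def test_all_au_flank_has_fraction_one(paper_fixture):
    gm = paper_fixture.gene_model
    stop, _ = gm.utr3_mrna()
    mrna = "G" * stop + "AT" * ((gm.mrna_length - stop) // 2)
    site = MiRNASite("m", GenomicInterval("mRNA", stop + 20, stop + 42))
    assert site_context(site, gm, mrna).au_fraction == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def test_fixture_clusters_4_utr3_and_1_cds(paper_fixture):
    clusters = cluster_predictions(paper_fixture.mirna_predictions, paper_fixture.gene_model)
    labels = [c.context_label.value for c in clusters]
    assert labels.count("utr3") == 4
    assert labels.count("exon") == 1
    # ordered 5'->3'
    starts = [c.interval.start for c in clusters]
    assert starts == sorted(starts)


def test_cluster_counts_insensitive_to_gap_range(paper_fixture):
    for gap in (0, 10, 25):
        clusters = cluster_predictions(paper_fixture.mirna_predictions, paper_fixture.gene_model, gap=gap)
        assert len(clusters) == 5


def test_cluster_count_monotone_in_gap(paper_fixture):
    counts = [
        len(cluster_predictions(paper_fixture.mirna_predictions, paper_fixture.gene_model, gap=g))
        for g in (0, 50, 200, 1000)
    ]
    assert counts == sorted(counts, reverse=True)


def test_empty_predictions_give_no_clusters(paper_fixture):
    import pandas as pd

    empty = pd.DataFrame(columns=["mirna_id", "tool", "mrna_start", "mrna_end"])
    assert cluster_predictions(empty, paper_fixture.gene_model) == []


def test_seed_of_positions():
    assert seed_of("AUGGAGUACAUCAUCAUCAUCA") == "TGGAGTA"
    with pytest.raises(ValueError):
        seed_of("AUG", (2, 8))
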