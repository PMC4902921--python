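"""Global alignment, variant calling, and the planted-variant oracle."""

from __future__ import annotations

import numpy as np
import pytest

from regmap.synth import generate_random_case
from regmap.variants import (
    GENOME_WIDE_BP_PER_VARIANT,
    AlignmentResult,
    Variant,
    align_pair,
    call_line_variants,
    call_variants,
    left_align_indel,
    polya_scan,
    variant_density,
)


def exhaustive_best_score(a: str, b: str, match=1, mismatch=-1, gap=-2) -> int:
    """Enumerate every global alignment recursively (lengths <= ~8)."""

    def rec(i: int, j: int) -> int:
        if i == len(a) and j == len(b):
            return 0
        best = -(10**9)
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            best = max(best, s + rec(i + 1, j + 1))
        if i < len(a):
            best = max(best, gap + rec(i + 1, j))
        if j < len(b):
            best = max(best, gap + rec(i, j + 1))
        return best

    return rec(0, 0)


def test_identical_sequences_full_score_no_gaps():
    aln = align_pair("ACGTACGT", "ACGTACGT")
    assert aln.score == 8
    assert "-" not in aln.aligned_a + aln.aligned_b


def test_single_mismatch_score():
    assert align_pair("ACGT", "AGGT").score == 2  # 3 matches - 1 mismatch


def test_single_deletion_alignment():
    aln = align_pair("ACGT", "ACT")
    assert aln.score == 3 - 2  # 3 matches - 1 gap
    gap_cols = [i for i, c in enumerate(aln.aligned_b) if c == "-"]
    assert len(gap_cols) == 1 and "-" not in aln.aligned_a


def test_alignment_degapping_recovers_inputs():
    a, b = "ACGTTGCA", "AGTTGGCA"
    aln = align_pair(a, b)
    assert aln.seq_a == a and aln.seq_b == b


def test_non_iupac_rejected():
    with pytest.raises(ValueError, match="IUPAC"):
        align_pair("ACXT", "ACGT")


@pytest.mark.parametrize("seed", range(20))
def test_alignment_score_matches_exhaustive_enumeration(seed):
    rng = np.random.default_rng(seed)
    a = "".join("ACGT"[i] for i in rng.integers(0, 4, int(rng.integers(1, 9))))
    b = "".join("ACGT"[i] for i in rng.integers(0, 4, int(rng.integers(1, 9))))
    assert align_pair(a, b).score == exhaustive_best_score(a, b)


def test_call_variants_identical_is_empty():
    assert call_variants(align_pair("ACGTACGT", "ACGTACGT")) == []


def test_snp_calling_is_symmetric():
    a, b = "AACGTACGTTT", "AACTTACGTTT"
    fwd = call_variants(align_pair(a, b), names=("x", "y"))
    rev = call_variants(align_pair(b, a), names=("y", "x"))
    assert len(fwd) == len(rev) == 1
    assert fwd[0].position == rev[0].position
    assert fwd[0].ref_allele == rev[0].alt_allele
    assert fwd[0].line_alleles == rev[0].line_alleles


def test_left_alignment_of_homopolymer_deletion():
    # deleting one A from CAAT is reported at the left-most position
    pos, ref, alt = left_align_indel(1, "AA", "A", "CAAT")
    assert (pos, ref, alt) == (0, "CA", "C")


def test_ref_offset_shifts_positions():
    aln = align_pair("AACGT", "AACTT")
    v, = call_variants(aln, ref_offset=100)
    assert v.position == 103


@pytest.mark.parametrize("seed", range(8))
def test_planted_variants_recovered_exactly(seed):
    case = generate_random_case(seed, n_variants=1 + seed % 10, length=700)
    aln = align_pair(case.ref, case.alt)
    called = call_variants(aln, names=("a", "b"))
    got = [(v.position, v.ref_allele, v.alt_allele, v.vtype) for v in called]
    want = [(v.position, v.ref_allele, v.alt_allele, v.vtype) for v in case.variants]
    assert got == want


def test_call_line_variants_merges_alleles(paper_fixture):
    called = call_line_variants(
        paper_fixture.ref_seq, paper_fixture.line_seqs, seq_id="locus"
    )
    assert len(called) == 5
    for v, truth in zip(called, paper_fixture.variants):
        assert (v.position, v.ref_allele, v.alt_allele) == (
            truth.position, truth.ref_allele, truth.alt_allele
        )
        assert v.line_alleles == truth.line_alleles
    types = sorted(v.vtype for v in called)
    assert types == ["deletion", "insertion", "snp", "snp", "snp"]


def test_variant_dataclass_validation():
    with pytest.raises(ValueError):
        Variant(0, "AT", "G", {})  # indel without a shared anchor
    assert Variant(0, "AT", "A", {}).vtype == "deletion"
    assert Variant(0, "A", "ATG", {}).vtype == "insertion"


def test_variant_density():
    assert variant_density(10, 1000) == pytest.approx(100)
    assert variant_density(1, 39) == pytest.approx(39)
    assert variant_density(7, 700) == pytest.approx(100)
    with pytest.raises(ValueError, match="no variants"):
        variant_density(0, 1000)
    assert GENOME_WIDE_BP_PER_VARIANT == pytest.approx(39.4)


@pytest.mark.parametrize(
    "seq,expected",
    [("AATAAA", [0]), ("CCCCCC", []), ("AATAATAAA", [3]), ("AATAAATAAA", [0, 4])],
)
def test_polya_scan(seq, expected):
    assert polya_scan(seq) == expected


def test_polya_hexamer_in_fixture_utr(paper_fixture):
    gm = paper_fixture.gene_model
    utr = paper_fixture.ref_seq[gm.utr3.start:gm.utr3.end]
    hit = paper_fixture.spec.polya[0] - gm.utr3.start
    assert hit in polya_scan(utr)


def test_alignment_result_rejects_double_gap_column():
    with pytest.raises(ValueError):
        AlignmentResult("A-C", "A-C", 0)
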