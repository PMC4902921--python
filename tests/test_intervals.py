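"""Coordinate arithmetic, normalisation, merging, and region classification."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from regmap.intervals import (
    GeneModel,
    GenomicInterval,
    RegionContext,
    classify_region,
    interval_length,
    merge,
    overlap,
)

# Printed browser-style coordinate pairs and the segment lengths they imply
# (half-open differences); the descending pair is a minus-strand convention.
PRINTED_PAIRS = [
    ("15:78399000 - 78406400", 7400),
    ("Chr 15: 78399030 - 78409992".replace("Chr ", ""), 10962),
    ("Chr15: 78405859 - 78409992", 4133),
    ("Chr15: 78399556 - 78399030", 526),
]


@pytest.mark.parametrize("printed,length", PRINTED_PAIRS)
def test_printed_pair_lengths(printed, length):
    iv = GenomicInterval.from_printed(printed)
    assert interval_length(iv) == length


def test_descending_pair_sets_minus_strand():
    iv = GenomicInterval.from_printed("Chr15: 78399556 - 78399030")
    assert (iv.start, iv.end, iv.strand) == (78399030, 78399556, "-")


def test_empty_interval_has_zero_length():
    assert interval_length(GenomicInterval("x", 5, 5)) == 0


def test_invalid_interval_rejected():
    with pytest.raises(ValueError):
        GenomicInterval("x", 10, 5)


@given(st.integers(0, 10**6), st.integers(1, 10**4))
def test_normalisation_round_trip(start, length):
    """Printing a minus-strand interval descending and re-reading reproduces it."""
    iv = GenomicInterval("15", start, start + length, "-")
    assert GenomicInterval.from_printed(iv.printed()) == iv


# ---------------------------------------------------------------------------
# overlap / merge
# ---------------------------------------------------------------------------

def test_overlap_half_open_adjacency_is_empty():
    assert overlap(GenomicInterval("c", 0, 10), GenomicInterval("c", 10, 20)) is None


def test_overlap_basic_and_commutative():
    a, b = GenomicInterval("c", 0, 10), GenomicInterval("c", 5, 20)
    got = overlap(a, b)
    assert (got.start, got.end) == (5, 10)
    assert overlap(b, a).start == got.start and overlap(b, a).end == got.end


def test_overlap_different_seq_is_none():
    assert overlap(GenomicInterval("c1", 0, 10), GenomicInterval("c2", 0, 10)) is None


@given(st.integers(0, 60), st.integers(0, 60), st.integers(0, 60), st.integers(0, 60))
def test_overlap_agrees_with_position_sets(a0, al, b0, bl):
    a = GenomicInterval("c", a0, a0 + al)
    b = GenomicInterval("c", b0, b0 + bl)
    expected = set(range(a.start, a.end)) & set(range(b.start, b.end))
    got = overlap(a, b)
    assert (set(range(got.start, got.end)) if got else set()) == expected


def test_merge_examples():
    ivs = [GenomicInterval("c", 0, 5), GenomicInterval("c", 4, 9)]
    assert [(m.start, m.end) for m in merge(ivs, 0)] == [(0, 9)]
    ivs = [GenomicInterval("c", 0, 5), GenomicInterval("c", 7, 9)]
    assert [(m.start, m.end) for m in merge(ivs, 2)] == [(0, 9)]
    assert merge([], 0) == []
    with pytest.raises(ValueError):
        merge(ivs, -1)


@settings(max_examples=200)
@given(
    st.lists(st.tuples(st.integers(0, 200), st.integers(0, 40)), max_size=12),
    st.integers(0, 10),
)
def test_merge_properties(pairs, gap):
    ivs = [GenomicInterval("c", s, s + l) for s, l in pairs]
    merged = merge(ivs, gap)
    # sorted, pairwise separated by > gap
    for prev, cur in zip(merged, merged[1:]):
        assert cur.start - prev.end > gap
    # idempotent
    assert merge(merged, gap) == merged
    # covered length bounded by input length sum (gap 0)
    if gap == 0:
        assert sum(m.length for m in merged) <= sum(iv.length for iv in ivs)
        covered = set()
        for iv in ivs:
            covered |= set(range(iv.start, iv.end))
        assert sum(m.length for m in merged) == len(covered)


# ---------------------------------------------------------------------------
# gene model / region classification
# ---------------------------------------------------------------------------

def _toy_gene(strand: str = "+") -> GeneModel:
    return GeneModel(
        gene_interval=GenomicInterval("c", 100, 500, strand),
        exons=(GenomicInterval("c", 100, 200, strand), GenomicInterval("c", 300, 500, strand)),
        intron=GenomicInterval("c", 200, 300, strand),
        utr5=GenomicInterval("c", 100, 120, strand) if strand == "+" else GenomicInterval("c", 480, 500, strand),
        utr3=GenomicInterval("c", 400, 500, strand) if strand == "+" else GenomicInterval("c", 100, 140, strand),
        tss=100 if strand == "+" else 499,
        stop_codon=400 if strand == "+" else 140,
    )


def test_classify_intron_and_boundary():
    gm = _toy_gene()
    assert classify_region(GenomicInterval("c", 210, 290), gm) is RegionContext.INTRON
    straddle = GenomicInterval("c", 190, 210)  # exon1/intron junction
    assert classify_region(straddle, gm) is RegionContext.BOUNDARY


def test_classify_is_strand_aware():
    plus, minus = _toy_gene("+"), _toy_gene("-")
    left = GenomicInterval("c", 0, 50)
    right = GenomicInterval("c", 600, 650)
    assert classify_region(left, plus) is RegionContext.UPSTREAM
    assert classify_region(right, plus) is RegionContext.DOWNSTREAM
    assert classify_region(left, minus) is RegionContext.DOWNSTREAM
    assert classify_region(right, minus) is RegionContext.UPSTREAM


def test_fixture_constrained_elements_context_split(paper_fixture):
    """2 exon-covering, 8 intronic, 1 upstream, 1 boundary-spanning."""
    gm = paper_fixture.gene_model
    labels = [classify_region(e, gm) for e in paper_fixture.tracks["constrained"].intervals]
    counts = {lab: labels.count(lab) for lab in set(labels)}
    assert counts == {
        RegionContext.EXON: 2,
        RegionContext.INTRON: 8,
        RegionContext.UPSTREAM: 1,
        RegionContext.BOUNDARY: 1,
    }


@settings(max_examples=300, deadline=None)
@given(st.integers(0, 700), st.integers(1, 120), st.sampled_from(["+", "-"]))
def test_classify_agrees_with_per_base_labels(start, length, strand):
    """Interval label == unique per-base label, else boundary."""
    gm = _toy_gene(strand)
    iv = GenomicInterval("c", start, start + length)
    base_labels = {gm.label_at(p) for p in range(iv.start, iv.end)}
    got = classify_region(iv, gm)
    if len(base_labels) == 1:
        assert got is base_labels.pop()
    else:
        assert got is RegionContext.BOUNDARY


def test_mrna_mapping_round_trip_both_strands():
    for strand in "+-":
        gm = _toy_gene(strand)
        n = gm.mrna_length
        assert n == 300
        for pos in range(n):
            assert gm.genomic_to_mrna(gm.mrna_to_genomic(pos)) == pos


def test_mrna_sequence_minus_strand_is_reverse_complement():
    gm = _toy_gene("-")
    genome = "A" * 100 + "C" * 100 + "G" * 100 + "T" * 200 + "A" * 300
    mrna = gm.mrna_sequence(genome)
    # 5'-most exon on minus strand is the right-hand exon [300, 500): T*200 -> A*200
    assert mrna == "A" * 200 + "G" * 100
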