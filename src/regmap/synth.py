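"""Deterministic synthetic-locus fixture generator and randomised test cases.

The paper-style fixture is a fully synthetic 11 kb surrogate locus (it is not
a real genome slice): a plus-strand two-exon gene with annotation tracks laid
out to reproduce the printed topology of the study locus — 12 constrained
elements (2 exon-covering, 8 intronic, 1 upstream, 1 exon/intron boundary),
two open-chromatin sites, promoter TFBS/histone/RNA-polymerase clusters, a
methylation-depleted intronic segment, two detectable CpG islands, five
planted F/L variants (3 SNPs + 2 indels; the L haplotype is identical to the
reference), a 14-SNP cross-strain promoter set, a 59 bp core promoter
overlapping the TSS, miRNA predictions clustering into 4 3'UTR + 1 CDS
binding regions with one seed perfectly complementary to the L allele, and a
17-strain allele table in which the Lean haplotype matches 13 classical
strains exactly while the Fat haplotype matches only WSB/EiJ.

Sequence composition is engineered for the detectors, not for base-level
realism: background is CpG-free AT-rich DNA (GC ~ 0.30) with CpG
dinucleotides planted at controlled densities, and each CpG island is
flanked by pure-AT spacers so island coverage cannot leak across.  Every
paper-derived count is re-checked by independent code at generation time
before anything is written; generation is byte-reproducible from its seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import cpg as _cpg
from . import integrate as _integrate
from . import methylation as _meth
from . import mirna as _mirna
from . import strains as _strains
from . import variants as _variants
from .intervals import GeneModel, GenomicInterval, RegionContext, classify_region
from .io import (
    FeatureTrack,
    StrainAlleleTable,
    write_bed,
    write_fasta,
    write_gene_model,
    write_gene_model_gff3,
    write_methylation,
    write_mirna_predictions,
    write_strain_table,
    write_variants,
)

DEFAULT_SEED = 161
LOCUS = "locus"


class FixtureError(AssertionError):
    """The generated bundle failed a self-consistency check."""


@dataclass(frozen=True)
class FixtureSpec:
    """Placement constants of the paper-style fixture (all 0-based half-open)."""

    seed: int = DEFAULT_SEED
    locus_length: int = 11_000
    # gene model
    gene: tuple[int, int] = (5000, 10_400)
    exon1: tuple[int, int] = (5000, 5400)
    intron: tuple[int, int] = (5400, 8400)
    exon2: tuple[int, int] = (8400, 10_400)
    utr5: tuple[int, int] = (5000, 5100)
    utr3: tuple[int, int] = (9400, 10_400)
    core_promoter: tuple[int, int] = (4971, 5030)  # 59 bp overlapping the TSS
    polya: tuple[int, int] = (10_300, 10_306)
    flank: int = 500
    # constrained elements: 1 upstream, 2 exon-covering, 8 intronic, 1 boundary
    constrained: tuple[tuple[int, int], ...] = (
        (4600, 4700),   # upstream
        (5110, 5340),   # exon 1 CDS
        (5350, 5450),   # exon1/intron boundary
        (5900, 5960),
        (6150, 6210),
        (6900, 6990),   # hosts the intronic tier-1 SNP
        (7050, 7110),
        (7200, 7260),
        (7700, 7760),
        (7950, 8010),
        (8150, 8210),
        (8500, 9380),   # exon 2 CDS
    )
    open_chromatin: tuple[tuple[int, int], ...] = ((4700, 5300), (6850, 7150))
    tfbs: tuple[tuple[int, int, str], ...] = (
        (4810, 4825, "SP1"),
        (4880, 4895, "NF1"),
        (5050, 5065, "CEBPA"),
        (5150, 5165, "ZFX"),
        (6950, 6965, "ESRRB"),
    )
    histone: tuple[tuple[int, int, str], ...] = (
        (4750, 5350, "H3K4me3"),
        (4820, 5250, "H3K4me2"),
        (6800, 7200, "H3K4me1"),
        (8500, 9300, "H3K36me3"),
    )
    rnapol: tuple[tuple[int, int, str], ...] = ((4850, 5150, "Pol2"),)
    # CpG islands and the pure-AT spacers that stop island coverage leaking
    islands: tuple[tuple[int, int], ...] = ((4300, 4600), (5150, 5450))
    at_spacers: tuple[tuple[int, int], ...] = ((4050, 4300), (4600, 5150), (5450, 5700))
    island_gc: float = 0.85
    background_gc: float = 0.30
    # methylation-depleted candidate segment (the intronic regulatory core)
    methylation_segment: tuple[int, int] = (6800, 7200)
    n_sites_depleted: int = 2
    intron_site_spacing: int = 24  # rest-of-intron planted CpG spacing (bp)
    other_site_spacing: int = 60   # promoter/exon2 planted CpG spacing (bp)
    # F/L variants (L == reference); positions are 0-based anchors
    snp_constrained: int = 6930    # inside constrained element (6900, 6990)
    snp_intron: int = 7500
    snp_utr3: int = 9445           # inside the seed-pairing window below
    insertion_anchor: int = 6100   # F carries a dinucleotide insertion
    deletion_pos: int = 6600       # F lacks this reference base
    # miRNA seed design (mRNA coordinates; seed = miRNA positions 2-8)
    seed_window_genomic: tuple[int, int] = (9440, 9447)
    seed_target_ref: str = "TACTCCA"  # reverse complement of the seed
    # cross-strain promoter SNPs: 1 in a constrained element, 1 in the core
    # promoter, 12 elsewhere in the promoter/exon1 zone
    strain_snp_constrained: int = 4650
    strain_snp_core_promoter: int = 4990
    strain_snps_other: tuple[int, ...] = (
        4520, 4560, 4730, 4770, 4820, 4870, 4920, 4950, 5040, 5060, 5080, 5100,
    )
    # strain panel
    classical_strains: tuple[str, ...] = (
        "C57BL/6J", "129S1/SvImJ", "A/J", "AKR/J", "BALB/cJ", "C3H/HeJ",
        "CBA/J", "DBA/2J", "FVB/NJ", "LP/J", "NOD/ShiLtJ", "NZO/HlLtJ",
        "BTBR/J",
    )
    wild_strains: tuple[str, ...] = ("WSB/EiJ", "CAST/EiJ", "PWK/PhJ", "SPRET/EiJ")
    # which variant (index) each near-match wild strain shares with L instead of F
    wild_near_misses: tuple[tuple[str, int], ...] = (
        ("CAST/EiJ", 1), ("PWK/PhJ", 2), ("SPRET/EiJ", 3),
    )


@dataclass
class PaperFixture:
    spec: FixtureSpec
    ref_seq: str
    line_seqs: dict[str, str]            # {"F": ..., "L": ...}
    gene_model: GeneModel
    tracks: dict[str, FeatureTrack]      # keyed by feature type
    methylation_segment: GenomicInterval
    variants: list[_variants.Variant]    # planted truth (on reference coords)
    mirna_predictions: pd.DataFrame
    mirna_seqs: dict[str, str]
    strain_table: StrainAlleleTable
    strain_classes: dict[str, str]
    manifest: dict


# ---------------------------------------------------------------------------
# sequence construction
# ---------------------------------------------------------------------------

def _sample_cpg_free(rng: np.random.Generator, n: int, gc: float) -> list[str]:
    """Random DNA with target GC and no CG dinucleotide."""
    bases = "ACGT"
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    p_after_c = np.array([(1 - gc) / 2, gc / 2, 0.0, (1 - gc) / 2])
    p_after_c = p_after_c / p_after_c.sum()
    out: list[str] = []
    prev = ""
    for _ in range(n):
        probs = p_after_c if prev == "C" else p
        base = bases[int(rng.choice(4, p=probs))]
        out.append(base)
        prev = base
    return out


def _build_reference(spec: FixtureSpec, rng: np.random.Generator) -> tuple[str, list[int]]:
    """Reference sequence plus the planted background CpG-site positions."""
    seq = _sample_cpg_free(rng, spec.locus_length, spec.background_gc)

    for lo, hi in spec.at_spacers:
        for i in range(lo, hi):
            seq[i] = "AT"[int(rng.integers(2))]

    for lo, hi in spec.islands:
        gc = spec.island_gc
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        for i in range(lo, hi):
            seq[i] = "ACGT"[int(rng.choice(4, p=p))]

    # the designated seed-pairing target on the reference (= L allele)
    lo, hi = spec.seed_window_genomic
    for i, base in zip(range(lo, hi), spec.seed_target_ref):
        seq[i] = base
    # poly(A) consensus hexamer in the 3'UTR
    for i, base in zip(range(*spec.polya), "AATAAA"):
        seq[i] = base

    # non-repetitive contexts around the planted indels so that calling and
    # left-alignment recover them at exactly the planted coordinates
    ins = spec.insertion_anchor
    seq[ins], seq[ins + 1] = "A", "C"
    dele = spec.deletion_pos
    seq[dele - 1], seq[dele], seq[dele + 1] = "A", "T", "C"
    seq[spec.snp_constrained] = "A"
    seq[spec.snp_intron], seq[spec.snp_intron + 1] = "A", "T"

    # planted CpG sites at controlled densities (background is CpG-free)
    reserved: list[tuple[int, int]] = [
        spec.seed_window_genomic,
        spec.polya,
        (ins - 2, ins + 4),
        (dele - 2, dele + 3),
        (spec.snp_constrained - 2, spec.snp_constrained + 3),
        (spec.snp_intron - 2, spec.snp_intron + 3),
        (spec.snp_utr3 - 2, spec.snp_utr3 + 3),
        *spec.islands,
        *spec.at_spacers,
    ]

    def free(pos: int) -> bool:
        return not any(lo <= pos < hi or lo <= pos + 1 < hi for lo, hi in reserved)

    seg_lo, seg_hi = spec.methylation_segment
    sites: list[int] = []

    def plant(lo: int, hi: int, spacing: int) -> None:
        pos = lo + int(rng.integers(spacing))
        while pos < hi - 1:
            if free(pos):
                seq[pos], seq[pos + 1] = "C", "G"
                sites.append(pos)
            pos += spacing + int(rng.integers(max(1, spacing // 3)))

    # rest of the intron: dense; depleted segment: exactly n_sites_depleted
    plant(spec.intron[0], seg_lo, spec.intron_site_spacing)
    plant(seg_hi, spec.intron[1], spec.intron_site_spacing)
    depleted_positions = np.linspace(seg_lo + 40, seg_hi - 40, spec.n_sites_depleted)
    for pos in depleted_positions.astype(int):
        if not free(pos):  # pragma: no cover - placement constants avoid this
            raise FixtureError(f"depleted-segment CpG at {pos} collides with a reserved zone")
        seq[pos], seq[pos + 1] = "C", "G"
        sites.append(int(pos))
    # upstream of the promoter islands and across exon 2: moderate density
    plant(spec.at_spacers[0][0] - 300, spec.at_spacers[0][0], spec.other_site_spacing)
    plant(spec.exon2[0], spec.polya[0] - 10, spec.other_site_spacing)

    return "".join(seq), sorted(sites)


def _apply_variants(ref: str, spec: FixtureSpec) -> tuple[str, list[_variants.Variant]]:
    """The F haplotype and the planted truth set (ascending positions)."""
    ins, dele = spec.insertion_anchor, spec.deletion_pos
    snps = [
        (spec.snp_constrained, "T", "rs251994838-like"),
        (spec.snp_intron, "C", "fl-3"),
        (spec.snp_utr3, "A", "rs31534689-like"),
    ]
    truth = [
        _variants.Variant(ins, ref[ins], ref[ins] + "TG", {"F": ref[ins] + "TG", "L": ref[ins]},
                          id="fl-1", seq_id=LOCUS),
        _variants.Variant(dele - 1, ref[dele - 1] + ref[dele], ref[dele - 1],
                          {"F": ref[dele - 1], "L": ref[dele - 1] + ref[dele]},
                          id="fl-2", seq_id=LOCUS),
    ]
    for pos, alt, vid in snps:
        truth.append(
            _variants.Variant(pos, ref[pos], alt, {"F": alt, "L": ref[pos]}, id=vid, seq_id=LOCUS)
        )
    truth.sort(key=lambda v: v.position)

    f = list(ref)
    f[spec.snp_constrained] = "T"
    f[spec.snp_intron] = "C"
    f[spec.snp_utr3] = "A"
    # apply indels right-to-left so earlier coordinates stay valid
    del f[dele]
    f[ins + 1:ins + 1] = list("TG")
    # note: deletion at 6600 > insertion at 6100, so apply deletion first
    return "".join(f), truth


# ---------------------------------------------------------------------------
# tracks and tables
# ---------------------------------------------------------------------------

def _iv(lo: int, hi: int) -> GenomicInterval:
    return GenomicInterval(LOCUS, lo, hi)


def _build_gene_model(spec: FixtureSpec) -> GeneModel:
    return GeneModel(
        gene_interval=GenomicInterval(LOCUS, *spec.gene, "+"),
        exons=(GenomicInterval(LOCUS, *spec.exon1, "+"), GenomicInterval(LOCUS, *spec.exon2, "+")),
        intron=GenomicInterval(LOCUS, *spec.intron, "+"),
        utr5=GenomicInterval(LOCUS, *spec.utr5, "+"),
        utr3=GenomicInterval(LOCUS, *spec.utr3, "+"),
        tss=spec.gene[0],
        stop_codon=spec.utr3[0],
        polya_signal=GenomicInterval(LOCUS, *spec.polya, "+"),
        core_promoter=GenomicInterval(LOCUS, *spec.core_promoter, "+"),
        upstream_flank=spec.flank,
        downstream_flank=spec.flank,
    )


def _build_tracks(spec: FixtureSpec, ref: str, site_positions: list[int],
                  rng: np.random.Generator) -> dict[str, FeatureTrack]:
    tracks = {
        "constrained": FeatureTrack(
            "constrained",
            [_iv(*c) for c in spec.constrained],
            labels=[f"ce{i + 1}" for i in range(len(spec.constrained))],
            source="synthetic",
        ),
        "open_chromatin": FeatureTrack(
            "open_chromatin",
            [_iv(*c) for c in spec.open_chromatin],
            labels=["DNase_promoter", "DNase_intron"],
            source="synthetic",
        ),
        "tfbs": FeatureTrack(
            "tfbs", [_iv(a, b) for a, b, _ in spec.tfbs],
            labels=[name for *_, name in spec.tfbs], source="synthetic",
        ),
        "histone": FeatureTrack(
            "histone", [_iv(a, b) for a, b, _ in spec.histone],
            labels=[name for *_, name in spec.histone], source="synthetic",
        ),
        "rnapol": FeatureTrack(
            "rnapol", [_iv(a, b) for a, b, _ in spec.rnapol],
            labels=[name for *_, name in spec.rnapol], source="synthetic",
        ),
        "strain_snp": FeatureTrack(
            "strain_snp",
            [_iv(p, p + 1) for p in sorted(
                (spec.strain_snp_constrained, spec.strain_snp_core_promoter, *spec.strain_snps_other)
            )],
            source="synthetic",
        ),
    }
    # methylation: one row per CpG site; islands unmethylated, elsewhere high
    island_sites = [
        lo + p
        for lo, hi in spec.islands
        for p in _meth.cpg_site_positions(ref[lo:hi])
    ]
    intervals, scores = [], []
    for pos in sorted(set(site_positions) | set(island_sites)):
        intervals.append(_iv(pos, pos + 2))
        if any(lo <= pos < hi for lo, hi in spec.islands):
            scores.append(float(rng.uniform(0.0, 0.05)))
        else:
            scores.append(float(rng.uniform(0.6, 1.0)))
    tracks["methylation"] = FeatureTrack("methylation", intervals, scores, source="synthetic")
    return tracks


_TOOLS = ("toolA", "toolB", "toolC", "toolD")


def _build_mirna(spec: FixtureSpec, gm: GeneModel, ref: str,
                 rng: np.random.Generator) -> tuple[pd.DataFrame, dict[str, str]]:
    """Per-tool prediction rows whose sites cluster into 1 CDS + 4 3'UTR regions."""
    seed_lo = gm.genomic_to_mrna(spec.seed_window_genomic[0])
    # clusters as (mrna_start, mrna_end, [mirna ids]); sites within a cluster
    # overlap each other so cluster counts are stable for merge gaps in [0, 25]
    clusters = [
        (1200, 1228, ["syn-miR-104", "syn-miR-105"]),                 # exon-2 CDS
        (seed_lo - 10, seed_lo + 22, ["syn-miR-338-like", "syn-miR-101"]),  # 3'UTR
        (1600, 1640, ["syn-miR-102", "syn-miR-106"]),
        (1900, 1930, ["syn-miR-103"]),
        (2330, 2362, ["syn-miR-107", "syn-miR-108"]),
    ]
    rows = []
    for lo, hi, mirnas in clusters:
        for m, mirna in enumerate(mirnas):
            for t, tool in enumerate(_TOOLS[: 2 + (m + lo) % 3]):
                jitter_lo = lo + (t + m) % 3
                jitter_hi = hi - (t + 2 * m) % 3
                rows.append({"mirna_id": mirna, "tool": tool,
                             "mrna_start": jitter_lo, "mrna_end": jitter_hi})
    df = pd.DataFrame(rows, columns=["mirna_id", "tool", "mrna_start", "mrna_end"])

    seqs: dict[str, str] = {}
    for _, _, mirnas in clusters:
        for mirna in mirnas:
            if mirna not in seqs:
                tail = "".join("ACGT"[int(b)] for b in rng.integers(0, 4, 14))
                seqs[mirna] = "A" + "".join(
                    "ACGT"[int(b)] for b in rng.integers(0, 4, 7)) + tail
    # the discriminating miRNA: seed (positions 2-8) reverse-complementary to
    # the reference (L) allele window
    seed = _mirna.seed_of("N" + _variants_revcomp(spec.seed_target_ref) + "N" * 14, (2, 8))
    tail = "".join("ACGT"[int(b)] for b in rng.integers(0, 4, 14))
    seqs["syn-miR-338-like"] = "A" + seed + tail
    return df, seqs


def _variants_revcomp(seq: str) -> str:
    from .intervals import reverse_complement

    return reverse_complement(seq)


def _build_strain_table(spec: FixtureSpec, truth: list[_variants.Variant]) -> tuple[StrainAlleleTable, dict[str, str]]:
    ref_alleles = [v.ref_allele for v in truth]   # = L haplotype
    alt_alleles = [v.alt_allele for v in truth]   # = F haplotype
    strains = [*spec.classical_strains, *spec.wild_strains]
    near = dict(spec.wild_near_misses)
    columns: dict[str, list[str]] = {}
    for strain in spec.classical_strains:
        columns[strain] = list(ref_alleles)
    for strain in spec.wild_strains:
        col = list(alt_alleles)
        if strain in near:
            col[near[strain]] = ref_alleles[near[strain]]
        columns[strain] = col
    table = StrainAlleleTable(
        variant_ids=[v.id or f"var{i}" for i, v in enumerate(truth)],
        positions=[v.position for v in truth],
        strains=strains,
        alleles=[[columns[s][i] for s in strains] for i in range(len(truth))],
        line_alleles={"F": list(alt_alleles), "L": list(ref_alleles)},
    )
    classes = {s: "classical" for s in spec.classical_strains}
    classes.update({s: "wild-derived" for s in spec.wild_strains})
    return table, classes


# ---------------------------------------------------------------------------
# assembly + self-check
# ---------------------------------------------------------------------------

def build_fixture(seed: int = DEFAULT_SEED, spec: Optional[FixtureSpec] = None) -> PaperFixture:
    """Build the complete paper-style bundle in memory and self-check it."""
    spec = spec or FixtureSpec(seed=seed)
    rng = np.random.default_rng(spec.seed)
    ref, site_positions = _build_reference(spec, rng)
    f_seq, truth = _apply_variants(ref, spec)
    gm = _build_gene_model(spec)
    tracks = _build_tracks(spec, ref, site_positions, rng)
    predictions, mirna_seqs = _build_mirna(spec, gm, ref, rng)
    table, classes = _build_strain_table(spec, truth)

    fixture = PaperFixture(
        spec=spec,
        ref_seq=ref,
        line_seqs={"F": f_seq, "L": ref},
        gene_model=gm,
        tracks=tracks,
        methylation_segment=_iv(*spec.methylation_segment),
        variants=truth,
        mirna_predictions=predictions,
        mirna_seqs=mirna_seqs,
        strain_table=table,
        strain_classes=classes,
        manifest={},
    )
    fixture.manifest = _self_check(fixture)
    return fixture


def _self_check(fx: PaperFixture) -> dict:
    """Re-derive every paper-topology count with the analysis modules."""
    spec, gm = fx.spec, fx.gene_model

    def check(cond: bool, msg: str) -> None:
        if not cond:
            raise FixtureError(msg)

    # constrained element census and context split
    elements = fx.tracks["constrained"].intervals
    check(len(elements) == 12, "expected 12 constrained elements")
    contexts = [classify_region(e, gm).value for e in elements]
    from collections import Counter

    ctx_counts = Counter(contexts)
    check(ctx_counts["exon"] == 2 and ctx_counts["intron"] == 8
          and ctx_counts["upstream"] == 1 and ctx_counts["boundary"] == 1,
          f"constrained context split wrong: {dict(ctx_counts)}")
    check(len(fx.tracks["open_chromatin"]) == 2, "expected 2 open chromatin sites")

    # CpG islands: exactly two, in the promoter/exon-1 zone
    islands = _cpg.find_cpg_islands(fx.ref_seq, seq_id=LOCUS)
    check(len(islands) == 2, f"expected 2 CpG islands, found {len(islands)}")
    promoter_zone = _iv(spec.islands[0][0] - 300, spec.islands[1][1] + 300)
    check(all(i.interval.intersects(promoter_zone) for i in islands),
          "islands outside the promoter/exon1 zone")

    # variant calling recovers the planted truth exactly
    called = _variants.call_line_variants(fx.ref_seq, fx.line_seqs, seq_id=LOCUS)
    called_fl = [v for v in called if v.line_alleles["F"] != v.line_alleles["L"]]
    check(len(called_fl) == 5, f"expected 5 F/L variants, called {len(called_fl)}")
    got = [(v.position, v.ref_allele, v.alt_allele, v.vtype) for v in called_fl]
    want = [(v.position, v.ref_allele, v.alt_allele, v.vtype) for v in fx.variants]
    check(got == want, f"called variants {got} != planted {want}")
    check(Counter(v.vtype for v in called_fl) == Counter({"snp": 3, "insertion": 1, "deletion": 1}),
          "expected 3 SNPs + 2 indels")

    # methylation depletion in the intronic segment
    rest = _meth.subtract(gm.intron, fx.methylation_segment)
    rep = _meth.depletion_test(fx.tracks["methylation"], fx.methylation_segment, rest)
    check(rep.direction == "depleted" and rep.p_value < 0.01,
          f"depletion test: {rep.direction}, p={rep.p_value:.3g}")

    # region calling: promoter/exon1 + intron + 3'UTR
    evidence = [fx.tracks[k] for k in ("constrained", "open_chromatin", "tfbs", "histone", "rnapol")]
    evidence.append(_cpg.islands_to_track(islands))
    evidence.append(_mirna.predictions_to_genomic_track(fx.mirna_predictions, gm))
    evidence.append(FeatureTrack("methylation", [fx.methylation_segment], source="depletion"))
    regions = _integrate.call_high_priority_regions(evidence, gene_model=gm)
    check(len(regions) == 3, f"expected 3 high-priority regions, got {len(regions)}")

    # miRNA clustering: 1 CDS + 4 3'UTR clusters; seed discrimination L=0 / F=1
    clusters = _mirna.cluster_predictions(fx.mirna_predictions, gm)
    labels = Counter(c.context_label.value for c in clusters)
    check(labels == Counter({"utr3": 4, "exon": 1}),
          f"cluster context split wrong: {dict(labels)}")
    mrna = gm.mrna_sequence(fx.ref_seq)
    seed_lo = gm.genomic_to_mrna(spec.seed_window_genomic[0])
    v_utr = next(v for v in fx.variants if v.position == spec.snp_utr3)
    site = _mirna.MiRNASite(
        "syn-miR-338-like",
        target=GenomicInterval("mRNA", seed_lo - 10, seed_lo + 22),
        seed_window=GenomicInterval("mRNA", seed_lo, seed_lo + 7),
    )
    effect = _mirna.allele_effect(
        site, fx.mirna_seqs["syn-miR-338-like"], mrna,
        gm.genomic_to_mrna(v_utr.position), v_utr.line_alleles,
    )
    check(effect.applicable and effect.mismatches == {"F": 1, "L": 0},
          f"allele effect wrong: {effect.mismatches}")

    # variant prioritisation: exactly the two designed tier-1 variants
    site.seed_mismatches = effect.mismatches
    tiers = _integrate.prioritise_variants(
        called_fl, regions, fx.tracks["constrained"], [site], gm,
        feature_tracks=evidence,
    )
    tier1 = [pv for pv in tiers if pv.tier == 1]
    check(len(tier1) == 2, f"expected 2 tier-1 variants, got {len(tier1)}")
    tags = sorted(t for pv in tier1 for t in pv.evidence
                  if t in ("constrained_overlap", "seed_disruptive"))
    check(tags == ["constrained_overlap", "seed_disruptive"],
          f"tier-1 evidence split wrong: {tags}")

    # promoter-region cross-strain SNPs: 14 total, 1 constrained, 1 core promoter
    per_snp, counts = _integrate.classify_strain_snps(
        fx.tracks["strain_snp"], fx.tracks["constrained"], gm.core_promoter,
    )
    check(len(per_snp) == 14, f"expected 14 strain SNPs, got {len(per_snp)}")
    check(counts["in_constrained"] == 1 and counts["in_core_promoter"] == 1
          and counts["other"] == 12, f"strain SNP split wrong: {dict(counts)}")

    # strain haplotype concordance
    rep_l = _strains.concordance(fx.strain_table, "L")
    rep_f = _strains.concordance(fx.strain_table, "F")
    check(len(rep_l.exact_match_strains) == 13, "Lean should match 13 strains exactly")
    check(rep_f.exact_match_strains == ["WSB/EiJ"], "Fat should match only WSB/EiJ")
    check(rep_f.strains_sharing(4) == sorted(s for s, _ in spec.wild_near_misses),
          "Fat 4-of-5 strains wrong")
    check(_strains.origin_call(rep_f, fx.strain_classes) == "wild-derived", "Fat origin")
    check(_strains.origin_call(rep_l, fx.strain_classes) == "classical", "Lean origin")

    # poly(A) hexamer present in the 3'UTR
    utr3 = fx.ref_seq[gm.utr3.start:gm.utr3.end]
    check(spec.polya[0] - gm.utr3.start in _variants.polya_scan(utr3), "poly(A) hexamer missing")

    return {
        "seed": spec.seed,
        "locus": LOCUS,
        "locus_length": spec.locus_length,
        "display_map": {
            "note": "synthetic surrogate locus; for display the paper-style descending "
                    "chromosome coordinate is chr15_like = 78410992 - x",
            "offset": 78_410_992,
        },
        "counts": {
            "constrained_elements": len(elements),
            "constrained_context": dict(ctx_counts),
            "open_chromatin_sites": len(fx.tracks["open_chromatin"]),
            "cpg_islands": len(islands),
            "fl_variants": len(called_fl),
            "fl_variant_types": dict(Counter(v.vtype for v in called_fl)),
            "high_priority_regions": len(regions),
            "mirna_clusters_utr3": labels["utr3"],
            "mirna_clusters_cds": labels["exon"],
            "strain_snps": len(per_snp),
            "strain_snps_in_constrained": counts["in_constrained"],
            "strain_snps_in_core_promoter": counts["in_core_promoter"],
            "lean_exact_match_strains": len(rep_l.exact_match_strains),
            "fat_exact_match_strains": len(rep_f.exact_match_strains),
            "tier1_variants": len(tier1),
        },
        "planted_variants": [
            {"position": v.position, "id": v.id, "ref": v.ref_allele,
             "alt": v.alt_allele, "type": v.vtype} for v in fx.variants
        ],
        "methylation_test": rep.to_dict(),
        "regions": [[r.interval.start, r.interval.end] for r in regions],
        "qualifying_elements": sorted(
            [e.start, e.end] for r in regions for e in r.anchor_elements
        ),
    }


# ---------------------------------------------------------------------------
# on-disk bundle
# ---------------------------------------------------------------------------

FIXTURE_README = """\
Synthetic surrogate locus bundle (generated by regmap.synth)
===========================================================

This bundle is fully synthetic: an 11 kb plus-strand contig named "locus"
with a two-exon gene, laid out to reproduce the *topology* of the study
locus (element counts, overlaps and the variant/strain design), not its
sequence.  Coordinates are locus-relative 0-based half-open; manifest.json
carries an affine map for paper-style descending display coordinates.

Design notes
------------
* The L (lean) haplotype is identical to the reference; F (fat) differs by
  3 SNPs and 2 indels.  (The source study is internally inconsistent about
  line-vs-reference counts; the bundle follows the line-vs-line figure.)
* Variant surrogates carry "-like" identifiers; they are not dbSNP records.
* Strain names are real inbred strain names but the alleles are synthetic.
"""


def generate_paper_fixture(out_dir, seed: int = DEFAULT_SEED) -> PaperFixture:
    """Write the validated fixture bundle to ``out_dir``; returns the bundle.

    The same seed always produces a byte-identical bundle; every
    paper-topology count is re-derived by the analysis modules before
    anything is written (a failure raises :class:`FixtureError`).
    """
    fx = build_fixture(seed=seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    write_fasta({"ref": fx.ref_seq, **fx.line_seqs}, out / "sequences.fa")
    write_fasta(fx.mirna_seqs, out / "mirna.fa")
    for key in ("constrained", "open_chromatin", "tfbs", "histone", "rnapol", "strain_snp"):
        write_bed(fx.tracks[key], out / f"{key}.bed")
    write_methylation(fx.tracks["methylation"], out / "methylation.bedgraph")
    write_mirna_predictions(fx.mirna_predictions, out / "mirna_predictions.tsv")
    write_strain_table(fx.strain_table, out / "strain_table.tsv")
    write_variants(fx.variants, out / "variants.tsv", line_names=("F", "L"))
    write_gene_model(fx.gene_model, out / "gene_model.yaml")
    write_gene_model_gff3(fx.gene_model, out / "gene_model.gff3")

    config = {
        "locus": LOCUS,
        "sequences": "sequences.fa",
        "reference_name": "ref",
        "line_names": ["F", "L"],
        "gene_model": "gene_model.yaml",
        "tracks": {
            key: f"{key}.bed"
            for key in ("constrained", "open_chromatin", "tfbs", "histone", "rnapol", "strain_snp")
        },
        "methylation": "methylation.bedgraph",
        "mirna_predictions": "mirna_predictions.tsv",
        "mirna_sequences": "mirna.fa",
        "strain_table": "strain_table.tsv",
        "strain_classes": {k: v for k, v in fx.strain_classes.items()},
        "parameters": {
            "region_window": 500,
            "region_merge_gap": 200,
            "cluster_gap": 10,
            "seed_positions": [2, 8],
            "seed_max_mismatches": 1,
            "methylation_segment": list(fx.spec.methylation_segment),
            "methylation_alpha": 0.01,
            "yates": False,
        },
        "seed": fx.spec.seed,
    }
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(fx.manifest, fh, indent=1, sort_keys=True)
    (out / "README.md").write_text(FIXTURE_README)
    return fx


# ---------------------------------------------------------------------------
# randomised cases for property tests
# ---------------------------------------------------------------------------

@dataclass
class RandomVariantCase:
    ref: str
    alt: str
    variants: list[_variants.Variant]  # planted truth, ascending


def generate_random_case(seed: int, n_variants: int, length: int = 600) -> RandomVariantCase:
    """Random reference + mutated haplotype with exactly-recoverable truth.

    Planted variants are >= 30 bp apart and >= 25 bp from either end, with
    locally non-repetitive indel contexts so left-alignment is the identity.
    """
    rng = np.random.default_rng(seed)
    if n_variants < 0:
        raise ValueError("n_variants must be >= 0")
    n_slots = (length - 50) // 50
    if n_variants > n_slots:
        raise ValueError(f"length {length} too short for {n_variants} variants")
    ref = list("ACGT"[int(b)] for b in rng.integers(0, 4, length))
    if n_variants == 0:
        positions = []
    else:
        slots = np.sort(rng.choice(n_slots, size=n_variants, replace=False))
        positions = sorted(25 + slots * 50 + rng.integers(0, 20, n_variants))
    truth: list[_variants.Variant] = []
    for pos in positions:
        pos = int(pos)
        kind = ("snp", "insertion", "deletion")[int(rng.integers(3))]
        if kind == "snp":
            ref_base = ref[pos]
            alt = "ACGT"[("ACGT".index(ref_base) + 1 + int(rng.integers(3))) % 4]
            truth.append(_variants.Variant(pos, ref_base, alt, {"a": ref_base, "b": alt}))
        elif kind == "insertion":
            ref[pos], ref[pos + 1] = "A", "C"
            ins = "".join("GT"[int(b)] for b in rng.integers(0, 2, int(rng.integers(1, 4))))
            ins = "T" + ins[1:-1] + "G" if len(ins) > 1 else "T"
            truth.append(_variants.Variant(pos, ref[pos], ref[pos] + ins,
                                           {"a": ref[pos], "b": ref[pos] + ins}))
        else:
            k = int(rng.integers(1, 4))
            ref[pos - 1] = "A"
            for i in range(k):
                ref[pos + i] = "TCG"[i % 3]
            ref[pos + k] = "A" if ref[pos + k - 1] != "A" else "C"
            ref_allele = ref[pos - 1] + "".join(ref[pos:pos + k])
            truth.append(_variants.Variant(pos - 1, ref_allele, ref[pos - 1],
                                           {"a": ref_allele, "b": ref[pos - 1]}))
    # build alt from truth, right-to-left
    alt_seq = list(ref)
    for v in reversed(truth):
        if v.vtype == "snp":
            alt_seq[v.position] = v.alt_allele
        elif v.vtype == "insertion":
            ins = v.alt_allele[1:]
            alt_seq[v.position + 1:v.position + 1] = list(ins)
        else:
            k = len(v.ref_allele) - 1
            del alt_seq[v.position + 1:v.position + 1 + k]
    return RandomVariantCase("".join(ref), "".join(alt_seq), truth)


@dataclass
class RandomTrackCase:
    tracks: list[FeatureTrack]
    qualifying: list[GenomicInterval]  # ground-truth elements meeting criterion (b)


def generate_random_tracks(
    seed: int,
    n_elements: int = 6,
    window: int = 200,
    seq_id: str = "chrT",
) -> RandomTrackCase:
    """Constrained elements with a designed number of supporting feature types.

    Elements are spaced far enough apart (> 2*window + feature size) that
    support cannot leak between candidate windows, so the ground truth is
    exact by construction.
    """
    rng = np.random.default_rng(seed)
    from .integrate import SUPPORTING_TYPES

    spacing = 2 * window + 300
    elements, qualifying = [], []
    by_type: dict[str, list[GenomicInterval]] = {t: [] for t in SUPPORTING_TYPES}
    for i in range(n_elements):
        start = 1000 + i * spacing + int(rng.integers(0, 50))
        element = GenomicInterval(seq_id, start, start + int(rng.integers(30, 120)))
        elements.append(element)
        k = int(rng.integers(0, 4))
        types = list(rng.choice(len(SUPPORTING_TYPES), size=k, replace=False))
        for t in types:
            ftype = SUPPORTING_TYPES[int(t)]
            flo = element.start - window + int(rng.integers(0, window))
            by_type[ftype].append(GenomicInterval(seq_id, max(0, flo), max(0, flo) + 40))
        if k >= 2:
            qualifying.append(element)
    tracks = [FeatureTrack("constrained", elements, source="random")]
    for ftype, ivs in by_type.items():
        if ivs:
            tracks.append(FeatureTrack(ftype, sorted(ivs), source="random"))
    return RandomTrackCase(tracks, qualifying)
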