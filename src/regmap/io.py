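"""Readers and writers for every on-disk representation the pipeline touches.

Canonical formats: FASTA for sequences, BED3/4/5 (0-based half-open) for
feature tracks, bedGraph-like rows for per-CpG methylation, a VCF-style TSV
(1-based POS, anchored indels) for variants, a variants x strains TSV for the
strain allele table, and YAML for the gene model / pipeline config.

Readers reject malformed rows rather than silently repairing them; every
error message carries the file name and line number.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GeneModel, GenomicInterval

PathLike = Union[str, Path]

FEATURE_TYPES = (
    "constrained",
    "open_chromatin",
    "tfbs",
    "histone",
    "rnapol",
    "methylation",
    "cpg_island",
    "mirna_site",
    "strain_snp",
)


class TrackIOError(ValueError):
    """Malformed input file; message carries file and line number."""


@dataclass
class FeatureTrack:
    """A typed set of intervals with optional per-interval score and label."""

    feature_type: str
    intervals: list[GenomicInterval]
    scores: Optional[list[float]] = None
    labels: Optional[list[str]] = None
    source: str = ""

    def __post_init__(self) -> None:
        if self.feature_type not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.feature_type!r}")
        for parallel, name in ((self.scores, "scores"), (self.labels, "labels")):
            if parallel is not None and len(parallel) != len(self.intervals):
                raise ValueError(f"{name} not parallel to intervals")
        if self.feature_type == "methylation" and self.scores is not None:
            bad = [s for s in self.scores if not 0.0 <= s <= 1.0]
            if bad:
                raise ValueError(f"methylation scores outside [0,1]: {bad[:3]}")

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def sorted(self) -> "FeatureTrack":
        order = sorted(range(len(self.intervals)), key=lambda i: self.intervals[i])
        return FeatureTrack(
            self.feature_type,
            [self.intervals[i] for i in order],
            [self.scores[i] for i in order] if self.scores is not None else None,
            [self.labels[i] for i in order] if self.labels is not None else None,
            self.source,
        )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: PathLike) -> dict[str, str]:
    """Read a FASTA file to ``{name: uppercase sequence}``, order preserved."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise TrackIOError(f"{path}: duplicate FASTA record name {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise TrackIOError(f"{path}: no FASTA records found")
    return records


def write_fasta(sequences: Mapping[str, str], path: PathLike, width: int = 70) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# BED / bedGraph
# ---------------------------------------------------------------------------

def _bed_rows(path: PathLike):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def read_bed(
    path: PathLike,
    feature_type: str,
    allow_descending: bool = False,
    source: Optional[str] = None,
) -> FeatureTrack:
    """Read BED3/4/5 into a :class:`FeatureTrack`.

    In the default strict dialect ``start > end`` is an error; with
    ``allow_descending=True`` a descending pair is normalised to ascending
    with strand set to ``-`` (the printed minus-strand convention).
    """
    intervals: list[GenomicInterval] = []
    labels: list[str] = []
    scores: list[float] = []
    any_label = any_score = False
    for lineno, cols in _bed_rows(path):
        if len(cols) < 3:
            raise TrackIOError(f"{path}:{lineno}: expected >=3 BED columns, got {len(cols)}")
        try:
            start, end = int(cols[1]), int(cols[2])
        except ValueError as exc:
            raise TrackIOError(f"{path}:{lineno}: non-integer coordinates") from exc
        if start > end:
            if not allow_descending:
                raise TrackIOError(f"{path}:{lineno}: start > end ({start} > {end})")
            iv = GenomicInterval.from_pair(cols[0], start, end)
        else:
            iv = GenomicInterval(cols[0], start, end)
        intervals.append(iv)
        if len(cols) >= 4:
            labels.append(cols[3])
            any_label = True
        else:
            labels.append("")
        if len(cols) >= 5:
            try:
                scores.append(float(cols[4]))
            except ValueError as exc:
                raise TrackIOError(f"{path}:{lineno}: non-numeric score {cols[4]!r}") from exc
            any_score = True
        else:
            scores.append(0.0)
    if any_label and all(lab in ("", ".") for lab in labels):
        any_label = False  # placeholder names only (BED5 written without labels)
    return FeatureTrack(
        feature_type,
        intervals,
        scores if any_score else None,
        labels if any_label else None,
        source=source or str(path),
    )


def write_bed(track: FeatureTrack, path: PathLike) -> None:
    """Write BED3/4/5 depending on which parallel fields are present."""
    with open(path, "w") as fh:
        for i, iv in enumerate(track.intervals):
            cols = [iv.seq_id, str(iv.start), str(iv.end)]
            if track.labels is not None or track.scores is not None:
                cols.append(track.labels[i] if track.labels is not None else ".")
            if track.scores is not None:
                score = track.scores[i]
                cols.append(f"{score:g}")
            fh.write("\t".join(cols) + "\n")


def read_methylation(path: PathLike, source: Optional[str] = None) -> FeatureTrack:
    """Read a bedGraph-like per-CpG methylation track.

    The value column may be a fraction in [0,1] or a percent in [0,100]
    (auto-detected: any value > 1 means percent); stored as fractions.
    """
    intervals: list[GenomicInterval] = []
    values: list[float] = []
    for lineno, cols in _bed_rows(path):
        if len(cols) < 4:
            raise TrackIOError(f"{path}:{lineno}: bedGraph needs 4 columns")
        try:
            start, end, value = int(cols[1]), int(cols[2]), float(cols[3])
        except ValueError as exc:
            raise TrackIOError(f"{path}:{lineno}: malformed bedGraph row") from exc
        if start > end:
            raise TrackIOError(f"{path}:{lineno}: start > end")
        if not 0.0 <= value <= 100.0:
            raise TrackIOError(f"{path}:{lineno}: methylation value {value} outside [0,100]")
        intervals.append(GenomicInterval(cols[0], start, end))
        values.append(value)
    if any(v > 1.0 for v in values):
        values = [v / 100.0 for v in values]
    return FeatureTrack("methylation", intervals, values, source=source or str(path))


def write_methylation(track: FeatureTrack, path: PathLike, percent: bool = True) -> None:
    with open(path, "w") as fh:
        for iv, score in zip(track.intervals, track.scores or []):
            value = score * 100.0 if percent else score
            fh.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{value:g}\n")


# ---------------------------------------------------------------------------
# Variant TSV (VCF-style 1-based anchored representation)
# ---------------------------------------------------------------------------

VARIANT_COLUMNS = ("CHROM", "POS", "ID", "REF", "ALT", "TYPE")


def write_variants(variants: Sequence, path: PathLike, line_names: Sequence[str] = ("F", "L")) -> None:
    """Write variants as a VCF-like TSV with per-line allele columns.

    POS is 1-based (internal coordinates are 0-based half-open).
    """
    with open(path, "w") as fh:
        fh.write("\t".join([*VARIANT_COLUMNS, *line_names]) + "\n")
        for v in variants:
            row = [
                v.seq_id,
                str(v.position + 1),
                v.id or ".",
                v.ref_allele,
                v.alt_allele,
                v.vtype,
                *[v.line_alleles.get(name, ".") for name in line_names],
            ]
            fh.write("\t".join(row) + "\n")


def read_variants(path: PathLike):
    """Read a variant TSV written by :func:`write_variants`; round-trip identity."""
    from .variants import Variant  # local import to avoid a cycle

    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[: len(VARIANT_COLUMNS)] != list(VARIANT_COLUMNS):
            raise TrackIOError(f"{path}:1: unexpected variant header {header[:6]}")
        line_names = header[len(VARIANT_COLUMNS):]
        for lineno, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            cols = raw.rstrip("\n").split("\t")
            if len(cols) != len(header):
                raise TrackIOError(f"{path}:{lineno}: expected {len(header)} columns")
            try:
                pos = int(cols[1]) - 1
            except ValueError as exc:
                raise TrackIOError(f"{path}:{lineno}: non-integer POS") from exc
            v = Variant(
                seq_id=cols[0],
                position=pos,
                id=None if cols[2] == "." else cols[2],
                ref_allele=cols[3],
                alt_allele=cols[4],
                line_alleles={n: a for n, a in zip(line_names, cols[6:])},
            )
            if v.vtype != cols[5]:
                raise TrackIOError(
                    f"{path}:{lineno}: declared type {cols[5]!r} != derived {v.vtype!r}"
                )
            out.append(v)
    return out


# ---------------------------------------------------------------------------
# Strain allele table
# ---------------------------------------------------------------------------

@dataclass
class StrainAlleleTable:
    """Allele matrix: rows = variants, columns = strains, plus the two lines."""

    variant_ids: list[str]
    positions: list[int]  # 0-based reference positions
    strains: list[str]
    alleles: list[list[str]]  # rows parallel to variant_ids
    line_alleles: dict[str, list[str]]  # line name -> alleles parallel to variant_ids

    def __post_init__(self) -> None:
        n = len(self.variant_ids)
        if len(self.positions) != n:
            raise ValueError("positions not parallel to variant_ids")
        for row, vid in zip(self.alleles, self.variant_ids):
            if len(row) != len(self.strains):
                raise ValueError(f"ragged allele row for {vid}")
        for line, alleles in self.line_alleles.items():
            if len(alleles) != n:
                raise ValueError(f"line {line}: expected {n} alleles")

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def allele(self, variant_id: str, strain: str) -> str:
        i = self.variant_ids.index(variant_id)
        j = self.strains.index(strain)
        return self.alleles[i][j]


def read_strain_table(path: PathLike, line_names: Sequence[str] = ("F", "L")) -> StrainAlleleTable:
    """Read the variants x strains TSV (columns: variant_id, pos, strains..., lines)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"variant_id", "pos", *line_names}
    missing = required - set(df.columns)
    if missing:
        raise TrackIOError(f"{path}: missing columns {sorted(missing)}")
    strain_cols = [c for c in df.columns if c not in {"variant_id", "pos", *line_names}]
    for col in [*strain_cols, *line_names]:
        empty = df.index[df[col].str.strip() == ""].tolist()
        if empty:
            vid = df.loc[empty[0], "variant_id"]
            raise TrackIOError(f"{path}: missing allele for variant {vid!r} x {col!r}")
    try:
        positions = [int(p) - 1 for p in df["pos"]]
    except ValueError as exc:
        raise TrackIOError(f"{path}: non-integer pos column") from exc
    return StrainAlleleTable(
        variant_ids=df["variant_id"].tolist(),
        positions=positions,
        strains=strain_cols,
        alleles=df[strain_cols].values.tolist(),
        line_alleles={name: df[name].tolist() for name in line_names},
    )


def write_strain_table(table: StrainAlleleTable, path: PathLike) -> None:
    df = pd.DataFrame(table.alleles, columns=table.strains)
    df.insert(0, "variant_id", table.variant_ids)
    df.insert(1, "pos", [p + 1 for p in table.positions])
    for line, alleles in table.line_alleles.items():
        df[line] = alleles
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# miRNA predictions
# ---------------------------------------------------------------------------

MIRNA_COLUMNS = ("mirna_id", "tool", "mrna_start", "mrna_end")


def read_mirna_predictions(path: PathLike) -> pd.DataFrame:
    """Read the per-tool miRNA target prediction TSV (mRNA coordinates).

    The ``tool`` column lets multi-tool consensus be computed per cluster.
    """
    df = pd.read_csv(path, sep="\t", dtype={"mirna_id": str, "tool": str})
    missing = set(MIRNA_COLUMNS) - set(df.columns)
    if missing:
        raise TrackIOError(f"{path}: missing columns {sorted(missing)}")
    bad = df.index[df["mrna_end"] <= df["mrna_start"]].tolist()
    if bad:
        raise TrackIOError(f"{path}: empty/descending site at data row {bad[0] + 1}")
    return df


def write_mirna_predictions(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene model (flat YAML config block or minimal GFF3)
# ---------------------------------------------------------------------------

def gene_model_to_dict(gm: GeneModel) -> dict:
    def pair(iv: GenomicInterval) -> list[int]:
        return [iv.start, iv.end]

    d = {
        "seq_id": gm.seq_id,
        "strand": gm.strand,
        "gene": pair(gm.gene_interval),
        "exons": [pair(e) for e in gm.exons],
        "intron": pair(gm.intron),
        "utr5": pair(gm.utr5),
        "utr3": pair(gm.utr3),
        "tss": gm.tss,
        "stop_codon": gm.stop_codon,
        "upstream_flank": gm.upstream_flank,
        "downstream_flank": gm.downstream_flank,
    }
    if gm.polya_signal is not None:
        d["polya_signal"] = pair(gm.polya_signal)
    if gm.core_promoter is not None:
        d["core_promoter"] = pair(gm.core_promoter)
    return d


def gene_model_from_dict(d: Mapping) -> GeneModel:
    seq_id = d["seq_id"]
    strand = d.get("strand", "+")

    def iv(pair) -> GenomicInterval:
        return GenomicInterval(seq_id, int(pair[0]), int(pair[1]), strand)

    return GeneModel(
        gene_interval=iv(d["gene"]),
        exons=tuple(iv(p) for p in d["exons"]),  # type: ignore[arg-type]
        intron=iv(d["intron"]),
        utr5=iv(d["utr5"]),
        utr3=iv(d["utr3"]),
        tss=int(d["tss"]),
        stop_codon=int(d["stop_codon"]),
        polya_signal=iv(d["polya_signal"]) if "polya_signal" in d else None,
        core_promoter=iv(d["core_promoter"]) if "core_promoter" in d else None,
        upstream_flank=int(d.get("upstream_flank", 500)),
        downstream_flank=int(d.get("downstream_flank", 500)),
    )


def read_gene_model(path: PathLike) -> GeneModel:
    """Read a gene model from a flat YAML config block or a minimal GFF3 file."""
    path = Path(path)
    if path.suffix.lower() in {".gff", ".gff3"}:
        return _read_gene_model_gff3(path)
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return gene_model_from_dict(d)


def write_gene_model(gm: GeneModel, path: PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(gene_model_to_dict(gm), fh, sort_keys=False)


def _read_gene_model_gff3(path: Path) -> GeneModel:
    """Minimal GFF3 reader (1-based inclusive -> half-open conversion).

    Recognised feature types: gene, exon, five_prime_UTR, three_prime_UTR,
    core_promoter (non-standard but convenient), polyA_signal_sequence.
    """
    feats: dict[str, list[GenomicInterval]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip() or raw.startswith("#"):
                continue
            cols = raw.rstrip("\n").split("\t")
            if len(cols) < 8:
                raise TrackIOError(f"{path}:{lineno}: expected >=8 GFF3 columns")
            seq_id, _, ftype, start, end, _, strand = cols[:7]
            try:
                iv = GenomicInterval(seq_id, int(start) - 1, int(end), strand if strand in "+-" else ".")
            except ValueError as exc:
                raise TrackIOError(f"{path}:{lineno}: bad coordinates") from exc
            feats.setdefault(ftype, []).append(iv)
    for needed in ("gene", "exon", "five_prime_UTR", "three_prime_UTR"):
        if needed not in feats:
            raise TrackIOError(f"{path}: missing {needed} feature")
    if len(feats["exon"]) != 2:
        raise TrackIOError(f"{path}: expected exactly 2 exons, got {len(feats['exon'])}")
    gene = feats["gene"][0]
    e1, e2 = sorted(feats["exon"], key=lambda e: e.start)
    strand = gene.strand if gene.strand in "+-" else "+"
    intron = GenomicInterval(gene.seq_id, e1.end, e2.start, strand)
    utr5 = feats["five_prime_UTR"][0]
    utr3 = feats["three_prime_UTR"][0]
    tss = e1.start if strand == "+" else e2.end - 1
    stop_codon = utr3.start if strand == "+" else utr3.end
    return GeneModel(
        gene_interval=gene,
        exons=(e1, e2),
        intron=intron,
        utr5=utr5,
        utr3=utr3,
        tss=tss,
        stop_codon=stop_codon,
        polya_signal=feats.get("polyA_signal_sequence", [None])[0],
        core_promoter=feats.get("core_promoter", [None])[0],
    )


def write_gene_model_gff3(gm: GeneModel, path: PathLike, gene_id: str = "gene1") -> None:
    def row(ftype: str, iv: GenomicInterval, attr: str) -> str:
        return "\t".join(
            [gm.seq_id, "regmap", ftype, str(iv.start + 1), str(iv.end), ".", gm.strand, ".", attr]
        )

    lines = ["##gff-version 3", row("gene", gm.gene_interval, f"ID={gene_id}")]
    for i, exon in enumerate(gm.exons, start=1):
        lines.append(row("exon", exon, f"ID={gene_id}.exon{i};Parent={gene_id}"))
    lines.append(row("five_prime_UTR", gm.utr5, f"Parent={gene_id}"))
    lines.append(row("three_prime_UTR", gm.utr3, f"Parent={gene_id}"))
    if gm.core_promoter is not None:
        lines.append(row("core_promoter", gm.core_promoter, f"Parent={gene_id}"))
    if gm.polya_signal is not None:
        lines.append(row("polyA_signal_sequence", gm.polya_signal, f"Parent={gene_id}"))
    Path(path).write_text("\n".join(lines) + "\n")
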