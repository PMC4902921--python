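"""Strand-aware genomic intervals, the two-exon gene model, and interval arithmetic.

All internal coordinates are 0-based half-open ascending (BED convention), so
``length == end - start`` holds exactly.  Genome-browser style *printed* pairs
may be descending (the convention for minus-strand loci); :meth:`GenomicInterval.from_pair`
normalises a descending pair ``(a, b)`` with ``a > b`` to ``(start=b, end=a, strand='-')``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval ``[start, end)`` on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(
                f"invalid interval {self.seq_id}:{self.start}-{self.end} "
                "(need 0 <= start <= end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    # -- construction -----------------------------------------------------

    @classmethod
    def from_pair(cls, seq_id: str, a: int, b: int, strand: Optional[str] = None) -> "GenomicInterval":
        """Build from a printed coordinate pair; a descending pair means minus strand."""
        if a > b:
            return cls(seq_id, b, a, "-")
        return cls(seq_id, a, b, strand if strand is not None else ".")

    _PRINTED = re.compile(
        r"^\s*(?:[Cc]hr)?(?P<seq>[\w.]+)\s*:\s*(?P<a>\d+)\s*-\s*(?P<b>\d+)\s*$"
    )

    @classmethod
    def from_printed(cls, text: str) -> "GenomicInterval":
        """Parse a browser-style string like ``"15:78399000 - 78406400"``.

        A leading ``chr`` prefix is dropped from the sequence name.  Descending
        pairs (``"15:78399556 - 78399030"``) are normalised to ascending with
        strand set to ``-``.
        """
        m = cls._PRINTED.match(text)
        if m is None:
            raise ValueError(f"cannot parse printed coordinates: {text!r}")
        return cls.from_pair(m.group("seq"), int(m.group("a")), int(m.group("b")))

    def printed(self) -> str:
        """Inverse of :meth:`from_printed`: minus-strand intervals print descending."""
        if self.strand == "-":
            return f"{self.seq_id}:{self.end} - {self.start}"
        return f"{self.seq_id}:{self.start} - {self.end}"

    # -- arithmetic --------------------------------------------------------

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def is_empty(self) -> bool:
        return self.end == self.start

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start <= other.start
            and other.end <= self.end
        )

    def intersection(self, other: "GenomicInterval") -> Optional["GenomicInterval"]:
        """Intersection or None (different seq_id or empty overlap)."""
        if self.seq_id != other.seq_id:
            return None
        lo = max(self.start, other.start)
        hi = min(self.end, other.end)
        if lo >= hi:
            return None
        return GenomicInterval(self.seq_id, lo, hi, self.strand)

    def intersects(self, other: "GenomicInterval") -> bool:
        return self.intersection(other) is not None

    def padded(self, pad: int, lo: int = 0, hi: Optional[int] = None) -> "GenomicInterval":
        """Expand by ``pad`` on both sides, clipped to ``[lo, hi]``."""
        start = max(lo, self.start - pad)
        end = self.end + pad
        if hi is not None:
            end = min(hi, end)
        return GenomicInterval(self.seq_id, start, max(start, end), self.strand)


def interval_length(iv: GenomicInterval) -> int:
    """Length in bp; an empty interval has length 0."""
    return iv.length


def overlap(a: GenomicInterval, b: GenomicInterval) -> Optional[GenomicInterval]:
    """Intersection of two intervals, or None when disjoint / different sequences."""
    return a.intersection(b)


def merge(intervals: Sequence[GenomicInterval], gap: int = 0) -> list[GenomicInterval]:
    """Merge intervals on one sequence, joining neighbours within ``gap`` bp.

    The result is sorted and pairwise non-overlapping; merging is idempotent.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    if not intervals:
        return []
    seq_ids = {iv.seq_id for iv in intervals}
    if len(seq_ids) > 1:
        raise ValueError(f"cannot merge intervals on multiple sequences: {sorted(seq_ids)}")
    ordered = sorted(intervals, key=lambda iv: (iv.start, iv.end))
    out: list[GenomicInterval] = [ordered[0]]
    for iv in ordered[1:]:
        prev = out[-1]
        if iv.start - prev.end <= gap:
            if iv.end > prev.end:
                out[-1] = GenomicInterval(prev.seq_id, prev.start, iv.end, prev.strand)
        else:
            out.append(iv)
    return out


class RegionContext(str, Enum):
    """Mutually exclusive positional context of a point relative to the gene model."""

    UPSTREAM = "upstream"
    CORE_PROMOTER = "core_promoter"
    UTR5 = "utr5"
    EXON = "exon"
    INTRON = "intron"
    UTR3 = "utr3"
    DOWNSTREAM = "downstream"
    BOUNDARY = "boundary"


@dataclass(frozen=True)
class GeneModel:
    """A two-exon, one-intron gene with UTRs and optional core promoter.

    ``exon``/``utr`` intervals are genomic (ascending).  ``tss`` is the
    strand-aware 5' end of exon 1 and ``stop_codon`` the genomic coordinate of
    the CDS/3'UTR junction (i.e. the first base of the 3'UTR on the plus
    strand, the base after it on the minus strand).
    """

    gene_interval: GenomicInterval
    exons: tuple[GenomicInterval, GenomicInterval]
    intron: GenomicInterval
    utr5: GenomicInterval
    utr3: GenomicInterval
    tss: int
    stop_codon: int
    polya_signal: Optional[GenomicInterval] = None
    core_promoter: Optional[GenomicInterval] = None
    upstream_flank: int = 500
    downstream_flank: int = 500

    def __post_init__(self) -> None:
        g = self.gene_interval
        e5, e3 = self.exons_5to3()
        first, second = sorted(self.exons, key=lambda e: e.start)
        if first.end > self.intron.start or self.intron.end > second.start:
            raise ValueError("intron must lie strictly between the two exons")
        if first.intersects(second):
            raise ValueError("exons must be disjoint")
        if not (g.start == first.start and g.end == second.end):
            raise ValueError("gene interval must span exon1..exon2")
        if self.strand == "+":
            if self.tss != e5.start:
                raise ValueError("tss must coincide with the 5' end of exon 1")
        else:
            if self.tss != e5.end - 1:
                raise ValueError("tss must coincide with the 5' end of exon 1")
        if not e3.contains(self.utr3):
            raise ValueError("utr3 must lie within the 3'-most exon")
        if not e5.contains(self.utr5):
            raise ValueError("utr5 must lie within the 5'-most exon")

    @property
    def strand(self) -> str:
        return self.gene_interval.strand if self.gene_interval.strand in "+-" else "+"

    @property
    def seq_id(self) -> str:
        return self.gene_interval.seq_id

    def exons_5to3(self) -> tuple[GenomicInterval, GenomicInterval]:
        first, second = sorted(self.exons, key=lambda e: e.start)
        return (first, second) if self.strand == "+" else (second, first)

    # -- positional labelling ---------------------------------------------

    def label_at(self, pos: int) -> RegionContext:
        """Label of a single base; exhaustive and mutually exclusive."""
        if self.core_promoter is not None and self.core_promoter.contains_point(pos):
            return RegionContext.CORE_PROMOTER
        g = self.gene_interval
        if pos < g.start:
            return RegionContext.UPSTREAM if self.strand == "+" else RegionContext.DOWNSTREAM
        if pos >= g.end:
            return RegionContext.DOWNSTREAM if self.strand == "+" else RegionContext.UPSTREAM
        if self.utr5.contains_point(pos):
            return RegionContext.UTR5
        if self.utr3.contains_point(pos):
            return RegionContext.UTR3
        if self.intron.contains_point(pos):
            return RegionContext.INTRON
        return RegionContext.EXON

    def _breakpoints(self) -> list[int]:
        pts = [self.gene_interval.start, self.gene_interval.end]
        for iv in (*self.exons, self.intron, self.utr5, self.utr3):
            pts.extend((iv.start, iv.end))
        if self.core_promoter is not None:
            pts.extend((self.core_promoter.start, self.core_promoter.end))
        return sorted(set(pts))

    # -- mRNA coordinates --------------------------------------------------

    @property
    def mrna_length(self) -> int:
        return sum(e.length for e in self.exons)

    def genomic_to_mrna(self, pos: int) -> int:
        """Map an exonic genomic position to spliced-mRNA coordinates (5'->3')."""
        offset = 0
        for exon in self.exons_5to3():
            if exon.contains_point(pos):
                if self.strand == "+":
                    return offset + (pos - exon.start)
                return offset + (exon.end - 1 - pos)
            offset += exon.length
        raise ValueError(f"position {pos} is not exonic")

    def mrna_to_genomic(self, pos: int) -> int:
        """Inverse of :meth:`genomic_to_mrna`."""
        if pos < 0 or pos >= self.mrna_length:
            raise ValueError(f"mRNA position {pos} out of range")
        offset = 0
        for exon in self.exons_5to3():
            if pos < offset + exon.length:
                if self.strand == "+":
                    return exon.start + (pos - offset)
                return exon.end - 1 - (pos - offset)
            offset += exon.length
        raise AssertionError("unreachable")

    def mrna_interval_to_genomic(self, start: int, end: int) -> list[GenomicInterval]:
        """Map an mRNA interval to (possibly split) ascending genomic intervals."""
        if end <= start:
            return []
        positions = [self.mrna_to_genomic(p) for p in range(start, end)]
        positions.sort()
        out: list[GenomicInterval] = []
        run_start = positions[0]
        prev = positions[0]
        for p in positions[1:]:
            if p != prev + 1:
                out.append(GenomicInterval(self.seq_id, run_start, prev + 1, self.strand))
                run_start = p
            prev = p
        out.append(GenomicInterval(self.seq_id, run_start, prev + 1, self.strand))
        return out

    @property
    def stop_codon_mrna(self) -> int:
        """mRNA coordinate of the CDS/3'UTR junction (start of the 3'UTR)."""
        if self.strand == "+":
            return self.genomic_to_mrna(self.utr3.start)
        return self.genomic_to_mrna(self.utr3.end - 1)

    def utr3_mrna(self) -> tuple[int, int]:
        """3'UTR as a half-open mRNA interval."""
        return self.stop_codon_mrna, self.mrna_length

    def mrna_sequence(self, genome_seq: str) -> str:
        """Spliced mRNA-sense sequence (DNA alphabet) from the locus sequence."""
        parts = []
        for exon in self.exons_5to3():
            s = genome_seq[exon.start:exon.end]
            if self.strand == "-":
                s = reverse_complement(s)
            parts.append(s)
        return "".join(parts)


_COMPLEMENT = str.maketrans("ACGTUNRYSWKMBDHVacgtunryswkmbdhv",
                            "TGCAANYRSWMKVHDBtgcaanyrswmkvhdb")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def classify_region(iv: GenomicInterval, gm: GeneModel) -> RegionContext:
    """Context label of an interval; ``boundary`` when it spans label borders.

    Strand-aware: for a minus-strand gene "upstream" lies right of the gene.
    An empty interval is treated as the point at its start.  Intervals outside
    the modelled locus classify as upstream/downstream, never an error.
    """
    if iv.seq_id != gm.seq_id:
        raise ValueError(f"interval on {iv.seq_id!r} but gene model on {gm.seq_id!r}")
    if iv.is_empty:
        return gm.label_at(iv.start)
    # evaluate one label per sub-segment between partition breakpoints
    cuts = [p for p in gm._breakpoints() if iv.start < p < iv.end]
    starts = [iv.start, *cuts]
    labels = {gm.label_at(p) for p in starts}
    if len(labels) == 1:
        return labels.pop()
    return RegionContext.BOUNDARY
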