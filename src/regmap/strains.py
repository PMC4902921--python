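"""Cross-strain allele concordance and strain-of-origin inference.

For each inbred strain in the allele table, count how many of the line's
variant alleles it shares (string-exact after normalisation).  A strain with
all alleles shared is an exact haplotype match; the line's likely origin is
the class (wild-derived vs classical laboratory) of its exact-match strains
when that set is class-homogeneous.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .io import StrainAlleleTable


def _norm_allele(a: str) -> str:
    return a.strip().upper()


@dataclass
class ConcordanceReport:
    line: str
    n_variants: int
    per_strain_shared: dict[str, int]

    def __post_init__(self) -> None:
        for strain, shared in self.per_strain_shared.items():
            if not 0 <= shared <= self.n_variants:
                raise ValueError(f"{strain}: shared count {shared} out of range")

    @property
    def exact_match_strains(self) -> list[str]:
        return sorted(
            s for s, n in self.per_strain_shared.items() if n == self.n_variants
        )

    def strains_sharing(self, k: int) -> list[str]:
        return sorted(s for s, n in self.per_strain_shared.items() if n == k)


def concordance(table: StrainAlleleTable, line: str) -> ConcordanceReport:
    """Per-strain allele match counts against one line's haplotype.

    Invariant to variant and strain ordering.  A missing allele entry is an
    error (raised by the table reader naming variant x strain).
    """
    if line not in table.line_alleles:
        raise ValueError(f"line {line!r} not present in table")
    line_alleles = [_norm_allele(a) for a in table.line_alleles[line]]
    shared: dict[str, int] = {}
    for j, strain in enumerate(table.strains):
        count = 0
        for i in range(table.n_variants):
            allele = _norm_allele(table.alleles[i][j])
            if not allele:
                raise ValueError(
                    f"missing allele for variant {table.variant_ids[i]!r} x strain {strain!r}"
                )
            if allele == line_alleles[i]:
                count += 1
        shared[strain] = count
    return ConcordanceReport(line=line, n_variants=table.n_variants, per_strain_shared=shared)


def origin_call(report: ConcordanceReport, strain_classes: Mapping[str, str]) -> str:
    """Origin label from the classes of the exact-match strain set.

    Returns the shared class (e.g. "wild-derived" or "classical") when the
    exact-match set is class-homogeneous, "ambiguous" when mixed, and
    "unresolved" when no strain matches exactly.
    """
    exact = report.exact_match_strains
    if not exact:
        return "unresolved"
    missing = [s for s in exact if s not in strain_classes]
    if missing:
        raise ValueError(f"no class annotation for strains {missing}")
    classes = {strain_classes[s] for s in exact}
    if len(classes) == 1:
        return classes.pop()
    return "ambiguous"
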