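"""Cross-comparison concordance: the per-variant status matrix over the four
case-control arms, the "consistently enriched" selection rule, and the
region-based exclusion that yields wet-lab validation candidates.

The cell-level rule: a comparison cell passes when the variant is
significant there at the FDR threshold, *or* when it is absent from either
cohort of that comparison (absence from every panel is itself consistent
with case enrichment of a rare allele). A variant is selected when all
cells pass. Significance is direction-blind by default -- a significantly
*depleted* cell also passes -- because the selection this models includes
such cells; ``require_enrichment=True`` switches to a strict odds-ratio > 1
reading (documented as NOT reproducing the packaged fixture's counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    AssociationResult,
    CaseCohort,
    Comparison,
    RegionFlag,
    Status,
    VariantKey,
    VariantRecord,
)

__all__ = [
    "ComparisonMatrix",
    "build_matrix",
    "select_consistent",
    "significant_keys",
    "concordant_in_cohort",
    "validation_candidates",
    "carrier_matrix",
]

#: Region classes excluded from wet-lab validation.
VALIDATION_EXCLUDED_FLAGS = frozenset(
    {RegionFlag.REPETITIVE, RegionFlag.POLYMORPHIC_LOCUS}
)

_PASSING = frozenset(
    {
        Status.SIGNIFICANT,
        Status.UNTESTABLE_CASE_ABSENT,
        Status.UNTESTABLE_CONTROL_ABSENT,
    }
)


@dataclass
class ComparisonMatrix:
    """Variants x comparisons grid of association results."""

    comparisons: tuple[Comparison, ...]
    rows: dict[VariantKey, dict[Comparison, AssociationResult]]

    def __len__(self) -> int:
        return len(self.rows)

    def cell(self, key: VariantKey, comparison: Comparison) -> AssociationResult:
        return self.rows[key][comparison]

    def column(self, comparison: Comparison) -> list[AssociationResult]:
        return [self.rows[key][comparison] for key in self.rows]

    def to_frame(self) -> pd.DataFrame:
        """Status grid as a DataFrame (variants x comparison labels)."""
        data = {
            c.label: [self.rows[k][c].status.value for k in self.rows]
            for c in self.comparisons
        }
        return pd.DataFrame(data, index=[k.hgvs or k.label for k in self.rows])


def build_matrix(result_lists: Sequence[Sequence[AssociationResult]]) -> ComparisonMatrix:
    """Assemble per-comparison result lists into a matrix.

    Every list must cover the same key universe and carry a distinct
    comparison label.
    """
    if not result_lists:
        return ComparisonMatrix((), {})
    comparisons = []
    universe: list[VariantKey] | None = None
    rows: dict[VariantKey, dict[Comparison, AssociationResult]] = {}
    for results in result_lists:
        if not results:
            raise ValueError("empty result list for one comparison")
        comp = results[0].comparison
        if any(r.comparison != comp for r in results):
            raise ValueError(f"mixed comparison labels in one list ({comp})")
        if comp in comparisons:
            raise ValueError(f"duplicate comparison {comp}")
        comparisons.append(comp)
        keys = [r.key for r in results]
        if universe is None:
            universe = keys
            rows = {k: {} for k in keys}
        elif set(keys) != set(universe):
            raise ValueError(
                f"comparison {comp} covers a different key universe "
                f"({len(keys)} vs {len(universe)} keys)"
            )
        for r in results:
            rows[r.key][comp] = r
    return ComparisonMatrix(tuple(comparisons), rows)


def _cell_passes(result: AssociationResult, require_enrichment: bool) -> bool:
    if result.status is Status.PENDING:
        raise ValueError(
            f"unannotated cell {result.key.label} ({result.comparison}); "
            "run multiple-testing annotation first"
        )
    if result.status not in _PASSING:
        return False
    if (
        require_enrichment
        and result.status is Status.SIGNIFICANT
        and result.or_cmle is not None
        and result.or_cmle <= 1.0
    ):
        return False
    return True


def select_consistent(
    matrix: ComparisonMatrix, require_enrichment: bool = False
) -> set[VariantKey]:
    """Variants whose every comparison cell is significant or cohort-absent."""
    return {
        key
        for key, cells in matrix.rows.items()
        if all(
            _cell_passes(cells[c], require_enrichment) for c in matrix.comparisons
        )
    }


def significant_keys(matrix: ComparisonMatrix, comparison: Comparison) -> set[VariantKey]:
    return {
        key
        for key, cells in matrix.rows.items()
        if cells[comparison].status is Status.SIGNIFICANT
    }


def concordant_in_cohort(matrix: ComparisonMatrix, case_name: str) -> set[VariantKey]:
    """Keys significant in *both* control comparisons of the named case cohort."""
    cols = [c for c in matrix.comparisons if c.case_name == case_name]
    if not cols:
        raise ValueError(f"no comparisons with case cohort {case_name!r}")
    sets = [significant_keys(matrix, c) for c in cols]
    return set.intersection(*sets)


def validation_candidates(
    selected: Iterable[VariantKey],
    records: Iterable[VariantRecord] | Mapping[VariantKey, VariantRecord],
    excluded_flags: frozenset[RegionFlag] = VALIDATION_EXCLUDED_FLAGS,
) -> set[VariantKey]:
    """Drop selected variants lying in highly repetitive or highly
    polymorphic regions; the remainder are wet-lab validation candidates."""
    if not isinstance(records, Mapping):
        records = {r.key: r for r in records}
    out = set()
    for key in selected:
        rec = records.get(key)
        flags = rec.region_flags if rec is not None else frozenset()
        if not flags & excluded_flags:
            out.add(key)
    return out


def carrier_matrix(
    cohort: CaseCohort,
    keys: Sequence[VariantKey],
    case_annotations: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Oncoplot-style data layer: variants x cases dosage matrix.

    Requires a genotype-backed cohort. Optional per-case annotation columns
    (age, family history, ...) are appended as extra rows, mirroring how
    such plots annotate their case axis.
    """
    if cohort.genotypes is None:
        raise ValueError(f"cohort {cohort.name!r} holds no per-individual genotypes")
    cases = [f"case_{i + 1}" for i in range(cohort.n_individuals)]
    rows = {}
    for key in keys:
        dosage = cohort.genotypes.get(key)
        if dosage is None:
            dosage = np.zeros(cohort.n_individuals, dtype=np.int8)
        rows[key.hgvs or key.label] = dosage
    df = pd.DataFrame(rows, index=cases).T
    if case_annotations is not None:
        anno = case_annotations.copy()
        anno.index = cases[: len(anno)]
        df = pd.concat([df, anno.T])
    return df
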