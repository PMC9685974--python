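"""Ordered variant-prioritization filters with a per-stage audit trail.

The cascade mirrors the funnel of a germline discovery study: sequencing
QC -> population-frequency rarity -> functional consequence (protein-
truncating classes exempt from the CADD cutoff) -> cancer-gene evidence ->
case recurrence -> manual-review flags. Every predicate is per-variant, so
the surviving set is the conjunction of the stage predicates and is
insensitive to stage order; the trace records the order actually run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

from .model import (
    CaseCohort,
    Consequence,
    GeneEvidence,
    PROTEIN_TRUNCATING,
    VariantKey,
    VariantRecord,
)

__all__ = [
    "FilterConfig",
    "FilterStage",
    "FilterTrace",
    "qc_filter",
    "frequency_filter",
    "consequence_filter",
    "gene_prioritization_filter",
    "recurrence_filter",
    "review_filter",
    "run_cascade",
]


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the prioritization cascade.

    Defaults follow the study design this package models: variants with a
    reference-population MAF of 1% or more are removed (unreported
    variants are kept), nonsynonymous SNVs need a scaled CADD score
    strictly above 20, protein-truncating classes are kept regardless of
    CADD, and a variant must be carried by at least three case
    individuals.
    """

    maf_threshold: float = 0.01
    cadd_threshold: float = 20.0
    min_carriers: int = 3
    cadd_exempt_consequences: frozenset[Consequence] = PROTEIN_TRUNCATING
    require_review_pass: bool = True

    def __post_init__(self) -> None:
        if self.maf_threshold <= 0 or self.cadd_threshold <= 0:
            raise ValueError("thresholds must be strictly positive")
        if self.min_carriers < 1:
            raise ValueError("min_carriers must be >= 1")


@dataclass(frozen=True)
class FilterStage:
    name: str
    n_in: int
    n_out: int
    removed: tuple[VariantKey, ...]

    def __post_init__(self) -> None:
        if self.n_in - self.n_out != len(self.removed):
            raise ValueError(
                f"stage {self.name}: {self.n_in} in, {self.n_out} out, "
                f"but {len(self.removed)} removals recorded"
            )


@dataclass
class FilterTrace:
    stages: list[FilterStage] = field(default_factory=list)

    def record(
        self,
        name: str,
        before: Sequence[VariantRecord],
        after: Sequence[VariantRecord],
    ) -> None:
        kept = {r.key for r in after}
        removed = tuple(r.key for r in before if r.key not in kept)
        self.stages.append(FilterStage(name, len(before), len(after), removed))

    def as_dict(self) -> dict:
        return {
            "stages": [
                {
                    "name": s.name,
                    "in": s.n_in,
                    "out": s.n_out,
                    "removed": [k.label for k in s.removed],
                }
                for s in self.stages
            ]
        }


def qc_filter(variants: Iterable[VariantRecord]) -> list[VariantRecord]:
    """Keep variants that passed the caller's quality-control checks."""
    return [v for v in variants if v.qc_pass]


def frequency_filter(
    variants: Iterable[VariantRecord], maf_threshold: float = 0.01
) -> list[VariantRecord]:
    """Keep rare variants: reference MAF strictly below the threshold.

    A variant unreported in the reference population (``maf_reference is
    None``) is retained -- absence of frequency evidence is treated as
    rarity, not as zero.
    """
    return [
        v
        for v in variants
        if v.maf_reference is None or v.maf_reference < maf_threshold
    ]


def consequence_filter(
    variants: Iterable[VariantRecord],
    cadd_threshold: float = 20.0,
    exempt: frozenset[Consequence] = PROTEIN_TRUNCATING,
) -> list[VariantRecord]:
    """Keep protein-truncating variants unconditionally and nonsynonymous
    SNVs with scaled CADD strictly above the threshold; drop other classes.
    """
    out = []
    for v in variants:
        if v.consequence in exempt:
            out.append(v)
        elif v.consequence is Consequence.NONSYNONYMOUS_SNV:
            if v.cadd_scaled is None:
                raise ValueError(
                    f"{v.key.label}: nonsynonymous SNV without a CADD score"
                )
            if v.cadd_scaled > cadd_threshold:
                out.append(v)
    return out


def gene_prioritization_filter(
    variants: Iterable[VariantRecord],
    evidence: Mapping[str, GeneEvidence],
) -> list[VariantRecord]:
    """Keep variants whose gene is on the primary cancer-gene list and
    corroborated by at least one other database (case-insensitive)."""
    upper = {g.upper(): e for g, e in evidence.items()}
    return [v for v in variants if upper.get(v.gene.upper(), _NO_EVIDENCE).eligible]


_NO_EVIDENCE = GeneEvidence("", False, frozenset())


def recurrence_filter(
    variants: Iterable[VariantRecord],
    case_cohort: CaseCohort,
    min_carriers: int = 3,
) -> list[VariantRecord]:
    """Keep variants carried by at least ``min_carriers`` case individuals.

    Carriers are counted as individuals with dosage >= 1; a homozygote
    counts once. Variants missing from the cohort have zero carriers.
    """
    return [v for v in variants if case_cohort.carriers(v.key) >= min_carriers]


def review_filter(variants: Iterable[VariantRecord]) -> list[VariantRecord]:
    """Drop variants whose manual read-pileup review marked them suspect.

    ``review_pass is None`` (review skipped, e.g. alignments too complex
    to judge) counts as a pass; only an explicit ``False`` removes.
    """
    return [v for v in variants if v.review_pass is not False]


def run_cascade(
    variants: Sequence[VariantRecord],
    case_cohort: CaseCohort,
    evidence: Mapping[str, GeneEvidence],
    config: FilterConfig | None = None,
) -> tuple[list[VariantRecord], FilterTrace]:
    """Apply all stages in order QC -> frequency -> consequence -> gene ->
    recurrence -> review, recording every removal in the trace."""
    config = config or FilterConfig()
    stages: list[tuple[str, Callable[[list[VariantRecord]], list[VariantRecord]]]] = [
        ("qc", qc_filter),
        ("frequency", lambda vs: frequency_filter(vs, config.maf_threshold)),
        (
            "consequence",
            lambda vs: consequence_filter(
                vs, config.cadd_threshold, config.cadd_exempt_consequences
            ),
        ),
        ("gene_evidence", lambda vs: gene_prioritization_filter(vs, evidence)),
        (
            "recurrence",
            lambda vs: recurrence_filter(vs, case_cohort, config.min_carriers),
        ),
        (
            "review",
            review_filter if config.require_review_pass else (lambda vs: list(vs)),
        ),
    ]
    trace = FilterTrace()
    current = list(variants)
    for name, stage in stages:
        nxt = stage(current)
        trace.record(name, current, nxt)
        current = nxt
    return current, trace
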