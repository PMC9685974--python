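"""Domain types for rare-variant case-control enrichment analysis.

The objects here mirror how aggregate variant data is exchanged in
case-control studies of rare germline variation: a case cohort is held as
per-variant allele/carrier counts over diploid individuals, while control
populations (gnomAD-style frequency panels, or an external case cohort
published only as frequencies) are held as (allele frequency, allele number)
summaries. The variant key -- (chromosome, position, ref, alt) -- is the
join key across every table; a transcript HGVS string rides along for
display only and never participates in equality.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "Consequence",
    "AcmgClass",
    "RegionFlag",
    "Status",
    "VariantKey",
    "VariantRecord",
    "CaseVariantCounts",
    "CaseCohort",
    "FrequencyEntry",
    "ControlFrequencyTable",
    "GeneEvidence",
    "ContingencyTable",
    "Comparison",
    "AssociationResult",
    "round_half_up",
    "PROTEIN_TRUNCATING",
]


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero (0.5 -> 1).

    Allele counts are reconstructed from published frequencies as
    ``round_half_up(AF * AN)``; this convention, not banker's rounding,
    matches how frequency tables are printed.
    """
    return int(math.floor(x + 0.5))


class Consequence(str, enum.Enum):
    NONSYNONYMOUS_SNV = "nonsynonymous_snv"
    FRAMESHIFT_INSERTION = "frameshift_insertion"
    FRAMESHIFT_DELETION = "frameshift_deletion"
    STOPGAIN = "stopgain"
    OTHER = "other"


#: Protein-truncating classes kept regardless of CADD score.
PROTEIN_TRUNCATING = frozenset(
    {
        Consequence.FRAMESHIFT_INSERTION,
        Consequence.FRAMESHIFT_DELETION,
        Consequence.STOPGAIN,
    }
)


class AcmgClass(str, enum.Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    UNCERTAIN = "uncertain"
    LIKELY_BENIGN = "likely_benign"
    BENIGN = "benign"
    UNKNOWN = "unknown"


class RegionFlag(str, enum.Enum):
    REPETITIVE = "repetitive"
    POLYMORPHIC_LOCUS = "polymorphic_locus"
    SEGMENTAL_DUPLICATION = "segmental_duplication"
    HOMOPOLYMER = "homopolymer"


class Status(str, enum.Enum):
    """Per-comparison outcome of one variant's association test."""

    PENDING = "pending"
    SIGNIFICANT = "significant"
    NOT_SIGNIFICANT = "not_significant"
    UNTESTABLE_CASE_ABSENT = "untestable_case_absent"
    UNTESTABLE_CONTROL_ABSENT = "untestable_control_absent"


@dataclass(frozen=True, order=True)
class VariantKey:
    """Identity of one alternate allele at one site.

    ``hgvs`` is display metadata (e.g. ``NM_170606.3:c.C2710T``) and is
    excluded from equality and hashing so that tables annotated with
    different transcript strings still join.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    hgvs: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt alleles are identical: {self.ref!r}")

    @property
    def label(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hgvs or self.label


@dataclass(frozen=True)
class VariantRecord:
    """One annotated candidate variant, as consumed by the filter cascade.

    ``maf_reference`` is the control-population (gnomAD-style) MAF used for
    frequency filtering; ``None`` means the variant is unreported there,
    which is *not* the same as a frequency of zero. ``review_pass`` is the
    boolean surrogate for visual read-pileup review; ``None`` means review
    was skipped (e.g. the locus was too complex to review).
    """

    key: VariantKey
    gene: str
    consequence: Consequence
    cadd_scaled: float | None = None
    maf_reference: float | None = None
    qc_pass: bool = True
    acmg_class: AcmgClass = AcmgClass.UNKNOWN
    region_flags: frozenset[RegionFlag] = frozenset()
    review_pass: bool | None = None
    notes: str = ""

    def __post_init__(self) -> None:
        if self.cadd_scaled is not None and self.cadd_scaled < 0:
            raise ValueError(f"CADD score must be >= 0, got {self.cadd_scaled}")
        if self.maf_reference is not None and not 0.0 <= self.maf_reference <= 1.0:
            raise ValueError(f"MAF must lie in [0, 1], got {self.maf_reference}")


@dataclass(frozen=True)
class CaseVariantCounts:
    """Summarised carrier information for one variant in a case cohort."""

    carrier_individuals: int
    alt_alleles: int
    allele_number: int

    def __post_init__(self) -> None:
        if not 0 <= self.alt_alleles <= self.allele_number:
            raise ValueError(
                f"alt alleles {self.alt_alleles} outside [0, AN={self.allele_number}]"
            )
        if self.carrier_individuals < 0 or self.carrier_individuals > self.alt_alleles:
            raise ValueError(
                "carrier individuals must lie in [0, alt alleles]: "
                f"{self.carrier_individuals} vs {self.alt_alleles}"
            )


@dataclass
class CaseCohort:
    """Diploid case cohort with per-variant carrier counts.

    ``genotypes`` optionally retains per-individual allele dosages (0/1/2,
    -1 for missing) for cohorts read from genotype-level files; summary-only
    cohorts (such as the packaged study fixture) leave it ``None``.
    """

    name: str
    n_individuals: int
    counts: dict[VariantKey, CaseVariantCounts] = field(default_factory=dict)
    genotypes: dict[VariantKey, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.n_individuals < 0:
            raise ValueError("cohort size must be non-negative")
        for key, c in self.counts.items():
            if c.allele_number > 2 * self.n_individuals:
                raise ValueError(
                    f"{key.label}: allele number {c.allele_number} exceeds "
                    f"2 x {self.n_individuals} individuals"
                )

    def __len__(self) -> int:
        return len(self.counts)

    def has_variant(self, key: VariantKey) -> bool:
        return key in self.counts

    def alt_allele_count(self, key: VariantKey) -> int:
        return self.counts[key].alt_alleles

    def allele_number_at(self, key: VariantKey) -> int:
        return self.counts[key].allele_number

    def carriers(self, key: VariantKey) -> int:
        """Number of case individuals carrying at least one alternate allele."""
        if key not in self.counts:
            return 0
        return self.counts[key].carrier_individuals


@dataclass(frozen=True)
class FrequencyEntry:
    allele_frequency: float
    allele_number: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.allele_frequency <= 1.0:
            raise ValueError(
                f"allele frequency outside [0, 1]: {self.allele_frequency}"
            )
        if self.allele_number < 0:
            raise ValueError("allele number must be non-negative")

    @property
    def allele_count(self) -> int:
        return round_half_up(self.allele_frequency * self.allele_number)


@dataclass
class ControlFrequencyTable:
    """Aggregate allele-frequency panel for a control (or external case) cohort.

    Keys absent from ``entries`` are "not reported in this cohort" -- the
    tri-state absence semantics the concordance rule relies on. An entry
    with frequency 0.0 is *present with zero observed alternate alleles*,
    which is a different thing.
    """

    name: str
    n_individuals: int
    entries: dict[VariantKey, FrequencyEntry] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, e in self.entries.items():
            if e.allele_number > 2 * self.n_individuals:
                raise ValueError(
                    f"{key.label}: allele number {e.allele_number} exceeds "
                    f"2 x {self.n_individuals} individuals"
                )

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def default_allele_number(self) -> int:
        return 2 * self.n_individuals

    def present(self, key: VariantKey) -> bool:
        return key in self.entries

    # CaseCohort-compatible surface so an external case cohort published
    # only as frequencies can sit on the case side of a comparison.
    has_variant = present

    def frequency(self, key: VariantKey) -> float:
        return self.entries[key].allele_frequency

    def alt_allele_count(self, key: VariantKey) -> int:
        return self.entries[key].allele_count

    def allele_number_at(self, key: VariantKey) -> int:
        return self.entries[key].allele_number


@dataclass(frozen=True)
class GeneEvidence:
    """Cancer-gene database support for one gene symbol."""

    gene: str
    in_primary_list: bool = False
    corroborating_lists: frozenset[str] = frozenset()

    @property
    def eligible(self) -> bool:
        """Primary-list membership corroborated by at least one other list."""
        return self.in_primary_list and len(self.corroborating_lists) >= 1


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 allele-count table: rows cases/controls, columns alt/ref alleles."""

    a: int  # case alternate alleles
    b: int  # case reference alleles
    c: int  # control alternate alleles
    d: int  # control reference alleles

    def __post_init__(self) -> None:
        for cell in (self.a, self.b, self.c, self.d):
            if cell < 0:
                raise ValueError(f"negative cell in {self.cells}")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)

    @property
    def case_an(self) -> int:
        return self.a + self.b

    @property
    def control_an(self) -> int:
        return self.c + self.d

    @property
    def alt_total(self) -> int:
        return self.a + self.c

    def support(self) -> tuple[int, int]:
        """Range of the case-alt cell with all margins held fixed."""
        kmin = max(0, self.alt_total - self.control_an)
        kmax = min(self.case_an, self.alt_total)
        return kmin, kmax

    def sample_odds_ratio(self) -> float:
        """Plain cross-product estimate (a*d)/(b*c); inf/0/nan at zero cells."""
        if self.b * self.c == 0:
            if self.a * self.d == 0:
                return math.nan
            return math.inf
        return (self.a * self.d) / (self.b * self.c)

    def transpose(self) -> "ContingencyTable":
        return ContingencyTable(self.a, self.c, self.b, self.d)


@dataclass(frozen=True)
class Comparison:
    """One case-cohort-versus-control-panel arm of the study design."""

    case_name: str
    control_name: str

    @property
    def label(self) -> str:
        return f"{self.case_name}_vs_{self.control_name}"

    def __str__(self) -> str:
        return self.label


@dataclass
class AssociationResult:
    """Exact-test outcome for one variant in one comparison.

    ``or_cmle`` is the conditional maximum-likelihood odds ratio (the
    estimator whose zero-cell limits are 0 and +inf); ``or_sample`` is the
    cross-product estimate, emitted alongside for comparison. ``p_adjusted``
    stays ``None`` until multiple-testing adjustment runs.
    """

    key: VariantKey
    comparison: Comparison
    table: ContingencyTable | None = None
    or_cmle: float | None = None
    or_sample: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    p_raw: float | None = None
    p_adjusted: float | None = None
    status: Status = Status.PENDING
    gene: str = ""

    @property
    def testable(self) -> bool:
        return self.table is not None

    def __post_init__(self) -> None:
        if self.p_raw is not None and not 0.0 < self.p_raw <= 1.0:
            raise ValueError(f"p-value outside (0, 1]: {self.p_raw}")


def variant_map(records: Iterable[VariantRecord]) -> dict[VariantKey, VariantRecord]:
    """Index records by key, rejecting duplicate keys."""
    out: dict[VariantKey, VariantRecord] = {}
    for rec in records:
        if rec.key in out:
            raise ValueError(f"duplicate variant key {rec.key.label}")
        out[rec.key] = rec
    return out
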