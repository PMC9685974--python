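"""Synthetic case cohorts and control panels with known ground truth.

The generator emulates the data a rare-variant case-control study consumes:
aggregate control panels with rare baseline allele frequencies (< 1%),
diploid case cohorts whose per-allele carrier probability is tied to a
per-variant true odds ratio, per-variant allele-number dropout, and the
annotation columns every filter stage inspects. Planted effects are
recorded in a truth table so pipeline output can be scored for sensitivity
and false-discovery proportion.

Sampling model: for baseline control allele frequency ``q`` and true odds
ratio ``psi``, the case-allele carrier probability is

    p_case = psi * q / (1 - q + psi * q)

and case alternate-allele counts are Binomial(case allele number, p_case)
-- odds-ratio-faithful sampling on alleles. At frequencies below 1%,
Hardy-Weinberg homozygotes are negligible, so per-allele sampling matches
per-genotype sampling to well within simulation noise while keeping the
allele-count tables exact.

Determinism: each variant draws from its own counter-derived stream
(``SeedSequence(seed, spawn_key=(variant_index,))``), so enlarging a
simulation never perturbs the draws of earlier variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    AcmgClass,
    CaseCohort,
    CaseVariantCounts,
    Consequence,
    ControlFrequencyTable,
    FrequencyEntry,
    GeneEvidence,
    RegionFlag,
    VariantKey,
    VariantRecord,
)

__all__ = [
    "PlantedEffect",
    "AnnotationModel",
    "SimulationConfig",
    "SyntheticDataset",
    "SyntheticStudy",
    "generate_cohort",
    "generate_study",
    "RecoveryReport",
    "recover_planted",
    "case_allele_probability",
]

PRIMARY_LIST = "primary"
CORROBORATING_LIST = "corroborating"


def case_allele_probability(psi: float, q: float) -> float:
    """Case-allele carrier probability for true odds ratio psi at baseline q."""
    if psi < 0 or not 0.0 <= q <= 1.0:
        raise ValueError("need psi >= 0 and q in [0, 1]")
    return psi * q / (1.0 - q + psi * q)


@dataclass(frozen=True)
class PlantedEffect:
    """A variant index carrying a known association signal."""

    index: int
    odds_ratio: float
    baseline_af: float

    def __post_init__(self) -> None:
        if self.odds_ratio <= 0:
            raise ValueError("planted odds ratio must be > 0")
        if not 0.0 <= self.baseline_af < 1.0:
            raise ValueError("baseline AF outside [0, 1)")


@dataclass(frozen=True)
class AnnotationModel:
    """Per-variant annotation sampling model.

    The QC failure rate defaults to 7.9%, the fraction of raw calls a
    stringent short-read caller typically rejects in an exome cohort of
    this design. Consequence classes mix functional and silent calls so
    the consequence stage has work to do; CADD scores are uniform on
    10-40 (phred-like scale), straddling the pathogenicity cutoff of 20.
    """

    qc_fail_rate: float = 0.079
    consequence_probs: tuple[tuple[Consequence, float], ...] = (
        (Consequence.NONSYNONYMOUS_SNV, 0.60),
        (Consequence.OTHER, 0.30),
        (Consequence.FRAMESHIFT_DELETION, 0.04),
        (Consequence.STOPGAIN, 0.04),
        (Consequence.FRAMESHIFT_INSERTION, 0.02),
    )
    cadd_range: tuple[float, float] = (10.0, 40.0)
    p_gene_primary: float = 0.5
    p_gene_corroborated: float = 0.6  # given primary membership
    region_flag_rate: float = 0.03
    review_fail_rate: float = 0.02
    maf_missing_rate: float = 0.05

    def __post_init__(self) -> None:
        total = sum(p for _, p in self.consequence_probs)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"consequence probabilities sum to {total}, not 1")
        for p in (
            self.qc_fail_rate,
            self.p_gene_primary,
            self.p_gene_corroborated,
            self.region_flag_rate,
            self.review_fail_rate,
            self.maf_missing_rate,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability outside [0, 1]: {p}")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for one synthetic dataset.

    Defaults mirror the cohort geometry this package models: a 290-case
    discovery cohort against a 9,977-individual control panel, with a
    466-case replication cohort and a 9,770-individual second panel used
    by :func:`generate_study`. Baseline allele frequencies are
    log-uniform on [1e-4, 1e-2) -- rare variation.
    """

    seed: int
    n_cases: int = 290
    n_control_individuals: int = 9977
    n_variants: int = 200
    baseline_law: str = "log_uniform"  # or "point"
    baseline_range: tuple[float, float] = (1e-4, 1e-2)
    planted_effects: tuple[PlantedEffect, ...] = ()
    annotations: AnnotationModel = field(default_factory=AnnotationModel)
    an_dropout_max: float = 0.05
    n_cases_replication: int = 466
    n_control_individuals_2: int = 9770

    def __post_init__(self) -> None:
        if self.baseline_law not in {"log_uniform", "point"}:
            raise ValueError(f"unknown baseline law {self.baseline_law!r}")
        lo, hi = self.baseline_range
        if not 0.0 < lo <= hi < 1.0:
            raise ValueError(f"baseline range invalid: {self.baseline_range}")
        for e in self.planted_effects:
            if not 0 <= e.index < self.n_variants:
                raise ValueError(f"planted index {e.index} >= n_variants")
        if len({e.index for e in self.planted_effects}) != len(self.planted_effects):
            raise ValueError("duplicate planted indices")
        if not 0.0 <= self.an_dropout_max < 1.0:
            raise ValueError("an_dropout_max outside [0, 1)")


@dataclass
class SyntheticDataset:
    case: CaseCohort
    control: ControlFrequencyTable
    variants: list[VariantRecord]
    evidence: dict[str, GeneEvidence]
    truth: pd.DataFrame


@dataclass
class SyntheticStudy:
    """Two case cohorts and two control panels drawn from one truth table."""

    cases: list[CaseCohort]
    controls: list[ControlFrequencyTable]
    variants: list[VariantRecord]
    evidence: dict[str, GeneEvidence]
    truth: pd.DataFrame


def _variant_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def _sample_counts(
    rng: np.random.Generator,
    an: int,
    prob: float,
) -> int:
    return int(rng.binomial(an, prob))


def _an_with_dropout(rng: np.random.Generator, n_individuals: int, dropout_max: float) -> int:
    full = 2 * n_individuals
    if dropout_max == 0.0:
        return full
    dropped = int(rng.integers(0, max(1, int(full * dropout_max)) + 1))
    # drop whole individuals (two alleles at a time), as missing genotypes do
    return full - 2 * (dropped // 2)


def _draw_baseline(rng: np.random.Generator, config: SimulationConfig) -> float:
    lo, hi = config.baseline_range
    if config.baseline_law == "point":
        return lo
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def _generate(
    config: SimulationConfig,
    case_specs: Sequence[tuple[str, int]],
    control_specs: Sequence[tuple[str, int]],
) -> SyntheticStudy:
    planted = {e.index: e for e in config.planted_effects}
    ann = config.annotations
    csq_values = [c for c, _ in ann.consequence_probs]
    csq_probs = [p for _, p in ann.consequence_probs]

    case_counts: list[dict[VariantKey, CaseVariantCounts]] = [
        {} for _ in case_specs
    ]
    case_genotypes: list[dict[VariantKey, np.ndarray]] = [{} for _ in case_specs]
    control_entries: list[dict[VariantKey, FrequencyEntry]] = [
        {} for _ in control_specs
    ]
    variants: list[VariantRecord] = []
    evidence: dict[str, GeneEvidence] = {}
    truth_rows = []

    for i in range(config.n_variants):
        rng = _variant_rng(config.seed, i)
        gene = f"GENE{i:05d}"
        key = VariantKey("chrS", i + 1, "A", "G", hgvs=f"{gene}:n.{i + 1}A>G")
        effect = planted.get(i)
        q = effect.baseline_af if effect else _draw_baseline(rng, config)
        psi = effect.odds_ratio if effect else 1.0
        p_case = case_allele_probability(psi, q)

        # control panels: integer allele counts, frequency = count / AN
        for j, (_, n_ctrl) in enumerate(control_specs):
            an = _an_with_dropout(rng, n_ctrl, config.an_dropout_max)
            count = _sample_counts(rng, an, q)
            control_entries[j][key] = FrequencyEntry(count / an, an)

        # case cohorts: per-individual dosages from two independent alleles
        for j, (_, n_case) in enumerate(case_specs):
            dosage = rng.binomial(1, p_case, size=n_case) + rng.binomial(
                1, p_case, size=n_case
            )
            dosage = dosage.astype(np.int8)
            case_counts[j][key] = CaseVariantCounts(
                carrier_individuals=int(np.sum(dosage >= 1)),
                alt_alleles=int(dosage.sum()),
                allele_number=2 * n_case,
            )
            case_genotypes[j][key] = dosage

        # annotations
        if effect is not None:
            qc_pass, consequence = True, Consequence.NONSYNONYMOUS_SNV
            cadd = float(rng.uniform(21.0, ann.cadd_range[1]))
            maf_ref: float | None = q
            flags: frozenset[RegionFlag] = frozenset()
            review: bool | None = True
            in_primary, corroborated = True, True
        else:
            qc_pass = bool(rng.random() >= ann.qc_fail_rate)
            consequence = csq_values[int(rng.choice(len(csq_values), p=csq_probs))]
            cadd = float(rng.uniform(*ann.cadd_range))
            maf_ref = None if rng.random() < ann.maf_missing_rate else q
            flags = (
                frozenset({RegionFlag(rng.choice([f.value for f in RegionFlag]))})
                if rng.random() < ann.region_flag_rate
                else frozenset()
            )
            review = False if rng.random() < ann.review_fail_rate else True
            in_primary = bool(rng.random() < ann.p_gene_primary)
            corroborated = in_primary and bool(
                rng.random() < ann.p_gene_corroborated
            )
        variants.append(
            VariantRecord(
                key=key,
                gene=gene,
                consequence=consequence,
                cadd_scaled=cadd,
                maf_reference=maf_ref,
                qc_pass=qc_pass,
                acmg_class=AcmgClass.UNKNOWN,
                region_flags=flags,
                review_pass=review,
            )
        )
        evidence[gene] = GeneEvidence(
            gene,
            in_primary_list=in_primary,
            corroborating_lists=frozenset(
                {CORROBORATING_LIST} if corroborated else set()
            ),
        )
        truth_rows.append(
            {
                "index": i,
                "chrom": key.chrom,
                "pos": key.pos,
                "ref": key.ref,
                "alt": key.alt,
                "gene": gene,
                "baseline_af": q,
                "true_or": psi,
                "planted": effect is not None,
            }
        )

    cases = [
        CaseCohort(name, n, case_counts[j], case_genotypes[j])
        for j, (name, n) in enumerate(case_specs)
    ]
    controls = [
        ControlFrequencyTable(name, n, control_entries[j])
        for j, (name, n) in enumerate(control_specs)
    ]
    return SyntheticStudy(
        cases, controls, variants, evidence, pd.DataFrame(truth_rows)
    )


def generate_cohort(
    config: SimulationConfig,
) -> SyntheticDataset:
    """Generate one case cohort plus one control panel (with annotations,
    gene evidence and the truth table). Deterministic under a fixed seed."""
    study = _generate(
        config,
        [("cases", config.n_cases)],
        [("controls", config.n_control_individuals)],
    )
    return SyntheticDataset(
        case=study.cases[0],
        control=study.controls[0],
        variants=study.variants,
        evidence=study.evidence,
        truth=study.truth,
    )


def generate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate the full four-arm design: discovery and replication case
    cohorts plus two control panels, all from the same per-variant truth."""
    return _generate(
        config,
        [
            ("cases", config.n_cases),
            ("cases_replication", config.n_cases_replication),
        ],
        [
            ("controls", config.n_control_individuals),
            ("controls_2", config.n_control_individuals_2),
        ],
    )


@dataclass(frozen=True)
class RecoveryReport:
    """How well a selected variant set recovered the planted effects."""

    n_planted: int
    n_selected: int
    true_positives: int
    false_positives: int

    @property
    def sensitivity(self) -> float:
        return 1.0 if self.n_planted == 0 else self.true_positives / self.n_planted

    @property
    def false_discovery_proportion(self) -> float:
        return 0.0 if self.n_selected == 0 else self.false_positives / self.n_selected


def recover_planted(
    truth: pd.DataFrame, selected: Iterable[VariantKey]
) -> RecoveryReport:
    """Score a selected key set against the truth table."""
    planted_keys = {
        VariantKey(str(r.chrom), int(r.pos), str(r.ref), str(r.alt))
        for r in truth[truth.planted].itertuples()
    }
    selected = set(selected)
    tp = len(selected & planted_keys)
    return RecoveryReport(
        n_planted=len(planted_keys),
        n_selected=len(selected),
        true_positives=tp,
        false_positives=len(selected) - tp,
    )
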