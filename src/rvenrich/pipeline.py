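"""End-to-end drivers: filter cascade -> four exact-test comparisons ->
FDR adjustment -> concordance selection -> validation candidates, with
file-based configuration, output tables and a reproducibility manifest.

Two entry points matter to most users:

* :func:`analyze_study` -- run the association/selection layer on loaded
  in-memory objects (what the synthetic recovery study and the packaged
  fixture reanalysis use);
* :func:`run_full_pipeline` -- the file-in/file-out driver behind the CLI.

:func:`reanalyze_study_fixture` recomputes the packaged 49-variant fixture from
its stored counts and frequencies and reports every headline number of
that analysis (significance counts per comparison, cross-cohort
concordance, the consistently-enriched selection and the post-exclusion
validation candidates).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .cohorts_io import (
    ConfigurationError,
    StudyFixture,
    load_study_fixture,
    read_case_genotypes,
    read_control_frequencies,
    read_gene_lists,
    read_variant_table,
    write_association_table,
    write_variant_table,
)
from .concordance import (
    ComparisonMatrix,
    build_matrix,
    concordant_in_cohort,
    select_consistent,
    significant_keys,
    validation_candidates,
)
from .exact_association import associate
from .filter_cascade import FilterConfig, FilterTrace, run_cascade
from .model import (
    AssociationResult,
    CaseCohort,
    Comparison,
    ControlFrequencyTable,
    GeneEvidence,
    VariantKey,
    VariantRecord,
)
from .multiple_testing import annotate_significance

__all__ = [
    "AnalysisConfig",
    "StudyResult",
    "analyze_study",
    "StudyReanalysis",
    "reanalyze_study_fixture",
    "RunConfig",
    "run_full_pipeline",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Statistical switches for the association/selection layer."""

    alpha: float = 0.05
    family_mode: str = "pooled"  # or "per_comparison"
    two_sided_rule: str = "minlike"  # or "doubling"
    or_estimator: str = "cmle"  # or "sample"
    require_enrichment: bool = False
    compute_or: bool = True


@dataclass
class StudyResult:
    """Association matrix plus the derived selections."""

    results: list[AssociationResult]
    matrix: ComparisonMatrix
    selected: set[VariantKey]
    candidates: set[VariantKey]

    def significant_count(self, comparison: Comparison) -> int:
        return len(significant_keys(self.matrix, comparison))


def analyze_study(
    keys: Sequence[VariantKey],
    cases: Sequence[CaseCohort | ControlFrequencyTable],
    controls: Sequence[ControlFrequencyTable],
    records: Sequence[VariantRecord],
    config: AnalysisConfig | None = None,
) -> StudyResult:
    """Cross every case cohort with every control panel, adjust, select."""
    config = config or AnalysisConfig()
    genes = {r.key: r.gene for r in records}
    per_comparison = [
        associate(
            case,
            control,
            keys,
            compute_or=config.compute_or,
            alpha=config.alpha,
            two_sided_rule=config.two_sided_rule,
            genes=genes,
        )
        for case in cases
        for control in controls
    ]
    flat = [r for results in per_comparison for r in results]
    annotate_significance(flat, alpha=config.alpha, family_mode=config.family_mode)
    matrix = build_matrix(per_comparison)
    selected = select_consistent(matrix, require_enrichment=config.require_enrichment)
    candidates = validation_candidates(selected, records)
    return StudyResult(flat, matrix, selected, candidates)


# ---------------------------------------------------------------------------
# packaged-fixture reanalysis


@dataclass
class StudyReanalysis:
    """Recomputed headline numbers of the packaged 49-variant analysis."""

    fixture: StudyFixture
    study: StudyResult
    comparisons: dict[str, Comparison]

    def result(self, gene_hgvs: str, comparison: str) -> AssociationResult:
        """Look up one cell by ``"GENE:c.X"``-style HGVS and comparison name."""
        comp = self.comparisons[comparison]
        for r in self.study.results:
            if r.comparison == comp and r.key.hgvs.endswith(gene_hgvs):
                return r
        raise KeyError(f"{gene_hgvs} in {comparison}")

    @property
    def counts(self) -> dict[str, int]:
        m = self.study.matrix
        c = self.comparisons
        return {
            "testable_sg_vs_gnomad": sum(
                1 for r in m.column(c["sg_vs_gnomad"]) if r.testable
            ),
            "testable_sg_vs_sg10k": sum(
                1 for r in m.column(c["sg_vs_sg10k"]) if r.testable
            ),
            "significant_sg_vs_gnomad": self.study.significant_count(
                c["sg_vs_gnomad"]
            ),
            "significant_sg_vs_sg10k": self.study.significant_count(c["sg_vs_sg10k"]),
            "significant_dbgap_vs_gnomad": self.study.significant_count(
                c["dbgap_vs_gnomad"]
            ),
            "significant_dbgap_vs_sg10k": self.study.significant_count(
                c["dbgap_vs_sg10k"]
            ),
            "dbgap_concordant": len(
                concordant_in_cohort(self.study.matrix, "dbgap_cases")
            ),
            "consistently_enriched": len(self.study.selected),
            "validation_candidates": len(self.study.candidates),
        }


def reanalyze_study_fixture(config: AnalysisConfig | None = None) -> StudyReanalysis:
    """Re-run exact association + FDR + concordance on the packaged fixture."""
    fx = load_study_fixture()
    study = analyze_study(
        fx.keys,
        [fx.sg_cases, fx.dbgap_cases],
        [fx.gnomad_eas, fx.sg10k],
        fx.variants,
        config,
    )
    comparisons = {
        "sg_vs_gnomad": Comparison("sg_cases", "gnomad_eas"),
        "sg_vs_sg10k": Comparison("sg_cases", "sg10k"),
        "dbgap_vs_gnomad": Comparison("dbgap_cases", "gnomad_eas"),
        "dbgap_vs_sg10k": Comparison("dbgap_cases", "sg10k"),
    }
    return StudyReanalysis(fx, study, comparisons)


# ---------------------------------------------------------------------------
# file-based pipeline


@dataclass(frozen=True)
class RunConfig:
    """File-based pipeline configuration.

    ``case_paths`` maps cohort name -> (path, cohort size); genotype files
    make genotype-backed cohorts, frequency tables (``*.freq.tsv`` or the
    ``frequency_cases`` set) are read as aggregate case summaries.
    """

    variants_path: Path
    case_paths: Mapping[str, tuple[Path, int]]
    control_paths: Mapping[str, tuple[Path, int]]
    gene_list_primary: Path | None = None
    gene_lists_other: Mapping[str, Path] = field(default_factory=dict)
    frequency_cases: frozenset[str] = frozenset()
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    run_filter: bool = True
    output_dir: Path = Path("rvenrich_out")

    def validate(self) -> None:
        paths = [self.variants_path]
        paths += [p for p, _ in self.case_paths.values()]
        paths += [p for p, _ in self.control_paths.values()]
        if self.gene_list_primary is not None:
            paths.append(self.gene_list_primary)
        paths += list(self.gene_lists_other.values())
        missing = [str(p) for p in paths if not Path(p).exists()]
        if missing:
            raise ConfigurationError(f"missing input files: {', '.join(missing)}")
        if self.run_filter and self.gene_list_primary is None:
            raise ConfigurationError(
                "the filter cascade needs a primary gene list (or disable filtering)"
            )
        if not self.case_paths or not self.control_paths:
            raise ConfigurationError("need at least one case and one control cohort")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class PipelineOutput:
    surviving: list[VariantRecord]
    trace: FilterTrace | None
    study: StudyResult
    output_dir: Path


def run_full_pipeline(config: RunConfig) -> PipelineOutput:
    """Execute cascade -> associations -> BH -> concordance -> candidates.

    All inputs are validated before any output is written, so a missing
    file never leaves partial results behind. Outputs: per-comparison and
    combined association TSVs, the selected/candidate variant TSVs, the
    filter-trace JSON and a manifest recording input hashes, thresholds
    and package version (re-running an identical manifest reproduces
    byte-identical tables).
    """
    config.validate()
    variants = read_variant_table(config.variants_path)

    cases: list[CaseCohort | ControlFrequencyTable] = []
    first_case: CaseCohort | None = None
    for name, (path, size) in config.case_paths.items():
        if name in config.frequency_cases:
            cases.append(read_control_frequencies(path, size, name=name))
        else:
            cohort = read_case_genotypes(path, size, name=name)
            cases.append(cohort)
            first_case = first_case or cohort
    controls = [
        read_control_frequencies(path, size, name=name)
        for name, (path, size) in config.control_paths.items()
    ]

    trace: FilterTrace | None = None
    if config.run_filter:
        if first_case is None:
            raise ConfigurationError(
                "filtering needs at least one genotype-backed case cohort"
            )
        evidence = read_gene_lists(config.gene_list_primary, config.gene_lists_other)
        variants, trace = run_cascade(
            variants, first_case, evidence, config.filter_config
        )

    keys = [v.key for v in variants]
    study = analyze_study(keys, cases, controls, variants, config.analysis)

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if study.results:
        write_association_table(study.results, out / "associations.tsv")
    write_variant_table(
        [v for v in variants if v.key in study.selected], out / "selected.tsv"
    )
    write_variant_table(
        [v for v in variants if v.key in study.candidates], out / "candidates.tsv"
    )
    if trace is not None:
        (out / "filter_trace.json").write_text(json.dumps(trace.as_dict(), indent=2))

    manifest = {
        "tool": "rvenrich",
        "version": __version__,
        "inputs": {
            str(config.variants_path): _sha256(config.variants_path),
            **{
                str(p): _sha256(p)
                for p, _ in list(config.case_paths.values())
                + list(config.control_paths.values())
            },
        },
        "cohort_sizes": {
            **{n: s for n, (_, s) in config.case_paths.items()},
            **{n: s for n, (_, s) in config.control_paths.items()},
        },
        "filter": {
            "enabled": config.run_filter,
            "maf_threshold": config.filter_config.maf_threshold,
            "cadd_threshold": config.filter_config.cadd_threshold,
            "min_carriers": config.filter_config.min_carriers,
        },
        "analysis": {
            "alpha": config.analysis.alpha,
            "family_mode": config.analysis.family_mode,
            "two_sided_rule": config.analysis.two_sided_rule,
            "or_estimator": config.analysis.or_estimator,
        },
        "n_selected": len(study.selected),
        "n_candidates": len(study.candidates),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return PipelineOutput(variants, trace, study, out)
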