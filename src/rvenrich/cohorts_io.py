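"""Readers and writers for every external representation the pipeline touches.

Formats:

* case genotypes -- VCF (v4.x, via pysam) or TSV, either per-sample dosage
  columns or summarised counts;
* control frequency panels -- TSV of (chrom, pos, ref, alt, af[, an]) with a
  percent/fraction dialect switch;
* gene lists -- plain text, one symbol per line, case-insensitive;
* association result tables -- TSV with the significance-star convention
  (``*`` < 0.05, ``**`` < 0.01, ``***`` < 0.001 on the adjusted p);
* the packaged study fixture: 49 candidate variants from a published
  breast-cancer case-control analysis (290 Singapore cases, a 466-case
  early-onset cohort published as frequencies, and two aggregate control
  panels of 9,977 and 9,770 individuals), stored as printed plus exact
  Singapore-arm allele counts.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .model import (
    AcmgClass,
    AssociationResult,
    CaseCohort,
    CaseVariantCounts,
    Comparison,
    Consequence,
    ContingencyTable,
    ControlFrequencyTable,
    FrequencyEntry,
    GeneEvidence,
    RegionFlag,
    Status,
    VariantKey,
    VariantRecord,
    round_half_up,
)

__all__ = [
    "ParseError",
    "ConfigurationError",
    "read_case_genotypes",
    "write_case_counts",
    "read_control_frequencies",
    "write_control_frequencies",
    "read_gene_lists",
    "read_variant_table",
    "write_variant_table",
    "write_association_table",
    "read_association_table",
    "StudyFixture",
    "load_study_fixture",
]

KEY_COLUMNS = ["chrom", "pos", "ref", "alt"]


class ParseError(ValueError):
    """A malformed record in an input file (the message names the line)."""


class ConfigurationError(ValueError):
    """An invalid or incomplete run configuration."""


def _key_from_row(row: Mapping[str, object], line: int | None = None) -> VariantKey:
    try:
        return VariantKey(
            str(row["chrom"]),
            int(row["pos"]),
            str(row["ref"]),
            str(row["alt"]),
            hgvs=str(row.get("hgvs", "") or ""),
        )
    except (KeyError, TypeError, ValueError) as exc:
        where = f" at line {line}" if line is not None else ""
        raise ParseError(f"malformed variant key{where}: {exc}") from exc


# ---------------------------------------------------------------------------
# case genotypes


def _read_case_vcf(path: Path, cohort_size: int | None, name: str) -> CaseCohort:
    import pysam

    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if not samples:
            raise ParseError(f"{path}: VCF has no sample columns")
        if cohort_size is not None and cohort_size != len(samples):
            raise ParseError(
                f"{path}: {len(samples)} samples but cohort_size={cohort_size}"
            )
        n = len(samples)
        counts: dict[VariantKey, CaseVariantCounts] = {}
        genotypes: dict[VariantKey, np.ndarray] = {}
        for rec in vcf:
            # multi-allelic sites decompose into one record per alt allele
            for alt_index, alt in enumerate(rec.alts or (), start=1):
                key = VariantKey(rec.chrom, rec.pos, rec.ref, alt)
                dosage = np.zeros(n, dtype=np.int8)
                for i, sample in enumerate(samples):
                    gt = rec.samples[sample].get("GT")
                    if gt is None or any(al is None for al in gt):
                        dosage[i] = -1  # missing genotype
                        continue
                    dosage[i] = sum(1 for al in gt if al == alt_index)
                counts[key] = _counts_from_dosage(dosage, n, key)
                genotypes[key] = dosage
    return CaseCohort(name, n, counts, genotypes)


def _counts_from_dosage(dosage: np.ndarray, n: int, key: VariantKey) -> CaseVariantCounts:
    if np.any(dosage > 2):
        raise ParseError(f"{key.label}: dosage outside {{0,1,2,missing}}")
    missing = int(np.sum(dosage == -1))
    called = dosage[dosage >= 0]
    return CaseVariantCounts(
        carrier_individuals=int(np.sum(called >= 1)),
        alt_alleles=int(called.sum()),
        allele_number=2 * (n - missing),
    )


def _read_case_tsv(path: Path, cohort_size: int | None, name: str) -> CaseCohort:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    for col in KEY_COLUMNS:
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    summary = "alt_alleles" in df.columns
    extra = [c for c in df.columns if c not in KEY_COLUMNS + ["hgvs"]]
    counts: dict[VariantKey, CaseVariantCounts] = {}
    genotypes: dict[VariantKey, np.ndarray] | None = None
    if summary:
        if cohort_size is None:
            raise ConfigurationError(
                f"{path}: summary tables need an explicit cohort_size"
            )
        n = cohort_size
        for line, row in enumerate(df.to_dict("records"), start=2):
            key = _key_from_row(row, line)
            alt = int(row["alt_alleles"])
            an = int(row.get("allele_number") or 2 * n)
            carriers = int(row.get("carriers", alt) if not pd.isna(row.get("carriers", alt)) else alt)
            try:
                counts[key] = CaseVariantCounts(carriers, alt, an)
            except ValueError as exc:
                raise ParseError(f"{path} line {line}: {exc}") from exc
    else:
        sample_cols = extra
        n = len(sample_cols)
        if cohort_size is not None and cohort_size != n:
            raise ParseError(f"{path}: {n} sample columns but cohort_size={cohort_size}")
        genotypes = {}
        for line, row in enumerate(df.to_dict("records"), start=2):
            key = _key_from_row(row, line)
            dosage = np.empty(n, dtype=np.int8)
            for i, col in enumerate(sample_cols):
                val = row[col]
                if pd.isna(val) or str(val) in {".", "./.", ".|."}:
                    dosage[i] = -1
                elif str(val) in {"0", "1", "2"}:
                    dosage[i] = int(val)
                else:
                    raise ParseError(
                        f"{path} line {line}: dosage {val!r} outside {{0,1,2,missing}}"
                    )
            counts[key] = _counts_from_dosage(dosage, n, key)
            genotypes[key] = dosage
    cohort = CaseCohort(name, n, counts, genotypes)
    return cohort


def read_case_genotypes(
    path: str | Path, cohort_size: int | None = None, name: str = "cases"
) -> CaseCohort:
    """Read a diploid case cohort from a VCF or a TSV.

    TSV tables carry the key columns (chrom, pos, ref, alt) plus either
    per-sample dosage columns (values 0/1/2 or ``.`` for missing) or
    summary columns ``alt_alleles`` [, ``carriers``, ``allele_number``].
    Missing genotypes reduce that variant's allele number by two per
    missing sample. A file with zero variant rows yields an empty cohort
    with its size preserved.
    """
    path = Path(path)
    if path.suffix in {".vcf", ".bcf"} or str(path).endswith(".vcf.gz"):
        return _read_case_vcf(path, cohort_size, name)
    return _read_case_tsv(path, cohort_size, name)


def write_case_counts(cohort: CaseCohort, path: str | Path) -> None:
    """Write a cohort as a summary TSV (readable back by read_case_genotypes)."""
    rows = [
        {
            "chrom": k.chrom,
            "pos": k.pos,
            "ref": k.ref,
            "alt": k.alt,
            "hgvs": k.hgvs,
            "alt_alleles": c.alt_alleles,
            "carriers": c.carrier_individuals,
            "allele_number": c.allele_number,
        }
        for k, c in cohort.counts.items()
    ]
    pd.DataFrame(
        rows,
        columns=KEY_COLUMNS + ["hgvs", "alt_alleles", "carriers", "allele_number"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# control frequency panels


def read_control_frequencies(
    path: str | Path,
    n_individuals: int,
    name: str = "controls",
    dialect: str = "fraction",
) -> ControlFrequencyTable:
    """Read an aggregate allele-frequency panel.

    Columns: key fields, ``af`` and optional ``an``. ``dialect="percent"``
    divides frequencies by 100. Rows absent from the file are simply not
    present in the panel (tri-state absence, not frequency zero). The
    allele number defaults to ``2 * n_individuals`` when not supplied.
    """
    if dialect not in {"fraction", "percent"}:
        raise ConfigurationError(f"unknown frequency dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    if "af" not in df.columns:
        raise ParseError(f"{path}: missing column 'af'")
    entries: dict[VariantKey, FrequencyEntry] = {}
    for line, row in enumerate(df.to_dict("records"), start=2):
        key = _key_from_row(row, line)
        af = float(row["af"])
        if dialect == "percent":
            af /= 100.0
        an = row.get("an")
        an = 2 * n_individuals if an is None or pd.isna(an) else int(an)
        try:
            entries[key] = FrequencyEntry(af, an)
        except ValueError as exc:
            raise ParseError(f"{path} line {line}: {exc}") from exc
    return ControlFrequencyTable(name, n_individuals, entries)


def write_control_frequencies(
    table: ControlFrequencyTable, path: str | Path
) -> None:
    rows = [
        {
            "chrom": k.chrom,
            "pos": k.pos,
            "ref": k.ref,
            "alt": k.alt,
            "hgvs": k.hgvs,
            "af": repr(e.allele_frequency),
            "an": e.allele_number,
        }
        for k, e in table.entries.items()
    ]
    pd.DataFrame(rows, columns=KEY_COLUMNS + ["hgvs", "af", "an"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# gene lists


def read_gene_lists(
    primary: str | Path, others: Mapping[str, str | Path]
) -> dict[str, GeneEvidence]:
    """Load the primary cancer-gene list plus corroborating lists.

    Symbols are matched case-insensitively (stored upper-case). Genes
    absent from every list are simply absent from the returned map; use
    ``.get(gene, GeneEvidence(gene))`` for ineligible-by-default lookups.
    """

    def _symbols(p: str | Path) -> set[str]:
        text = Path(p).read_text()
        return {line.strip().upper() for line in text.splitlines() if line.strip()}

    primary_genes = _symbols(primary)
    if not primary_genes:
        raise ConfigurationError(f"primary gene list {primary} is empty")
    corroborating = {label: _symbols(p) for label, p in others.items()}
    evidence: dict[str, GeneEvidence] = {}
    all_genes = primary_genes.union(*corroborating.values()) if corroborating else primary_genes
    for gene in sorted(all_genes):
        labels = frozenset(
            label for label, genes in corroborating.items() if gene in genes
        )
        evidence[gene] = GeneEvidence(gene, gene in primary_genes, labels)
    return evidence


# ---------------------------------------------------------------------------
# annotated variant tables


_VARIANT_COLUMNS = KEY_COLUMNS + [
    "hgvs",
    "gene",
    "consequence",
    "cadd",
    "maf_reference",
    "qc_pass",
    "acmg",
    "region_flags",
    "review_pass",
]


def _parse_flags(raw: object) -> frozenset[RegionFlag]:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)) or raw == "":
        return frozenset()
    return frozenset(RegionFlag(part) for part in str(raw).split(","))


def _parse_tristate(raw: object) -> bool | None:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)) or raw == "":
        return None
    return str(raw).strip().lower() in {"true", "1", "yes"}


def read_variant_table(path: str | Path) -> list[VariantRecord]:
    """Read an annotated variant table (the filter cascade's input form)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    records = []
    for line, row in enumerate(df.to_dict("records"), start=2):
        key = _key_from_row(row, line)
        try:
            records.append(
                VariantRecord(
                    key=key,
                    gene=str(row["gene"]),
                    consequence=Consequence(row["consequence"]),
                    cadd_scaled=None if pd.isna(row.get("cadd")) else float(row["cadd"]),
                    maf_reference=(
                        None
                        if pd.isna(row.get("maf_reference"))
                        else float(row["maf_reference"])
                    ),
                    qc_pass=bool(_parse_tristate(row.get("qc_pass", True)) is not False),
                    acmg_class=AcmgClass(row.get("acmg", "unknown") or "unknown"),
                    region_flags=_parse_flags(row.get("region_flags")),
                    review_pass=_parse_tristate(row.get("review_pass")),
                )
            )
        except (KeyError, ValueError) as exc:
            raise ParseError(f"{path} line {line}: {exc}") from exc
    return records


def write_variant_table(records: Iterable[VariantRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "chrom": r.key.chrom,
                "pos": r.key.pos,
                "ref": r.key.ref,
                "alt": r.key.alt,
                "hgvs": r.key.hgvs,
                "gene": r.gene,
                "consequence": r.consequence.value,
                "cadd": r.cadd_scaled,
                "maf_reference": r.maf_reference,
                "qc_pass": str(r.qc_pass).lower(),
                "acmg": r.acmg_class.value,
                "region_flags": ",".join(sorted(f.value for f in r.region_flags)),
                "review_pass": "" if r.review_pass is None else str(r.review_pass).lower(),
            }
        )
    pd.DataFrame(rows, columns=_VARIANT_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# association result tables


def significance_stars(p_adjusted: float | None) -> str:
    """Star convention on the adjusted p: *** < 0.001, ** < 0.01, * < 0.05."""
    if p_adjusted is None:
        return ""
    for stars, cut in (("***", 1e-3), ("**", 1e-2), ("*", 5e-2)):
        if p_adjusted < cut:
            return stars
    return ""


def _fmt_or(value: float | None) -> str:
    if value is None:
        return ""
    if math.isinf(value):
        return "Inf"
    return repr(value)


_ASSOC_COLUMNS = KEY_COLUMNS + [
    "hgvs",
    "gene",
    "case_af",
    "control_af",
    "odds_ratio",
    "ci_low",
    "ci_high",
    "p_raw",
    "p_adjusted",
    "stars",
    # extras enabling lossless read-back
    "comparison_case",
    "comparison_control",
    "status",
    "a",
    "b",
    "c",
    "d",
    "or_sample",
]


def write_association_table(
    results: Iterable[AssociationResult], path: str | Path
) -> None:
    """Write association results as TSV, one row per variant per comparison."""
    results = list(results)
    if not results:
        raise ValueError("refusing to write an empty association table")
    rows = []
    for r in results:
        t = r.table
        rows.append(
            {
                "chrom": r.key.chrom,
                "pos": r.key.pos,
                "ref": r.key.ref,
                "alt": r.key.alt,
                "hgvs": r.key.hgvs,
                "gene": r.gene,
                "case_af": "" if t is None else repr(t.a / t.case_an),
                "control_af": "" if t is None else repr(t.c / t.control_an),
                "odds_ratio": _fmt_or(r.or_cmle),
                "ci_low": _fmt_or(r.ci_low),
                "ci_high": _fmt_or(r.ci_high),
                "p_raw": "" if r.p_raw is None else repr(r.p_raw),
                "p_adjusted": "" if r.p_adjusted is None else repr(r.p_adjusted),
                "stars": significance_stars(r.p_adjusted),
                "comparison_case": r.comparison.case_name,
                "comparison_control": r.comparison.control_name,
                "status": r.status.value,
                "a": "" if t is None else t.a,
                "b": "" if t is None else t.b,
                "c": "" if t is None else t.c,
                "d": "" if t is None else t.d,
                "or_sample": _fmt_or(r.or_sample),
            }
        )
    pd.DataFrame(rows, columns=_ASSOC_COLUMNS).to_csv(path, sep="\t", index=False)


def _parse_or(raw: object) -> float | None:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)) or raw == "":
        return None
    if str(raw) == "Inf":
        return math.inf
    return float(raw)


def read_association_table(path: str | Path) -> list[AssociationResult]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    out = []
    for line, row in enumerate(df.to_dict("records"), start=2):
        key = _key_from_row(row, line)
        table = None
        if not pd.isna(row.get("a")):
            table = ContingencyTable(
                int(row["a"]), int(row["b"]), int(row["c"]), int(row["d"])
            )
        out.append(
            AssociationResult(
                key=key,
                comparison=Comparison(
                    str(row["comparison_case"]), str(row["comparison_control"])
                ),
                table=table,
                or_cmle=_parse_or(row.get("odds_ratio")),
                or_sample=_parse_or(row.get("or_sample")),
                ci_low=_parse_or(row.get("ci_low")),
                ci_high=_parse_or(row.get("ci_high")),
                p_raw=None if pd.isna(row.get("p_raw")) else float(row["p_raw"]),
                p_adjusted=(
                    None if pd.isna(row.get("p_adjusted")) else float(row["p_adjusted"])
                ),
                status=Status(row["status"]),
                gene="" if pd.isna(row.get("gene")) else str(row["gene"]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# the packaged study fixture


#: Diploid cohort sizes of the four arms of the packaged study fixture.
FIXTURE_COHORT_SIZES = {
    "sg_cases": 290,
    "dbgap_cases": 466,
    "gnomad_eas": 9977,
    "sg10k": 9770,
}


@dataclass
class StudyFixture:
    """The packaged 49-variant case-control fixture.

    Holds the discovery case cohort as exact allele/carrier counts, the
    replication case cohort and both control panels as frequency tables,
    the annotated variant records feeding the filter stages, and the
    printed odds-ratio/adjusted-p reference values for cross-checks.
    Variant keys use transcript-space surrogates (accession, cDNA position,
    alleles parsed from the HGVS) because genomic coordinates are not part
    of the published table; all joins go through these keys consistently.
    """

    variants: list[VariantRecord]
    sg_cases: CaseCohort
    dbgap_cases: ControlFrequencyTable
    gnomad_eas: ControlFrequencyTable
    sg10k: ControlFrequencyTable
    printed: pd.DataFrame
    discrepant_keys: frozenset[VariantKey] = frozenset()

    @property
    def keys(self) -> list[VariantKey]:
        return [rec.key for rec in self.variants]

    @property
    def genes(self) -> dict[VariantKey, str]:
        return {rec.key: rec.gene for rec in self.variants}

    def comparisons(self) -> list[tuple[object, ControlFrequencyTable]]:
        """The four (case side, control side) pairs of the study design."""
        return [
            (self.sg_cases, self.gnomad_eas),
            (self.sg_cases, self.sg10k),
            (self.dbgap_cases, self.gnomad_eas),
            (self.dbgap_cases, self.sg10k),
        ]


def load_study_fixture() -> StudyFixture:
    """Load the packaged 49-variant fixture.

    Singapore-arm allele counts are stored exactly (they take precedence
    over the printed, 2-decimal-rounded percentages); the replication case
    cohort and both control panels are reconstructed from printed
    frequencies over default allele numbers (2 x cohort size). Rows whose
    printed frequency and patient count disagree beyond rounding are
    flagged in ``discrepant_keys`` and noted per-record.
    """
    ref = importlib.resources.files("rvenrich.data").joinpath("candidate_variants.tsv")
    with importlib.resources.as_file(ref) as p:
        df = pd.read_csv(p, sep="\t", dtype={"ref": str, "alt": str})
    if len(df) != 49:
        raise RuntimeError(f"fixture must hold 49 variants, found {len(df)}")

    sizes = FIXTURE_COHORT_SIZES
    variants: list[VariantRecord] = []
    sg_counts: dict[VariantKey, CaseVariantCounts] = {}
    dbgap: dict[VariantKey, FrequencyEntry] = {}
    gnomad: dict[VariantKey, FrequencyEntry] = {}
    sg10k: dict[VariantKey, FrequencyEntry] = {}
    discrepant: set[VariantKey] = set()

    for row in df.to_dict("records"):
        key = VariantKey(
            str(row["transcript"]),
            int(row["pos"]),
            str(row["ref"]),
            str(row["alt"]),
            hgvs=f"{row['transcript']}:{row['hgvs_c']}",
        )
        note = "" if pd.isna(row["sg_af_note"]) else str(row["sg_af_note"])
        gnomad_af = None if pd.isna(row["af_gnomad_eas"]) else row["af_gnomad_eas"] / 100.0
        variants.append(
            VariantRecord(
                key=key,
                gene=str(row["gene"]),
                consequence=Consequence(row["consequence"]),
                cadd_scaled=float(row["cadd"]),
                maf_reference=gnomad_af,
                qc_pass=True,
                acmg_class=AcmgClass(row["acmg"]),
                region_flags=_parse_flags(row["region_flags"]),
                review_pass=_parse_tristate(row["review_pass"]),
                notes=note,
            )
        )
        n_pat = int(row["n_patients"])
        alt = int(row["sg_alt_alleles"])
        sg_counts[key] = CaseVariantCounts(
            carrier_individuals=n_pat,
            alt_alleles=alt,
            allele_number=2 * sizes["sg_cases"],
        )
        if note:
            discrepant.add(key)
        for col, store, cohort in (
            ("af_case_dbgap", dbgap, "dbgap_cases"),
            ("af_gnomad_eas", gnomad, "gnomad_eas"),
            ("af_sg10k", sg10k, "sg10k"),
        ):
            if not pd.isna(row[col]):
                store[key] = FrequencyEntry(row[col] / 100.0, 2 * sizes[cohort])

    return StudyFixture(
        variants=variants,
        sg_cases=CaseCohort("sg_cases", sizes["sg_cases"], sg_counts),
        dbgap_cases=ControlFrequencyTable("dbgap_cases", sizes["dbgap_cases"], dbgap),
        gnomad_eas=ControlFrequencyTable("gnomad_eas", sizes["gnomad_eas"], gnomad),
        sg10k=ControlFrequencyTable("sg10k", sizes["sg10k"], sg10k),
        printed=df,
        discrepant_keys=frozenset(discrepant),
    )
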