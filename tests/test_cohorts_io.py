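"""I/O layer: VCF/TSV case cohorts, frequency panels, gene lists,
association tables and the packaged 49-variant fixture."""

import math

import pandas as pd
import pytest

from rvenrich.cohorts_io import (
    ConfigurationError,
    ParseError,
    load_study_fixture,
    read_association_table,
    read_case_genotypes,
    read_control_frequencies,
    read_gene_lists,
    read_variant_table,
    significance_stars,
    write_association_table,
    write_case_counts,
    write_control_frequencies,
    write_variant_table,
)
from rvenrich.model import (
    AssociationResult,
    Comparison,
    ContingencyTable,
    Status,
    VariantKey,
)

VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\tS4
"""


class TestVariantKey:
    def test_validation(self):
        with pytest.raises(ValueError):
            VariantKey("1", 0, "A", "G")
        with pytest.raises(ValueError):
            VariantKey("1", 5, "A", "A")

    def test_hgvs_is_display_only(self):
        a = VariantKey("1", 5, "A", "G", hgvs="NM_1:c.5A>G")
        b = VariantKey("1", 5, "A", "G")
        assert a == b and hash(a) == hash(b)


class TestReadCaseGenotypes:
    def test_toy_vcf_dosages_and_missing(self, tmp_path):
        # genotypes 0/1, 1/1, 0/0, ./. -> 3 alt alleles over AN = 6
        vcf = tmp_path / "cases.vcf"
        vcf.write_text(
            VCF_HEADER + "1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\t1/1\t0/0\t./.\n"
        )
        cohort = read_case_genotypes(vcf, cohort_size=4)
        key = VariantKey("1", 100, "A", "G")
        counts = cohort.counts[key]
        assert counts.alt_alleles == 3
        assert counts.allele_number == 6
        assert counts.carrier_individuals == 2
        assert cohort.genotypes[key].tolist() == [1, 2, 0, -1]

    def test_multiallelic_site_decomposes(self, tmp_path):
        vcf = tmp_path / "cases.vcf"
        vcf.write_text(
            VCF_HEADER + "1\t100\t.\tA\tG,T\t.\tPASS\t.\tGT\t0/1\t0/2\t1/2\t0/0\n"
        )
        cohort = read_case_genotypes(vcf, cohort_size=4)
        assert cohort.counts[VariantKey("1", 100, "A", "G")].alt_alleles == 2
        assert cohort.counts[VariantKey("1", 100, "A", "T")].alt_alleles == 2
        assert len(cohort) == 2

    def test_zero_variant_rows_preserves_cohort_size(self, tmp_path):
        vcf = tmp_path / "cases.vcf"
        vcf.write_text(VCF_HEADER)
        cohort = read_case_genotypes(vcf, cohort_size=4)
        assert len(cohort) == 0
        assert cohort.n_individuals == 4

    def test_cohort_size_mismatch_rejected(self, tmp_path):
        vcf = tmp_path / "cases.vcf"
        vcf.write_text(VCF_HEADER)
        with pytest.raises(ParseError, match="cohort_size"):
            read_case_genotypes(vcf, cohort_size=290)

    def test_tsv_dosage_columns(self, tmp_path):
        tsv = tmp_path / "cases.tsv"
        tsv.write_text(
            "chrom\tpos\tref\talt\tS1\tS2\tS3\n" "1\t10\tA\tG\t0\t1\t.\n"
        )
        cohort = read_case_genotypes(tsv)
        counts = cohort.counts[VariantKey("1", 10, "A", "G")]
        assert (counts.alt_alleles, counts.allele_number) == (1, 4)

    def test_tsv_invalid_dosage_names_line(self, tmp_path):
        tsv = tmp_path / "cases.tsv"
        tsv.write_text("chrom\tpos\tref\talt\tS1\n1\t10\tA\tG\t3\n")
        with pytest.raises(ParseError, match="line 2"):
            read_case_genotypes(tsv)

    def test_summary_roundtrip_exact(self, tmp_path, study_fixture):
        path = tmp_path / "sg.tsv"
        write_case_counts(study_fixture.sg_cases, path)
        back = read_case_genotypes(path, cohort_size=290, name="sg_cases")
        assert back.counts == study_fixture.sg_cases.counts


class TestReadControlFrequencies:
    def test_percent_dialect_with_default_allele_number(self, tmp_path):
        path = tmp_path / "panel.tsv"
        path.write_text("chrom\tpos\tref\talt\taf\n7\t2710\tC\tT\t0.20\n")
        panel = read_control_frequencies(path, 9977, dialect="percent")
        key = VariantKey("7", 2710, "C", "T")
        assert panel.frequency(key) == pytest.approx(0.0020)
        assert panel.allele_number_at(key) == 19954
        assert panel.alt_allele_count(key) == 40

    def test_missing_row_means_absent(self, tmp_path):
        path = tmp_path / "panel.tsv"
        path.write_text("chrom\tpos\tref\talt\taf\n1\t1\tA\tG\t0.001\n")
        panel = read_control_frequencies(path, 100)
        assert not panel.present(VariantKey("1", 2, "A", "G"))

    def test_explicit_allele_number_count_reconstruction(self, tmp_path):
        path = tmp_path / "panel.tsv"
        path.write_text("chrom\tpos\tref\talt\taf\tan\n1\t1\tA\tG\t0.5\t10\n")
        panel = read_control_frequencies(path, 100)
        assert panel.alt_allele_count(VariantKey("1", 1, "A", "G")) == 5

    def test_out_of_range_frequency_rejected(self, tmp_path):
        path = tmp_path / "panel.tsv"
        path.write_text("chrom\tpos\tref\talt\taf\n1\t1\tA\tG\t1.5\n")
        with pytest.raises(ParseError, match="line 2"):
            read_control_frequencies(path, 100)

    def test_roundtrip_counts_exact(self, tmp_path, study_fixture):
        path = tmp_path / "sg10k.tsv"
        write_control_frequencies(study_fixture.sg10k, path)
        back = read_control_frequencies(path, 9770, name="sg10k")
        for key, entry in study_fixture.sg10k.entries.items():
            assert back.entries[key].allele_number == entry.allele_number
            assert back.entries[key].allele_count == entry.allele_count


class TestGeneLists:
    def _write(self, tmp_path, name, genes):
        p = tmp_path / name
        p.write_text("\n".join(genes) + "\n")
        return p

    def test_primary_plus_corroboration_is_eligible(self, tmp_path):
        primary = self._write(tmp_path, "ncg.txt", ["RNF43", "KMT2C"])
        cosmic = self._write(tmp_path, "cgc.txt", ["rnf43"])
        ev = read_gene_lists(primary, {"cgc": cosmic})
        assert ev["RNF43"].eligible
        assert not ev["KMT2C"].eligible  # primary only
        assert "BRCA1" not in ev  # in no list

    def test_corroboration_without_primary_is_ineligible(self, tmp_path):
        primary = self._write(tmp_path, "ncg.txt", ["KMT2C"])
        a = self._write(tmp_path, "a.txt", ["GPRIN2"])
        b = self._write(tmp_path, "b.txt", ["GPRIN2"])
        ev = read_gene_lists(primary, {"a": a, "b": b})
        assert ev["GPRIN2"].corroborating_lists == {"a", "b"}
        assert not ev["GPRIN2"].eligible

    def test_empty_primary_list_is_a_configuration_error(self, tmp_path):
        primary = self._write(tmp_path, "ncg.txt", [])
        with pytest.raises(ConfigurationError):
            read_gene_lists(primary, {})


class TestAssociationTable:
    def _results(self):
        comp = Comparison("cases", "controls")
        table = ContingencyTable(3, 577, 0, 19954)
        return [
            AssociationResult(
                VariantKey("17", 311, "C", "T", hgvs="NM_1:c.C311T"),
                comp,
                table=ContingencyTable(7, 573, 12, 19942),
                or_cmle=19.99,
                or_sample=20.3,
                ci_low=6.5,
                ci_high=56.7,
                p_raw=1e-7,
                p_adjusted=0.004,
                status=Status.SIGNIFICANT,
                gene="RNF43",
            ),
            AssociationResult(
                VariantKey("17", 1589, "G", "C"),
                comp,
                table=table,
                or_cmle=math.inf,
                or_sample=math.inf,
                ci_low=14.25,
                ci_high=math.inf,
                p_raw=5e-5,
                p_adjusted=0.2,
                status=Status.NOT_SIGNIFICANT,
                gene="RNF43",
            ),
            AssociationResult(
                VariantKey("16", 44, "A", "C"),
                comp,
                status=Status.UNTESTABLE_CONTROL_ABSENT,
                gene="BRD7",
            ),
        ]

    def test_stars_convention(self):
        assert significance_stars(0.0005) == "***"
        assert significance_stars(0.004) == "**"
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.2) == ""
        assert significance_stars(None) == ""

    def test_write_read_roundtrip_with_infinities(self, tmp_path):
        path = tmp_path / "assoc.tsv"
        results = self._results()
        write_association_table(results, path)
        raw = path.read_text()
        assert "Inf" in raw and "inf" not in raw.replace("Inf", "")
        back = read_association_table(path)
        for orig, rt in zip(results, back):
            assert rt.key == orig.key
            assert rt.status == orig.status
            assert rt.or_cmle == orig.or_cmle
            assert rt.p_adjusted == orig.p_adjusted
            assert (rt.table is None) == (orig.table is None)
            if rt.table is not None:
                assert rt.table.cells == orig.table.cells

    def test_star_column_matches_adjusted_p(self, tmp_path):
        path = tmp_path / "assoc.tsv"
        write_association_table(self._results(), path)
        df = pd.read_csv(path, sep="\t")
        assert df.loc[0, "stars"] == "**"
        assert pd.isna(df.loc[1, "stars"])  # 0.2 -> no stars

    def test_empty_results_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_association_table([], tmp_path / "assoc.tsv")


class TestVariantTableRoundtrip:
    def test_fixture_records_roundtrip(self, tmp_path, study_fixture):
        path = tmp_path / "variants.tsv"
        write_variant_table(study_fixture.variants, path)
        back = read_variant_table(path)
        assert [r.key for r in back] == [r.key for r in study_fixture.variants]
        for orig, rt in zip(study_fixture.variants, back):
            assert rt.consequence == orig.consequence
            assert rt.region_flags == orig.region_flags
            assert rt.review_pass == orig.review_pass
            assert rt.maf_reference == pytest.approx(
                orig.maf_reference, abs=1e-12
            ) or (rt.maf_reference is None and orig.maf_reference is None)


class TestStudyFixture:
    def test_shape_and_cohort_sizes(self, study_fixture):
        assert len(study_fixture.variants) == 49
        assert len({r.gene for r in study_fixture.variants}) == 37
        assert study_fixture.sg_cases.n_individuals == 290
        assert study_fixture.dbgap_cases.n_individuals == 466
        assert study_fixture.gnomad_eas.n_individuals == 9977
        assert study_fixture.sg10k.n_individuals == 9770

    def test_carrier_counts_match_printed_patient_numbers(self, study_fixture):
        by_gene = {r.key.hgvs: r.key for r in study_fixture.variants}
        gprin2 = by_gene["NM_014696.4:c.C983G"]
        assert study_fixture.sg_cases.carriers(gprin2) == 17
        kmt2c = by_gene["NM_170606.3:c.C2710T"]
        assert study_fixture.sg_cases.alt_allele_count(kmt2c) == 28

    def test_absence_is_tristate(self, study_fixture):
        brd7 = next(r.key for r in study_fixture.variants if r.gene == "BRD7")
        for panel in (study_fixture.dbgap_cases, study_fixture.gnomad_eas, study_fixture.sg10k):
            assert not panel.present(brd7)
        # reported-as-zero is NOT absence: one variant has frequency 0.00
        zero_keys = [
            k for k, e in study_fixture.gnomad_eas.entries.items()
            if e.allele_frequency == 0.0
        ]
        assert zero_keys  # e.g. several rows print 0.00 in the big panel

    def test_panel_counts(self, study_fixture):
        assert len(study_fixture.gnomad_eas) == 47  # two variants unreported
        assert len(study_fixture.sg10k) == 42
        assert len(study_fixture.dbgap_cases) == 34

    def test_case_af_consistent_with_printed_percentages(self, study_fixture):
        """carriers/(2*290) at 2 decimals of percent equals the printed AF
        for every row whose allele count is internally consistent."""
        printed = study_fixture.printed.set_index("hgvs_c")
        for rec in study_fixture.variants:
            row = printed.loc[rec.key.hgvs.split(":")[1]]
            if rec.key in study_fixture.discrepant_keys:
                continue
            alt = study_fixture.sg_cases.alt_allele_count(rec.key)
            assert round(100 * alt / 580, 2) == pytest.approx(
                row["af_case_sg"], abs=5e-3
            )

    def test_known_discrepant_rows_are_flagged(self, study_fixture):
        genes = {r.gene for r in study_fixture.variants if r.key in study_fixture.discrepant_keys}
        assert {"MAF", "TPTE2"} <= genes
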