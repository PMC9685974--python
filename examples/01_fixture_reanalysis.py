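"""Re-run the packaged 49-variant case-control analysis.

Loads the packaged fixture (49 candidate variants from a 290-case breast
cancer discovery cohort, a 466-case replication cohort published as
frequencies, and two aggregate population panels of 9,977 and 9,770
individuals), recomputes every 2x2 exact test, BH-adjusts the pooled
family, and applies the cross-cohort concordance selection.
"""

from rvenrich import reanalyze_study_fixture

ra = reanalyze_study_fixture()

print("Recomputed analysis of the packaged fixture")
print("-" * 46)
for name, value in ra.counts.items():
    print(f"{name:32s} {value}")

print()
print("Selected (consistently enriched or cohort-absent in all 4 comparisons):")
for key in sorted(ra.study.selected):
    gene = ra.fixture.genes[key]
    flag = "" if key in ra.study.candidates else "  [excluded from validation]"
    print(f"  {gene:10s} {key.hgvs}{flag}")

r = ra.result("c.C2710T", "sg_vs_gnomad")
print()
print("One cell in detail -- KMT2C stopgain, discovery cases vs large panel:")
print(f"  table (a,b,c,d) = {r.table.cells}")
print(f"  conditional-MLE OR = {r.or_cmle:.2f}  95% CI ({r.ci_low:.2f}, {r.ci_high:.2f})")
print(f"  raw p = {r.p_raw:.3g}   BH-adjusted p = {r.p_adjusted:.3g}")
print()
print("The selection counts (13 / 23 / 14 / 10) are the headline numbers of")
print("the analysis: variants enriched in cases against both population")
print("panels and in both case cohorts, minus repetitive/polymorphic loci.")
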