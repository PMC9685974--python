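# Methods

This note documents the statistical model, the conventions the package
commits to where a design choice was genuinely open, the synthetic-data
generator's scope, and known limitations.

## Data model

The unit of analysis is one alternate allele at one site. The join key
across all tables is (chromosome, position, ref, alt); a transcript
HGVS string is carried for display but excluded from equality, so
tables annotated against different transcript strings still join. In
the packaged fixture, where genomic coordinates are not part of the
published table, keys use transcript-space surrogates (accession as the
chromosome label, cDNA position, alleles parsed from the HGVS; unknown
deleted bases are encoded as N-runs). This is a labelling convention
only — every join in the fixture goes through the same keys.

Absence is tri-state and load-bearing. A variant can be (a) present
with a frequency (including frequency 0.00 — observed zero alternate
alleles over the panel's allele number), (b) absent from a control
panel, or (c) absent from a case cohort. Only (a) forms a testable
table; (b) and (c) yield `untestable_control_absent` /
`untestable_case_absent` statuses that never enter the FDR family but
*pass* the concordance rule (see below).

## Exact inference on 2×2 allele-count tables

With both margins fixed, the case-alternate cell follows Fisher's
noncentral hypergeometric distribution with noncentrality ψ (the odds
ratio). All quantities derive from that one density, computed with
log-gamma binomial coefficients and per-evaluation normalization, so
allele numbers of ~20,000 (population panels) are handled without
overflow.

* **Two-sided p.** Default rule is minimum-likelihood: sum the null
  probabilities of every support point whose probability does not
  exceed the observed one, with a relative tie tolerance of 1e−7 to
  absorb floating-point ties. This is the convention of the standard
  exact-test implementations (R's `fisher.test`, scipy), and the one
  under which the fixture's published significance pattern reproduces.
  A tail-doubling alternative sits behind `rule="doubling"`.
  The exact p is strictly positive; values that would underflow double
  precision are clamped to the smallest positive float.
* **Odds-ratio estimator.** Default is the conditional MLE — the root
  of E[K | ψ] = a, found by bracketed root-finding on log ψ (initial
  bracket ±30, geometric expansion, `brentq` at xtol 1e−12, residual
  checked to 1e−10). Its zero-cell conventions (0 when a = 0, +∞ when
  a saturates the support; 0 for the degenerate all-absent table)
  match how aggregate case-control tables are conventionally printed.
  The sample cross-product OR is emitted alongside; at the cell sizes
  of the fixture's well-populated rows the two agree within 1%.
* **Exact CI.** Cornfield-style test inversion: the lower bound solves
  P(K ≥ a | ψ) = α/2 (0 when a is the support minimum), the upper
  solves P(K ≤ a | ψ) = α/2 (+∞ at the support maximum); roots by
  bisection on log ψ to 1e−8. The interval is conservative by
  construction; simulated coverage at a fixed true ψ is ≥ 95% (checked
  over 2,000 replicates in the test suite).

Control cohorts enter only as (allele frequency, allele number)
aggregates. Counts are reconstructed as round-half-up(AF × AN), the
same rounding used when frequencies are emitted, so count → frequency
→ count round-trips exactly. AN defaults to 2 × cohort size when a
per-variant value is not supplied; for published tables that print
only rounded frequencies this reconstruction is approximate, which is
why per-row odds-ratio agreement is only asserted for rows with
well-populated cells.

## Multiple testing

Benjamini–Hochberg step-up, implemented directly (q_(i) = min over
j ≥ i of m·p_(j)/j, capped at 1). The default family is **pooled**: all
testable tables across every case–control comparison form one family.
This choice was forced by the data: with per-comparison families the
packaged fixture's borderline cells land at adjusted p of 0.050–0.070
and the published selection counts are unreachable, whereas the pooled
family reproduces every published count and back-calculates the
printed borderline adjusted p-values (0.018 vs 0.02, 0.023 vs 0.026,
0.029 vs 0.03). `family_mode="per_comparison"` remains available and
is exercised by the tests, but is documented as not reproducing the
fixture's counts. Significance is strict: adjusted p < α with α = 0.05.

## Concordance selection

A comparison cell passes when its status is `significant` or either
absence status; a variant is selected when all four cells pass. Two
deliberate readings are baked in:

* "Missing" passes whether the variant is absent from the control or
  from the case cohort of a comparison. This is the only reading under
  which the fixture yields its published 14-variant selection (two
  selected variants are absent from the replication case cohort).
* Significance is direction-blind: a significantly *depleted* cell
  (ψ̂ < 1) also passes, because the fixture's published 13- and
  14-variant sets contain such cells. `require_enrichment=True`
  switches to a strict ψ̂ > 1 rule and is documented as not
  reproducing those counts.

Validation candidates are the selection minus variants flagged
`repetitive` or `polymorphic_locus`; `segmental_duplication` and
`homopolymer` flags annotate reliability but do not exclude (those
variants were validation-attempted in the study this models).

## Filter cascade

Boundary conventions, each exercised by a test: MAF is retained iff
< 1% strictly (a variant at exactly 1% is removed) and an absent MAF is
retained; CADD is retained iff strictly > 20 for nonsynonymous SNVs;
protein-truncating classes (stopgain, frameshift indels) bypass CADD;
recurrence counts carrier *individuals* (a homozygote counts once);
review is tri-state with "not reviewed" counting as a pass (loci too
complex to review were not excludable on review grounds). All
predicates are per-variant, so the surviving set is the conjunction of
the predicates and stage order affects only the trace, not the result
(property-tested against brute force). QC and review are consumed as
flags; the cascade never inspects reads.

## Synthetic data

The generator emulates the study geometry: a 290-case discovery cohort,
a 466-case replication cohort, control panels of 9,977 and 9,770
diploid individuals, baseline allele frequencies log-uniform on
[1e−4, 1e−2), per-variant allele-number dropout (whole individuals,
up to 5%), and annotation columns calibrated to the modelled study
(7.9% QC failure; a consequence mix dominated by nonsynonymous SNVs;
CADD uniform on 10–40 straddling the cutoff at 20). Planted effects
sample case alleles at probability ψq/(1 − q + ψq) —
odds-ratio-faithful per-allele sampling; at baseline frequencies below
1% Hardy–Weinberg homozygotes are negligible, so this matches
per-genotype sampling while keeping allele-count tables exact. Each
variant draws from its own counter-derived substream
(`SeedSequence(seed, spawn_key=(index,))`), so enlarging a simulation
never perturbs earlier variants.

What the generator does **not** model: linkage disequilibrium,
population structure or relatedness, genotype-quality error modes,
per-site coverage variation beyond uniform AN dropout, and gene-level
clustering of variants (each synthetic variant gets its own gene).
Passing recovery tests therefore demonstrate the pipeline's behaviour
under clean sampling assumptions, not robustness to stratification or
calling artefacts.

Problem sizes in the test suite are chosen for single-CPU runtimes:
the recovery study uses 10 planted effects (ψ = 30 at q = 0.002) among
190 nulls over 200 independent seeds; the null-calibration check uses
2,000 variant-replicates; CI coverage uses 2,000 tables. The
law-of-large-numbers check runs one variant at 100,000 cases.

## The packaged fixture

The 49-variant fixture stores, per variant: the printed per-cohort
allele frequencies (2 dp of percent), the exact discovery-arm carrier
and allele counts, consequence/CADD/ACMG annotations, and region
flags. The discovery-arm allele count takes precedence over the
rounded percentage. For a handful of rows the published table is
internally inconsistent (a printed frequency implying more alleles
than 2 × the printed patient count permits); these rows store the
patient-count reading and are flagged, and the fixture loader exposes
the flagged keys. Rows whose allele count derives from the printed
frequency but does not re-round to it at 2 dp are flagged likewise;
the allele-frequency self-check test skips exactly the flagged rows.

## Known limitations

* Exact per-row reproduction of every published odds ratio is not
  possible without the study's unprinted per-variant allele numbers;
  agreement is asserted (at 1%) only for rows whose four cells are all
  ≥ ~20, where the reconstruction is insensitive to AN.
* The conditional exact test is conservative; at very sparse cells the
  minimum-likelihood p and the doubling p can differ materially, and
  the package makes no mid-p correction (out of scope).
* Multi-allelic decomposition treats each alternate allele
  independently; no joint burden or haplotype modelling.
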