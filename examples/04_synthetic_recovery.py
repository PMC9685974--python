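"""Planted-signal recovery through the full four-arm analysis.

Plants ten variants with true odds ratio 30 at baseline frequency 0.2%
among 190 nulls, samples a discovery cohort (290 cases), a replication
cohort (466 cases) and two control panels from the same truth, then runs
exact association + BH + concordance selection and scores the result.
"""

from rvenrich import (
    AnalysisConfig,
    PlantedEffect,
    SimulationConfig,
    analyze_study,
    generate_study,
    recover_planted,
)

planted = tuple(PlantedEffect(i, odds_ratio=30.0, baseline_af=0.002) for i in range(10))
config = SimulationConfig(seed=7, n_variants=200, planted_effects=planted)
study = generate_study(config)

result = analyze_study(
    [v.key for v in study.variants],
    study.cases,
    study.controls,
    study.variants,
    AnalysisConfig(compute_or=False),
)
report = recover_planted(study.truth, result.selected)

print(f"planted signals      : {report.n_planted} (true OR 30, baseline AF 0.2%)")
print(f"selected by pipeline : {report.n_selected}")
print(f"true positives       : {report.true_positives}")
print(f"false positives      : {report.false_positives}")
print(f"sensitivity          : {report.sensitivity:.2f}")
print(f"FDP                  : {report.false_discovery_proportion:.2f}")
print()
print("Requiring significance (or absence) in all four case-control")
print("comparisons is a strict rule: null variants essentially never pass,")
print("while an odds ratio of 30 at this baseline frequency is recovered")
print("with near-certainty at these cohort sizes.")
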