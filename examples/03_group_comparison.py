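"""Bootstrap comparison of kinetics between microbial groups.

Builds a cohort where Gram-positive and Gram-negative infections genuinely
differ in their albumin change-point (using the published per-group fits),
then asks whether the bootstrap detects the difference and whether each
group's change-point differs from the diagnosis day (day 0).
"""
from bsikinetics import (
    Biomarker,
    MicrobialGroup,
    REFERENCE_GROUP_KINETICS,
    SimulationScenario,
    bootstrap_group_difference,
    generate_cohort,
    one_group_vs_reference,
)
from bsikinetics.simulate import reference_scenario

base = reference_scenario()
scenario = SimulationScenario(
    n_patients=600,
    group_probs={MicrobialGroup.GRAM_POS: 0.5, MicrobialGroup.GRAM_NEG: 0.5},
    kinetics={g: REFERENCE_GROUP_KINETICS[g]
              for g in (MicrobialGroup.GRAM_POS, MicrobialGroup.GRAM_NEG)},
    sampling_profile=base.sampling_profile,
    crp_noise_sd_log=base.crp_noise_sd_log,
    pa_noise_sd=base.pa_noise_sd,
    seed=3,
)
cohort = generate_cohort(scenario)

d = bootstrap_group_difference(cohort, Biomarker.PA, MicrobialGroup.GRAM_POS,
                               MicrobialGroup.GRAM_NEG, "c", n_reps=500, rng=1)
verdict = "significant" if d.significant else "not significant"
print(f"albumin change-point, gram_pos - gram_neg: "
      f"95% CI {d.ci95[0]:.2f} to {d.ci95[1]:.2f} ({verdict})")

for g in (MicrobialGroup.GRAM_POS, MicrobialGroup.GRAM_NEG):
    r = one_group_vs_reference(cohort, Biomarker.PA, g, "c", 0.0,
                               n_reps=500, rng=1)
    verdict = "differs from day 0" if r.significant else "compatible with day 0"
    print(f"{g.value}: change-point 95% CI {r.ci95[0]:.2f} to "
          f"{r.ci95[1]:.2f} -> {verdict}")

# The true group change-points are -0.3 vs -1.1 days. A significant
# difference means the 95% percentile interval of the bootstrapped
# difference excludes zero; the per-group tests ask the clinically
# interpretable question "did albumin start falling before the day the
# blood culture was drawn?".
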