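"""A synthetic two-arm trial: simulate INR trajectories, compare arm TTRs.

Generates one year of monthly INR visits per patient for both arms from the
packaged band dynamics, scores every trajectory with the Rosendaal method,
and re-estimates the generating transition probabilities from the data.
"""

from warfcea import (
    SimulationSpec,
    arm_contrast_check,
    default_base_case,
    estimate_transition_probs,
    simulate_cohort,
)

config = default_base_case()
n = 500

cohorts = {
    name: simulate_cohort(
        SimulationSpec(arm=config.arm(name), n_patients=n, seed=seed)
    )
    for name, seed in (("intervention", 11), ("control", 22))
}

contrast = arm_contrast_check(cohorts["intervention"], cohorts["control"])
print(f"median TTR, managed therapy : {contrast.intervention_median:5.1f}%")
print(f"median TTR, standard care   : {contrast.control_median:5.1f}%")
print(f"poor control (<65%) percent : "
      f"{contrast.intervention_category_percent['<65%']:.1f}% vs "
      f"{contrast.control_category_percent['<65%']:.1f}%")
# The managed arm's higher in-range retention shows up directly as a higher
# median TTR and fewer poorly controlled patients.

print("\nparameter recovery (control arm, estimate vs generating value):")
est = estimate_transition_probs(cohorts["control"])
for name in ("p_within_to_below", "p_within_to_above",
             "p_below_to_within", "p_above_to_within"):
    e = est[name]
    truth = getattr(config.arm_control, name).base
    print(f"  {name:20} {e.estimate:.4f} +/- {e.se:.4f}  (truth {truth:.4f})")
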