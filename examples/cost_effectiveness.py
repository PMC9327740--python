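"""Lifetime cost-effectiveness of pharmacist-managed warfarin therapy.

Runs both arms of the nine-state Markov cohort model at the packaged base
case and prints the discounted per-patient totals, their increments and the
dominance verdict.
"""

from warfcea import classify_threshold, compute_icer, default_base_case, evaluate_arm

config = default_base_case()
intervention = evaluate_arm(config, "intervention")
control = evaluate_arm(config, "control")

for out in (intervention, control):
    print(
        f"{out.arm:>12}: {out.total_qaly:6.2f} QALYs, "
        f"{out.total_cost:8.2f} USD  "
        f"(undiscounted {out.undiscounted_qaly:.2f} / {out.undiscounted_cost:.2f}, "
        f"{out.life_years:.1f} life-years)"
    )

res = compute_icer(intervention, control)
print(f"\nincremental cost : {res.delta_cost:8.2f} USD")
print(f"incremental QALYs: {res.delta_qaly:8.3f}")
print(f"ICER             : {res.icer:8.2f} USD/QALY")
print(f"verdict          : {res.dominance}")
print(f"classification   : {classify_threshold(res, gdp_per_capita=3000.0)}")

# A negative ICER with positive incremental QALYs means the managed-therapy
# strategy both saves money and gains healthy life over standard care:
# dominance, so the ratio itself is not used for the classification.
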