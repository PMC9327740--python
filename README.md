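# warfcea

Cost-effectiveness modelling of pharmacist-managed warfarin therapy (PMWT)
for patients with mechanical mitral valve prostheses, plus the trial
endpoint machinery around it: a nine-state half-cycle-corrected Markov
cohort model, Rosendaal time-in-therapeutic-range (TTR) scoring, one-way
sensitivity analysis, and a synthetic INR-trajectory generator.

## The problem

Lifelong warfarin after mechanical mitral valve replacement demands tight
INR control (target 2.5–3.5). Time outside that range exposes patients to
thromboembolism (below range) and major bleeding (above range).
Pharmacist-managed dosing keeps patients in range more of the time than
standard care; the question for a payer is whether the better control is
worth it over a lifetime. This package answers that with a cohort
state-transition model and quantifies INR control itself with the Rosendaal
TTR statistic.

## The model

A cohort starts distributed over three no-event INR band states
(within / below / above range, per-arm initial proportions) and moves each
one-month cycle by a 9×9 transition matrix **P**:

* band ↔ band transitions differ by arm (PMWT vs standard care);
* below-range → thromboembolism (TE) and above-range → major bleeding at
  shared monthly hazards;
* event states (bleeding, TE, reoperation) carry recurrence, cross-event
  and death transitions, with residual mass flowing into recovery
  sub-states (post-TE, post-bleed/reoperation);
* recovery death is scaled by excess-mortality risk ratios (×2.25 post-TE,
  ×1.5 post-bleed/reoperation); death is absorbing.

Per cycle *t* the engine accrues, with trapezoidal half-cycle correction
(occupancy averaged over the cycle's endpoints) and monthly-compounded
annual discounting at rate *r*:

    QALY_t = Σ_s u_s · occ_t(s) · (1/12) · (1+r)^(−t/12)
    Cost_t = Σ_s c_s · occ_t(s) · (1+r)^(−t/12)

over a 480-cycle (40-year) lifetime horizon. Arms are compared by
incremental cost-effectiveness ratio ICER = ΔC/ΔE and dominance; WHO-CHOICE
thresholds (1×/3× GDP per capita per QALY) classify non-dominant results.

TTR is computed by the Rosendaal method: linear interpolation of INR
between visits, the in-range share of interpolated time, with NICE control
categories (<65% poor, 65–75%, >75%).

## Worked example

```python
from warfcea import compute_icer, default_base_case, evaluate_arm

config = default_base_case()
res = compute_icer(evaluate_arm(config, "intervention"),
                   evaluate_arm(config, "control"))
print(res.to_dict())
```

Running `python examples/cost_effectiveness.py` prints:

```
intervention:  20.60 QALYs,   501.34 USD  (undiscounted 37.34 / 991.60, 38.7 life-years)
     control:  18.80 QALYs,  1428.03 USD  (undiscounted 33.03 / 2712.16, 36.1 life-years)

incremental cost :  -926.69 USD
incremental QALYs:    1.798
ICER             :  -515.49 USD/QALY
verdict          : intervention-dominant
classification   : cost-saving
```

The managed-therapy arm gains 1.8 discounted QALYs and saves 927 USD per
patient over a lifetime: it dominates standard care, so it is cost-saving
and the negative ICER is reported but not used for classification. The
other scripts in `examples/` demonstrate the tornado sensitivity sweep, the
Rosendaal TTR scorer on hand-checkable series, and a synthetic two-arm
trial with parameter recovery.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the headline decision-model quantities from scratch — both
arms' lifetime discounted QALYs and costs at the packaged base case and
their increments — and writes them as JSON. The cohort engine is
deterministic; the seed is accepted for interface uniformity.

## Layout

* `warfcea.parameters` — validated parameter set (base/low/high triples),
  packaged base case, config file I/O, the sensitivity catalog
* `warfcea.markov` — transition matrices, cohort propagation, discounted
  outcome accumulation
* `warfcea.econ` — ICER/dominance, WHO-threshold classification, one-way
  sensitivity, retention-reduction scenario
* `warfcea.ttr` — Rosendaal TTR, control categories, cohort summaries
* `warfcea.cohort` — synthetic INR trajectories, transition-probability
  re-estimation, arm contrasts
* `warfcea.reporting` — pipeline functions writing CSV/JSON artifacts with
  run manifests
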