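# Methods

## State space and transition structure

The model tracks a closed cohort over nine mutually exclusive health
states: three no-event INR band states (within / below / above the 2.5–3.5
therapeutic range), three acute event states (major bleeding,
thromboembolism (TE), valve reoperation), two recovery sub-states and
absorbing death. The published description names eight states but counts
nine; this package resolves the ninth by splitting recovery into
*post-TE* and *post-bleed-or-reoperation* sub-states. That split gives the
two excess-death risk ratios (×2.25 after major TE, ×1.5 after major
bleeding/reoperation) a mechanistic home: each multiplies its sub-state's
monthly recovery death probability (0.00147), while the acute event
states' own death probabilities are used as published, unscaled. An
alternative reading (a separate model-entry state) was considered and not
implemented.

Row assembly, per arm:

| row | explicit exits | residual mass |
|---|---|---|
| within range | → below, → above (arm-specific) | stays |
| below range | → within (arm), → TE (0.0023, shared) | stays |
| above range | → within (arm), → bleeding (0.0115, shared) | stays |
| TE | → bleeding, reoperation, death; recurrent TE | → recovery (post-TE) |
| bleeding | → TE, reoperation, death; recurrent bleed | → recovery (post-bleed/reop) |
| reoperation | → TE, bleeding, death; recurrent reop | → recovery (post-bleed/reop) |
| recovery (each) | → TE, bleeding, reoperation; → death × risk ratio | stays |
| death | — | absorbing |

Recovery is quasi-absorbing: patients do not return to the INR band
states, but recurrent events flow back to the event states. The three INR
band states carry **no background mortality** — no such transition is
published, and the no-event closed form (below) is consistent with the
published intervention-arm total only under that assumption. A row whose
explicit exits exceed 1 raises an infeasibility error naming the row.

## Outcome accumulation

* **Cycle length** 1 month; **horizon** 480 cycles. "Lifetime" is
  quantified as 40 years: the trial cohort's mean age ≈46 carried to ≈86.
* **Half-cycle correction**: trapezoidal — cycle *t*'s effective occupancy
  is the mean of the state vectors at its start and end. The correction is
  named but not formalized in the source; trapezoidal averaging is the
  standard construction and is toggleable.
* **Discounting**: per-cycle factor (1+r)^(−t/12) anchored at cycle 0,
  i.e. monthly compounding of the annual rate (3.5% base for both costs
  and QALYs).
* **Utilities**: within-range utility 0.987 applied to *all three* band
  states (out-of-range INR is asymptomatic per se and no separate
  utilities are published); recovery utility 0.668 to both recovery
  sub-states; death 0.
* **Costs**: event costs (bleeding 2,777.78; TE 2,314.81; reoperation
  16,203.70 USD) are charged per cycle of event-state occupancy. Whether
  the original analysis charged per entry instead is unknowable from the
  publication; both conventions are implemented (`cost_timing=`), and with
  event-state stay probabilities ≤0.09 they differ by ~3%. Per-cycle is
  canonical. Costs are consumed already in USD; no currency conversion.

With all event hazards zeroed the cohort never leaves the band states and
the QALY total collapses to the geometric series
(u/12)·Σ_{t<N}(1+r)^(−t/12) ≈ 21.47 at u=0.987, r=0.035, N=480 — used as
an exact oracle in the tests.

## Incremental analysis and sensitivity

Increments are intervention minus control. Dominance (cheaper **and** more
effective) yields "cost-saving"; otherwise the ICER is placed against
WHO-CHOICE bands at 1× and 3× GDP per capita per QALY. GDP per capita is a
runtime input (examples use 3,000 USD as a plausible Egyptian figure); no
threshold constant is baked in.

One-way sensitivity sweeps all 44 ranged parameters (each to its published
low and high bound, others at base) and sorts by ICER span. Sensitivity
bounds may leave the probability simplex (the published within-range
initial proportion has high 1.0937); probabilities are clamped to [0,1] at
matrix-build time and initial proportions renormalized, each with a log
record. An infeasible extreme flags its tornado entry rather than aborting
the sweep.

The retention-reduction scenario cuts the intervention arm's monthly
within-range *stay* probability by a relative fraction (canonically 10%)
and redistributes the freed mass to the below/above exits proportionally
to their base values — the mechanism behind the published flip claim is
unstated, and this is the ledgered canonical reading; absolute-cut and
single-exit variants were examined and behave similarly or degenerately.

## Rosendaal TTR

INR is interpolated linearly in calendar time between successive
measurements; each segment's time is apportioned to below/within/above
analytically from the boundary crossing points. Range boundaries are
inclusive (the common Rosendaal convention). Percentages are taken over
the first-to-last-measurement span; time before the first or after the
last visit is not counted. At least two measurements are required. A
configurable maximum between-visit gap can exclude long segments from both
numerator and denominator; it is **off** by default (the trial set no
cap). Control categories: <65% poor (strict), 65–75% inclusive, >75%
good (strict). Cohort summaries use medians and linear-interpolation
quantiles for the IQR.

## Synthetic cohorts

The generator emulates the trial's follow-up design: 12 monthly visits
plus baseline, visit days on a 30-day grid with ±3-day uniform integer
jitter (never enough to reorder), the patient's INR band evolving by the
arm's 3-band chain (stay = remainder) from the arm's initial proportions,
and the observed INR drawn uniformly within the band's interval (tails
capped at 1.2 and 6.0, clinically plausible display bounds; no within-band
distribution is published). Band state is sampled at visit times only,
matching the cycle-synchronous structure of the cohort model the
probabilities feed.

What a green test establishes: band-occupancy structure, seed-determinism,
and recoverability of the generating transition probabilities (MLE counts
/ exposures within 3 binomial SEs at n=5,000). What it does not: real INR
kinetics within a month, dose–response, covariate effects, or the trial's
true visit-interval and measurement distributions.

## Numerical choices

* Matrix rows validated to sum to 1 within 1e-12; trace mass conservation
  within 1e-9 over 480 cycles; death column non-decreasing.
* Propagation is iterated vector–matrix multiplication; tests cross-check
  against `numpy` matrix powers to 1e-12 on random stochastic matrices.
* TTR crossing points computed in closed form; tests cross-check against a
  ~2·10⁵-cell midpoint-grid integration within 0.1 percentage points.
* The engine contains no randomness; sensitivity and scenario outputs are
  byte-reproducible. Cohort simulation is deterministic given its seed.

## Known limitations

* **The published per-arm totals are not recoverable from the published
  inputs.** The frozen canonical configuration (480 cycles, half-cycle
  correction, per-cycle costs, risk ratios applied) yields 20.60 QALYs /
  501.34 USD (intervention) and 18.80 QALYs / 1,428.03 USD (control)
  against published 21.53 / 436.38 and 10.43 / 1,242.25. The control QALY
  gap is structural, not a tuning issue: 10.43 discounted QALYs would
  require losing ≈52% of the discounted no-event lifetime (21.47), while
  the published event hazards remove at most a few percent — control
  cumulative mortality reaches only ≈25% by cycle 480, and event/recovery
  utility decrements are small. Conversely the published intervention
  total (21.53) exceeds the zero-event upper bound at 480 cycles. The
  qualitative conclusions — dominance at base case, robustness of
  cost-effectiveness across all one-way extremes — do reproduce. The
  acceptance tests assert the published totals unweakened and fail
  honestly; the corresponding reproduction tolerances were not relaxed.
* Consequently the published retention-reduction flip (dominance lost at a
  10% cut) does not occur here: the scenario shrinks but does not reverse
  the cost saving under any examined reading.
* Cohort (Markov) engine only: no microsimulation, no age-dependent
  background mortality, no probabilistic sensitivity analysis, no
  acceptability curves — all outside the analysis being reproduced.
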