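"""Synthetic patient-level INR trajectories with the model's band structure.

No patient-level trial data are published, so this module generates
stand-in cohorts whose statistical structure matches what the analysis
assumes: each patient's INR band (below / within / above the therapeutic
range) starts from the arm's initial proportions and evolves monthly by the
arm's three-band transition chain; visits land on a ~30-day grid with small
uniform jitter; the observed INR is drawn uniformly within the current
band's interval. Hidden band sequences are retained so that transition
probabilities can be re-estimated and checked against their generating
values (a parameter-recovery harness for the published inputs).

All randomness flows from a single integer seed; identical spec + seed
yields bit-identical trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .parameters import ArmINRDynamics
from .ttr import INRSeries, cohort_ttr_summary, rosendaal_ttr

BANDS = ("within", "below", "above")

#: Display intervals per band; tails capped at clinically plausible 1.2 / 6.0.
DEFAULT_BAND_INTERVALS: dict[str, tuple[float, float]] = {
    "below": (1.2, 2.5),
    "within": (2.5, 3.5),
    "above": (3.5, 6.0),
}


@dataclass(frozen=True)
class SimulationSpec:
    """What to simulate: arm dynamics, cohort size, follow-up and seed."""

    arm: ArmINRDynamics
    n_patients: int
    n_months: int = 12
    visit_jitter_days: int = 3
    band_intervals: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BAND_INTERVALS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.n_months < 1:
            raise ValueError("n_months must be >= 1")
        if self.visit_jitter_days < 0:
            raise ValueError("visit_jitter_days must be >= 0")
        if 2 * self.visit_jitter_days >= 30:
            raise ValueError("jitter must be < 15 days so visits never reorder")
        if set(self.band_intervals) != set(BANDS):
            raise ValueError(f"band_intervals must cover exactly {BANDS}")
        for band, (lo, hi) in self.band_intervals.items():
            if not (0 < lo < hi):
                raise ValueError(f"band {band}: invalid interval ({lo}, {hi})")

    def to_dict(self) -> dict:
        return {
            "arm": self.arm.model_dump(),
            "n_patients": self.n_patients,
            "n_months": self.n_months,
            "visit_jitter_days": self.visit_jitter_days,
            "band_intervals": {b: list(v) for b, v in self.band_intervals.items()},
            "seed": self.seed,
        }


def band_transition_matrix(arm: ArmINRDynamics) -> np.ndarray:
    """3x3 monthly chain over (within, below, above); stay = remainder."""
    wb = arm.p_within_to_below.base
    wa = arm.p_within_to_above.base
    bw = arm.p_below_to_within.base
    aw = arm.p_above_to_within.base
    return np.array(
        [
            [1.0 - wb - wa, wb, wa],
            [bw, 1.0 - bw, 0.0],
            [aw, 0.0, 1.0 - aw],
        ]
    )


def band_initial_distribution(arm: ArmINRDynamics) -> np.ndarray:
    p = np.array(arm.initial_proportions())
    return p / p.sum()


@dataclass(frozen=True)
class TrajectorySet:
    """Simulated series plus the hidden band sequences behind them."""

    series: list[INRSeries]
    band_sequences: list[np.ndarray]
    spec: SimulationSpec

    def __len__(self) -> int:
        return len(self.series)

    def to_dataframe(self) -> pd.DataFrame:
        frames = []
        for s, bands in zip(self.series, self.band_sequences):
            frames.append(
                pd.DataFrame(
                    {
                        "patient_id": s.patient_id,
                        "day": s.days.astype(int),
                        "inr": s.inr,
                        "band": [BANDS[b] for b in bands],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def to_csv(self, path: str | Path, *, include_bands: bool = False) -> None:
        df = self.to_dataframe()
        if not include_bands:
            df = df.drop(columns="band")
        df.to_csv(path, index=False)


def simulate_cohort(spec: SimulationSpec) -> TrajectorySet:
    """Draw one synthetic cohort of INR trajectories.

    Each patient gets ``n_months + 1`` visits (month 0 at day 0 exactly,
    later visits at 30*t plus uniform integer jitter). The band state is
    sampled at visit times only, mirroring the cycle-synchronous structure
    of the cohort model the transition probabilities feed.
    """
    rng = np.random.default_rng(spec.seed)
    chain = band_transition_matrix(spec.arm)
    init = band_initial_distribution(spec.arm)
    intervals = np.array([spec.band_intervals[b] for b in BANDS])
    n_visits = spec.n_months + 1

    series: list[INRSeries] = []
    band_sequences: list[np.ndarray] = []
    for i in range(spec.n_patients):
        bands = np.empty(n_visits, dtype=np.int64)
        bands[0] = rng.choice(3, p=init)
        for t in range(1, n_visits):
            bands[t] = rng.choice(3, p=chain[bands[t - 1]])
        days = 30 * np.arange(n_visits)
        if spec.visit_jitter_days:
            jitter = rng.integers(
                -spec.visit_jitter_days, spec.visit_jitter_days + 1, size=n_visits
            )
            jitter[0] = 0
            days = days + jitter
        lo, hi = intervals[bands, 0], intervals[bands, 1]
        inr = rng.uniform(lo, hi)
        series.append(
            INRSeries(patient_id=f"pt{i:05d}", days=days.astype(float), inr=inr)
        )
        band_sequences.append(bands)
    return TrajectorySet(series=series, band_sequences=band_sequences, spec=spec)


@dataclass(frozen=True)
class TransitionEstimate:
    """MLE of one transition probability with its binomial standard error."""

    estimate: float | None
    se: float | None
    n_exposures: int

    @property
    def available(self) -> bool:
        return self.estimate is not None


def _infer_bands(series: INRSeries, intervals: dict[str, tuple[float, float]]
                 ) -> np.ndarray:
    low = intervals["within"][0]
    high = intervals["within"][1]
    return np.where(series.inr < low, 1, np.where(series.inr > high, 2, 0))


def estimate_transition_probs(
    trajset: TrajectorySet,
    *,
    source: Literal["hidden", "observed"] = "hidden",
) -> dict[str, TransitionEstimate]:
    """Re-estimate the arm's INR dynamics from simulated trajectories.

    Estimates are observed transition counts over source-band exposures
    (the discrete-chain maximum-likelihood estimator), with binomial
    standard errors sqrt(p(1-p)/n). ``source="observed"`` infers bands from
    the recorded INR values instead of the hidden states (identical here,
    since the band intervals partition the INR axis). Initial proportions
    are estimated from first visits. A band never visited yields
    unavailable estimates for its outgoing transitions.
    """
    if source == "hidden":
        seqs = trajset.band_sequences
    else:
        seqs = [
            _infer_bands(s, trajset.spec.band_intervals) for s in trajset.series
        ]
    counts = np.zeros((3, 3), dtype=np.int64)
    first = np.zeros(3, dtype=np.int64)
    for bands in seqs:
        first[bands[0]] += 1
        np.add.at(counts, (bands[:-1], bands[1:]), 1)
    exposures = counts.sum(axis=1)

    def est(src: int, dst: int) -> TransitionEstimate:
        n = int(exposures[src])
        if n == 0:
            return TransitionEstimate(estimate=None, se=None, n_exposures=0)
        p = counts[src, dst] / n
        return TransitionEstimate(
            estimate=float(p), se=float(np.sqrt(p * (1 - p) / n)), n_exposures=n
        )

    n_pat = len(trajset)

    def init_est(band: int) -> TransitionEstimate:
        p = first[band] / n_pat
        return TransitionEstimate(
            estimate=float(p),
            se=float(np.sqrt(p * (1 - p) / n_pat)),
            n_exposures=n_pat,
        )

    return {
        "initial_within": init_est(0),
        "initial_below": init_est(1),
        "initial_above": init_est(2),
        "p_within_to_below": est(0, 1),
        "p_within_to_above": est(0, 2),
        "p_below_to_within": est(1, 0),
        "p_above_to_within": est(2, 0),
    }


@dataclass(frozen=True)
class ArmContrast:
    """Arm-level TTR comparison between two simulated cohorts."""

    intervention_median: float
    control_median: float
    intervention_category_percent: dict[str, float]
    control_category_percent: dict[str, float]
    intervention_exceeds_control: bool

    def to_dict(self) -> dict:
        return {
            "intervention_median": self.intervention_median,
            "control_median": self.control_median,
            "intervention_category_percent": dict(
                self.intervention_category_percent
            ),
            "control_category_percent": dict(self.control_category_percent),
            "intervention_exceeds_control": self.intervention_exceeds_control,
        }


def arm_contrast_check(
    intervention: TrajectorySet,
    control: TrajectorySet,
    range_low: float = 2.5,
    range_high: float = 3.5,
) -> ArmContrast:
    """Score both simulated arms with Rosendaal TTR and compare medians."""
    summaries = []
    for trajset in (intervention, control):
        results = [
            rosendaal_ttr(s, range_low, range_high) for s in trajset.series
        ]
        summaries.append(cohort_ttr_summary(results))
    si, sc = summaries
    return ArmContrast(
        intervention_median=si.median,
        control_median=sc.median,
        intervention_category_percent=si.category_percent,
        control_category_percent=sc.category_percent,
        intervention_exceeds_control=si.median > sc.median,
    )
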