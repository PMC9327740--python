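"""Incremental cost-effectiveness analysis and one-way sensitivity sweeps.

Increments are always intervention minus control. A strategy "dominates"
when it is both cheaper and more effective; dominance, not the (then
negative) ICER, drives the cost-effectiveness classification. Threshold
labels follow the WHO-CHOICE convention: an ICER below 1x GDP per capita
per QALY is very cost-effective, below 3x is cost-effective. GDP per capita
is a caller-supplied input, never a built-in constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Literal

import pandas as pd

from .errors import ClassificationError, InfeasibleParameterError
from .markov import ArmOutcome, evaluate_arm
from .parameters import ModelConfig, parameter_catalog, set_parameter

Dominance = Literal["intervention-dominant", "control-dominant", "trade-off"]

CELabel = Literal[
    "cost-saving", "very cost-effective", "cost-effective", "not cost-effective"
]


@dataclass(frozen=True)
class IncrementalResult:
    """Pairwise comparison of the two arms (intervention minus control)."""

    delta_cost: float
    delta_qaly: float
    icer: float | None
    dominance: Dominance

    def to_dict(self) -> dict:
        return {
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "icer": self.icer,
            "dominance": self.dominance,
        }


def compute_icer(intervention: ArmOutcome, control: ArmOutcome) -> IncrementalResult:
    """Incremental cost, incremental QALYs, their ratio and the dominance label.

    The ICER is undefined (``None``) when the QALY difference is zero; the
    dominance label then follows the cost sign alone.
    """
    dc = intervention.total_cost - control.total_cost
    dq = intervention.total_qaly - control.total_qaly
    if dq == 0.0:
        icer = None
        if dc < 0:
            dominance: Dominance = "intervention-dominant"
        elif dc > 0:
            dominance = "control-dominant"
        else:
            dominance = "trade-off"
    else:
        icer = dc / dq
        if dc < 0 and dq > 0:
            dominance = "intervention-dominant"
        elif dc > 0 and dq < 0:
            dominance = "control-dominant"
        else:
            dominance = "trade-off"
    return IncrementalResult(delta_cost=dc, delta_qaly=dq, icer=icer,
                             dominance=dominance)


def classify_threshold(result: IncrementalResult, gdp_per_capita: float) -> CELabel:
    """WHO-CHOICE willingness-to-pay classification of an incremental result.

    A dominant intervention is cost-saving regardless of the numeric ICER.
    Otherwise the ICER is compared with 1x / 3x GDP per capita per QALY.
    """
    if gdp_per_capita <= 0:
        raise ValueError("gdp_per_capita must be positive")
    if result.dominance == "intervention-dominant":
        return "cost-saving"
    if result.dominance == "control-dominant":
        return "not cost-effective"
    if result.icer is None:
        raise ClassificationError(
            "ICER undefined (zero QALY difference) and result not dominant"
        )
    if 0 <= result.icer <= gdp_per_capita:
        return "very cost-effective"
    if result.icer <= 3 * gdp_per_capita:
        return "cost-effective"
    return "not cost-effective"


@dataclass(frozen=True)
class TornadoEntry:
    """One-way sensitivity result for a single parameter."""

    parameter: str
    icer_at_low: float | None
    icer_at_high: float | None
    span: float
    dominance_at_low: Dominance | None
    dominance_at_high: Dominance | None
    error: str | None = None

    def to_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "icer_at_low": self.icer_at_low,
            "icer_at_high": self.icer_at_high,
            "span": self.span,
            "dominance_at_low": self.dominance_at_low,
            "dominance_at_high": self.dominance_at_high,
            "error": self.error,
        }


EvaluateFn = Callable[[ModelConfig], IncrementalResult]


def _default_evaluate(config: ModelConfig) -> IncrementalResult:
    return compute_icer(
        evaluate_arm(config, "intervention"), evaluate_arm(config, "control")
    )


def one_way_sensitivity(
    config: ModelConfig, evaluate: EvaluateFn | None = None
) -> list[TornadoEntry]:
    """Sweep every catalog parameter to its low and high bound, one at a time.

    All other parameters stay at base. Returns one entry per parameter,
    sorted by descending ICER span (the tornado ordering); an infeasible
    extreme flags the entry rather than aborting the sweep.
    """
    evaluate = evaluate or _default_evaluate
    entries: list[TornadoEntry] = []
    for name, pv in parameter_catalog(config):
        results: dict[str, IncrementalResult | None] = {}
        err = None
        for bound in ("low", "high"):
            try:
                results[bound] = evaluate(set_parameter(config, name, pv.at(bound)))
            except InfeasibleParameterError as exc:
                results[bound] = None
                err = str(exc)
        lo, hi = results["low"], results["high"]
        icer_lo = lo.icer if lo else None
        icer_hi = hi.icer if hi else None
        if icer_lo is not None and icer_hi is not None:
            span = abs(icer_hi - icer_lo)
        else:
            span = math.nan
        entries.append(
            TornadoEntry(
                parameter=name,
                icer_at_low=icer_lo,
                icer_at_high=icer_hi,
                span=span,
                dominance_at_low=lo.dominance if lo else None,
                dominance_at_high=hi.dominance if hi else None,
                error=err,
            )
        )
    entries.sort(key=lambda e: -1.0 if math.isnan(e.span) else e.span, reverse=True)
    return entries


def tornado_dataframe(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame([e.to_dict() for e in entries])


def retention_reduction_scenario(
    config: ModelConfig, fraction: float
) -> IncrementalResult:
    """Scenario: the intervention arm retains patients in range less well.

    The intervention arm's monthly probability of *remaining* within the
    therapeutic range is cut by the given relative fraction; the freed
    probability mass is redistributed to the below-/above-range exits in
    proportion to their base values. Both arms are then re-run.
    """
    if not (0 <= fraction < 1):
        raise ValueError("fraction must be in [0, 1)")
    arm = config.arm_intervention
    p_wb = arm.p_within_to_below.base
    p_wa = arm.p_within_to_above.base
    stay = 1.0 - p_wb - p_wa
    freed = stay * fraction
    exits = p_wb + p_wa
    if exits <= 0:
        raise ValueError("within-range row has no exits to absorb the freed mass")
    new_config = set_parameter(
        config, "intervention.p_within_to_below", p_wb + freed * p_wb / exits
    )
    new_config = set_parameter(
        new_config, "intervention.p_within_to_above", p_wa + freed * p_wa / exits
    )
    return _default_evaluate(new_config)
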