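"""Canonical health-state space of the anticoagulation Markov cohort model.

Nine mutually exclusive states. The three no-event states partition patients
by INR band (therapeutic target 2.5-3.5 for mechanical mitral valve
prostheses). Event states are major bleeding, thromboembolism (TE) and valve
reoperation. Recovery is split into two sub-states so that the excess-death
risk ratios after a major TE (x2.25) versus a major bleed or reoperation
(x1.5) each have a well-defined home. Death is absorbing.
"""

from __future__ import annotations

from enum import Enum


class HealthState(str, Enum):
    WITHIN_RANGE = "within_range"
    BELOW_RANGE = "below_range"
    ABOVE_RANGE = "above_range"
    BLEEDING = "bleeding"
    TE = "te"
    REOPERATION = "reoperation"
    RECOVERY_POST_TE = "recovery_post_te"
    RECOVERY_POST_BLEED_OR_REOP = "recovery_post_bleed_or_reop"
    DEATH = "death"


#: Canonical state ordering used for every matrix / trace column.
STATE_ORDER: tuple[HealthState, ...] = tuple(HealthState)

#: Column index of each state in the canonical ordering.
STATE_INDEX: dict[HealthState, int] = {s: i for i, s in enumerate(STATE_ORDER)}

N_STATES: int = len(STATE_ORDER)

#: The three no-event INR band states, in canonical order.
INR_STATES: tuple[HealthState, ...] = (
    HealthState.WITHIN_RANGE,
    HealthState.BELOW_RANGE,
    HealthState.ABOVE_RANGE,
)

#: Acute event states that carry a per-cycle cost.
EVENT_STATES: tuple[HealthState, ...] = (
    HealthState.BLEEDING,
    HealthState.TE,
    HealthState.REOPERATION,
)
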