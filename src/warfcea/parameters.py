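"""Model parameter set: loading, validation and the packaged base case.

Every model input carries a ``ParameterValue`` triple (base, low, high); the
low/high bounds delimit the one-way sensitivity analysis. The packaged base
case holds the complete published input set for the two-arm comparison of
pharmacist-managed warfarin therapy versus standard care: per-arm initial INR
band proportions and monthly INR band transition probabilities, shared
warfarin-event dynamics, health-state utilities, event costs in USD, and
discounting/horizon settings.

Sensitivity bounds may exceed 1 for a probability (e.g. the intervention
arm's initial within-range proportion has high 1.0937, a published range
artefact); such values are kept verbatim here and clamped to [0, 1] only at
matrix-build time, with a log record.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterator, Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import ConfigError

logger = logging.getLogger(__name__)

_FIXTURE_NAME = "base_case_table1.json"

#: Number of published parameter rows that carry a low/high range.
N_RANGED_PARAMETERS = 44


class ParameterValue(BaseModel):
    """A model input with its base-case value and sensitivity range."""

    model_config = ConfigDict(frozen=True)

    base: float
    low: float
    high: float

    @model_validator(mode="after")
    def _ordered(self) -> "ParameterValue":
        if not (self.low <= self.base <= self.high):
            raise ValueError(
                f"range must satisfy low <= base <= high, got "
                f"({self.low}, {self.base}, {self.high})"
            )
        return self

    def at(self, which: Literal["base", "low", "high"]) -> float:
        return getattr(self, which)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.base, self.low, self.high)


def _check_prob(name: str, pv: ParameterValue) -> None:
    if not (0.0 <= pv.base <= 1.0):
        raise ValueError(f"{name}: base probability {pv.base} outside [0, 1]")
    if pv.low < 0.0:
        raise ValueError(f"{name}: low bound {pv.low} below 0")


class ArmINRDynamics(BaseModel):
    """Initial INR band proportions and monthly band transitions for one arm."""

    model_config = ConfigDict(frozen=True)

    initial_within: ParameterValue
    initial_below: ParameterValue
    initial_above: ParameterValue
    p_within_to_below: ParameterValue
    p_within_to_above: ParameterValue
    p_below_to_within: ParameterValue
    p_above_to_within: ParameterValue

    @model_validator(mode="after")
    def _valid(self) -> "ArmINRDynamics":
        total = (
            self.initial_within.base
            + self.initial_below.base
            + self.initial_above.base
        )
        # The published sensitivity bounds push single proportions off the
        # simplex (e.g. within-range high 1.0937); such configs are accepted
        # and renormalized at matrix-build time. Gross inconsistency is still
        # rejected.
        if abs(total - 1.0) > 0.15:
            raise ValueError(
                f"initial proportions must sum to ~1, got {total!r}"
            )
        for name in (
            "p_within_to_below",
            "p_within_to_above",
            "p_below_to_within",
            "p_above_to_within",
        ):
            _check_prob(name, getattr(self, name))
        exits = self.p_within_to_below.base + self.p_within_to_above.base
        if exits > 1.0:
            raise ValueError(
                f"within_range row: exit probabilities sum to {exits} > 1"
            )
        return self

    def initial_proportions(self) -> tuple[float, float, float]:
        return (
            self.initial_within.base,
            self.initial_below.base,
            self.initial_above.base,
        )


class EventDynamics(BaseModel):
    """Arm-independent event-state dynamics (monthly probabilities).

    ``rr_death_major_te`` / ``rr_death_major_bleeding`` are unitless risk
    ratios multiplying the post-recovery death probability, reflecting excess
    mortality after a major thromboembolism or a major bleed/reoperation.
    """

    model_config = ConfigDict(frozen=True)

    p_above_to_bleeding: ParameterValue
    p_below_to_te: ParameterValue
    te_to_bleeding: ParameterValue
    te_to_reoperation: ParameterValue
    te_to_death: ParameterValue
    te_to_te: ParameterValue
    bleeding_to_te: ParameterValue
    bleeding_to_reoperation: ParameterValue
    bleeding_to_death: ParameterValue
    bleeding_to_bleeding: ParameterValue
    reop_to_te: ParameterValue
    reop_to_bleeding: ParameterValue
    reop_to_death: ParameterValue
    reop_to_reop: ParameterValue
    recovery_to_te: ParameterValue
    recovery_to_bleeding: ParameterValue
    recovery_to_reoperation: ParameterValue
    recovery_to_death: ParameterValue
    rr_death_major_te: ParameterValue
    rr_death_major_bleeding: ParameterValue

    @model_validator(mode="after")
    def _valid(self) -> "EventDynamics":
        for name in type(self).model_fields:
            pv = getattr(self, name)
            if name.startswith("rr_"):
                if pv.base < 1.0:
                    raise ValueError(f"{name}: risk ratio {pv.base} < 1")
            else:
                _check_prob(name, pv)
        for row, names in {
            "te": ("te_to_bleeding", "te_to_reoperation", "te_to_death", "te_to_te"),
            "bleeding": (
                "bleeding_to_te",
                "bleeding_to_reoperation",
                "bleeding_to_death",
                "bleeding_to_bleeding",
            ),
            "reoperation": (
                "reop_to_te",
                "reop_to_bleeding",
                "reop_to_death",
                "reop_to_reop",
            ),
        }.items():
            s = sum(getattr(self, n).base for n in names)
            if s > 1.0:
                raise ValueError(f"{row} row: outgoing probabilities sum to {s} > 1")
        return self


class UtilitySet(BaseModel):
    """Health-state utility weights in [0, 1]; death is fixed at 0.

    ``u_within_range`` is applied to all three no-event INR band states:
    out-of-range INR is asymptomatic per se, and no separate out-of-range
    utilities are published.
    """

    model_config = ConfigDict(frozen=True)

    u_within_range: ParameterValue
    u_bleeding: ParameterValue
    u_te: ParameterValue
    u_reoperation: ParameterValue
    u_recovery: ParameterValue

    u_death: float = 0.0

    @model_validator(mode="after")
    def _valid(self) -> "UtilitySet":
        for name in (
            "u_within_range",
            "u_bleeding",
            "u_te",
            "u_reoperation",
            "u_recovery",
        ):
            pv = getattr(self, name)
            if not (0.0 <= pv.base <= 1.0):
                raise ValueError(f"{name}: utility {pv.base} outside [0, 1]")
        if self.u_death != 0.0:
            raise ValueError("u_death is fixed at 0")
        return self


class CostSet(BaseModel):
    """Event costs in USD, charged per cycle of event-state occupancy."""

    model_config = ConfigDict(frozen=True)

    c_bleeding: ParameterValue
    c_te: ParameterValue
    c_reoperation: ParameterValue

    @model_validator(mode="after")
    def _valid(self) -> "CostSet":
        for name in type(self).model_fields:
            if getattr(self, name).low < 0:
                raise ValueError(f"{name}: cost must be >= 0")
        return self


class DiscountHorizonSpec(BaseModel):
    """Discount rates (annual), cycle length and horizon.

    The default 480 one-month cycles quantifies the lifetime horizon: 40
    years from the trial cohort's mean age of ~46 reaches ~86 years.
    """

    model_config = ConfigDict(frozen=True)

    annual_discount_cost: ParameterValue
    annual_discount_qaly: ParameterValue
    cycle_length_months: int = 1
    horizon_cycles: int = Field(default=480, ge=1)
    half_cycle_correction: bool = True

    @model_validator(mode="after")
    def _valid(self) -> "DiscountHorizonSpec":
        for name in ("annual_discount_cost", "annual_discount_qaly"):
            pv = getattr(self, name)
            if not (0.0 <= pv.base < 1.0):
                raise ValueError(f"{name}: discount rate {pv.base} outside [0, 1)")
        if self.cycle_length_months < 1:
            raise ValueError("cycle_length_months must be >= 1")
        return self


class ModelConfig(BaseModel):
    """Complete, validated input set for the two-arm cohort model."""

    model_config = ConfigDict(frozen=True)

    arm_intervention: ArmINRDynamics
    arm_control: ArmINRDynamics
    events: EventDynamics
    utilities: UtilitySet
    costs: CostSet
    discount_horizon: DiscountHorizonSpec
    inr_range_low: float = 2.5
    inr_range_high: float = 3.5

    @model_validator(mode="after")
    def _valid(self) -> "ModelConfig":
        if not (0 < self.inr_range_low < self.inr_range_high):
            raise ValueError("require 0 < inr_range_low < inr_range_high")
        for arm_name in ("arm_intervention", "arm_control"):
            arm = getattr(self, arm_name)
            below = arm.p_below_to_within.base + self.events.p_below_to_te.base
            if below > 1.0:
                raise ValueError(
                    f"{arm_name} below_range row: outgoing probabilities "
                    f"sum to {below} > 1"
                )
            above = arm.p_above_to_within.base + self.events.p_above_to_bleeding.base
            if above > 1.0:
                raise ValueError(
                    f"{arm_name} above_range row: outgoing probabilities "
                    f"sum to {above} > 1"
                )
        return self

    def arm(self, which: str) -> ArmINRDynamics:
        """Return one arm's INR dynamics by name.

        Accepts ``"intervention"`` or ``"control"``.
        """
        if which == "intervention":
            return self.arm_intervention
        if which == "control":
            return self.arm_control
        raise ValueError(f"unknown arm {which!r}")


def _fixture_path() -> Path:
    return Path(__file__).parent / "data" / _FIXTURE_NAME


def default_base_case() -> ModelConfig:
    """Return the packaged base-case configuration (all published inputs)."""
    with open(_fixture_path(), encoding="utf-8") as fh:
        return ModelConfig.model_validate(json.load(fh))


def _deep_merge(base: dict, override: dict, path: str, missing: list[str]) -> dict:
    merged = {}
    for key, base_val in base.items():
        here = f"{path}.{key}" if path else key
        if key not in override:
            # leaf sections absent from the user file fall back wholesale
            missing.append(here)
            merged[key] = base_val
        elif isinstance(base_val, dict) and isinstance(override[key], dict):
            merged[key] = _deep_merge(base_val, override[key], here, missing)
        else:
            merged[key] = override[key]
    for key in override:
        if key not in base:
            raise ConfigError(f"unknown config field {path + '.' if path else ''}{key}")
    return merged


def load_config(path: str | Path) -> ModelConfig:
    """Load a JSON or YAML configuration file.

    Fields absent from the file fall back to the packaged base case, with a
    logged warning naming each fallback. Validation failures raise
    :class:`~warfcea.errors.ConfigError` naming the offending field or
    state row.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text(encoding="utf-8")
    try:
        if path.suffix.lower() in (".yaml", ".yml"):
            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")

    with open(_fixture_path(), encoding="utf-8") as fh:
        defaults = json.load(fh)
    missing: list[str] = []
    merged = _deep_merge(defaults, raw, "", missing)
    if missing:
        logger.warning(
            "config %s: %d field(s) missing, using base-case values: %s",
            path,
            len(missing),
            ", ".join(missing),
        )
    try:
        return ModelConfig.model_validate(merged)
    except ValueError as exc:
        raise ConfigError(f"invalid config {path}: {exc}") from exc


def save_config(config: ModelConfig, path: str | Path) -> None:
    """Serialize a configuration to JSON or YAML (by file suffix)."""
    path = Path(path)
    data = config.model_dump()
    with open(path, "w", encoding="utf-8") as fh:
        if path.suffix.lower() in (".yaml", ".yml"):
            yaml.safe_dump(data, fh, sort_keys=False)
        else:
            json.dump(data, fh, indent=2)


def _catalog_entries(config: ModelConfig) -> Iterator[tuple[str, ParameterValue]]:
    for arm_key, prefix in (
        ("arm_intervention", "intervention"),
        ("arm_control", "control"),
    ):
        arm = getattr(config, arm_key)
        for name in ArmINRDynamics.model_fields:
            yield f"{prefix}.{name}", getattr(arm, name)
    for name in EventDynamics.model_fields:
        yield f"events.{name}", getattr(config.events, name)
    for name in (
        "u_within_range",
        "u_bleeding",
        "u_te",
        "u_reoperation",
        "u_recovery",
    ):
        yield f"utilities.{name}", getattr(config.utilities, name)
    for name in CostSet.model_fields:
        yield f"costs.{name}", getattr(config.costs, name)
    yield "discount_rate_cost", config.discount_horizon.annual_discount_cost
    yield "discount_rate_qaly", config.discount_horizon.annual_discount_qaly


def parameter_catalog(config: ModelConfig) -> list[tuple[str, ParameterValue]]:
    """Flat, stably named enumeration of every ranged parameter.

    This is the parameter space swept by the one-way sensitivity analysis:
    each entry carries its (base, low, high) triple.
    """
    return list(_catalog_entries(config))


_SPECIAL_PATHS = {
    "discount_rate_cost": ("discount_horizon", "annual_discount_cost"),
    "discount_rate_qaly": ("discount_horizon", "annual_discount_qaly"),
}

_SECTION_KEYS = {
    "intervention": "arm_intervention",
    "control": "arm_control",
    "events": "events",
    "utilities": "utilities",
    "costs": "costs",
}


def set_parameter(config: ModelConfig, name: str, value: float) -> ModelConfig:
    """Return a new config with one catalog parameter's base value replaced.

    ``name`` uses :func:`parameter_catalog` naming. The low/high range of the
    modified parameter is widened if needed so the triple stays ordered.
    """
    data = config.model_dump()
    if name in _SPECIAL_PATHS:
        section, field = _SPECIAL_PATHS[name]
    else:
        try:
            prefix, field = name.split(".", 1)
            section = _SECTION_KEYS[prefix]
        except (ValueError, KeyError):
            raise KeyError(f"unknown parameter name {name!r}") from None
    if field not in data[section]:
        raise KeyError(f"unknown parameter name {name!r}")
    pv = data[section][field]
    data[section][field] = {
        "base": value,
        "low": min(value, pv["low"]),
        "high": max(value, pv["high"]),
    }
    return ModelConfig.model_validate(data)
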