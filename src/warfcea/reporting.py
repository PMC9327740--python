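"""Pipeline entry points: run a stage end-to-end and write its artifacts.

Each ``run_*`` function is the library-level equivalent of a command: it
takes file paths or plain values, executes the corresponding analysis
stage, writes CSV/JSON outputs plus a run manifest into the output
directory, and returns the in-memory results. Reruns with identical inputs
reproduce identical numerical outputs (only the manifest timestamp
differs). Monetary values are written at full precision in JSON; rounding
to 2 decimals happens only in log messages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Literal

from . import __version__
from .cohort import SimulationSpec, simulate_cohort
from .econ import (
    classify_threshold,
    compute_icer,
    one_way_sensitivity,
    retention_reduction_scenario,
    tornado_dataframe,
)
from .markov import evaluate_arm
from .parameters import ModelConfig, default_base_case, load_config
from .ttr import (
    cohort_ttr_summary,
    read_inr_csv,
    results_dataframe,
    rosendaal_ttr,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunManifest:
    """Provenance record written alongside every output set."""

    command: str
    config_hash: str
    overrides: dict
    seed: int | None
    version: str
    timestamp: str


def _config_hash(config: ModelConfig) -> str:
    blob = json.dumps(config.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _write_manifest(
    out_dir: Path,
    command: str,
    config: ModelConfig | None,
    overrides: dict,
    seed: int | None = None,
) -> RunManifest:
    manifest = RunManifest(
        command=command,
        config_hash=_config_hash(config) if config else "",
        overrides=overrides,
        seed=seed,
        version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(asdict(manifest), fh, indent=2)
    return manifest


def _resolve_config(config: ModelConfig | str | Path | None) -> ModelConfig:
    if config is None:
        return default_base_case()
    if isinstance(config, ModelConfig):
        return config
    return load_config(config)


def _write_json(path: Path, payload: dict) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)


def run_model(
    config: ModelConfig | str | Path | None = None,
    out_dir: str | Path = ".",
    *,
    horizon_cycles: int | None = None,
    half_cycle_correction: bool | None = None,
    cost_timing: Literal["per_cycle", "per_entry"] = "per_cycle",
) -> dict:
    """Run both arms of the cohort model and write traces + results.

    Writes ``trace_intervention.csv`` / ``trace_control.csv`` (one row per
    cycle, canonical state columns), ``results.json`` (per-arm totals,
    increments, ICER, dominance) and ``manifest.json``.
    """
    cfg = _resolve_config(config)
    overrides: dict = {"cost_timing": cost_timing}
    updates: dict = {}
    if horizon_cycles is not None:
        updates["horizon_cycles"] = horizon_cycles
        overrides["horizon_cycles"] = horizon_cycles
    if half_cycle_correction is not None:
        updates["half_cycle_correction"] = half_cycle_correction
        overrides["half_cycle_correction"] = half_cycle_correction
    if updates:
        dh = cfg.discount_horizon.model_copy(update=updates)
        cfg = cfg.model_copy(update={"discount_horizon": dh})

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outcomes = {
        which: evaluate_arm(cfg, which, cost_timing=cost_timing)
        for which in ("intervention", "control")
    }
    for which, outcome in outcomes.items():
        outcome.trace.to_csv(out_dir / f"trace_{which}.csv")
    incremental = compute_icer(outcomes["intervention"], outcomes["control"])
    results = {
        "intervention": outcomes["intervention"].to_dict(),
        "control": outcomes["control"].to_dict(),
        "incremental": incremental.to_dict(),
    }
    _write_json(out_dir / "results.json", results)
    _write_manifest(out_dir, "run-model", cfg, overrides)
    logger.info(
        "run-model: dominance=%s delta_cost=%.2f delta_qaly=%.4f",
        incremental.dominance,
        incremental.delta_cost,
        incremental.delta_qaly,
    )
    return results


def run_sensitivity(
    config: ModelConfig | str | Path | None = None,
    gdp_per_capita: float = 3000.0,
    out_dir: str | Path = ".",
    *,
    retention_fraction: float = 0.10,
) -> dict:
    """One-way sensitivity sweep plus the retention-reduction scenario.

    Writes ``tornado.csv`` (one row per catalog parameter, sorted by
    descending ICER span), ``retention_scenario.json`` and
    ``manifest.json``. ``gdp_per_capita`` (USD) sets the WHO-CHOICE
    willingness-to-pay bands used for classification.
    """
    if gdp_per_capita <= 0:
        raise ValueError("gdp_per_capita must be positive")
    cfg = _resolve_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    entries = one_way_sensitivity(cfg)
    tornado_dataframe(entries).to_csv(out_dir / "tornado.csv", index=False)

    scenario = retention_reduction_scenario(cfg, retention_fraction)
    scenario_payload = {
        "fraction": retention_fraction,
        **scenario.to_dict(),
        "classification": classify_threshold(scenario, gdp_per_capita),
        "gdp_per_capita": gdp_per_capita,
    }
    _write_json(out_dir / "retention_scenario.json", scenario_payload)
    _write_manifest(
        out_dir,
        "sensitivity",
        cfg,
        {"gdp_per_capita": gdp_per_capita, "retention_fraction": retention_fraction},
    )
    logger.info(
        "sensitivity: %d parameters swept; retention scenario -> %s",
        len(entries),
        scenario_payload["classification"],
    )
    return {"tornado": [e.to_dict() for e in entries], "retention": scenario_payload}


def run_ttr(
    inr_csv: str | Path,
    out_dir: str | Path = ".",
    range_low: float = 2.5,
    range_high: float = 3.5,
) -> dict:
    """Score a long-format INR CSV: per-patient TTR table + cohort summary.

    Writes ``ttr_per_patient.csv``, ``cohort_summary.json`` and
    ``manifest.json``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    series = read_inr_csv(inr_csv)
    results = [rosendaal_ttr(s, range_low, range_high) for s in series]
    results_dataframe(results).to_csv(out_dir / "ttr_per_patient.csv", index=False)
    summary = cohort_ttr_summary(results)
    _write_json(out_dir / "cohort_summary.json", summary.to_dict())
    _write_manifest(
        out_dir,
        "ttr",
        None,
        {"inr_csv": str(inr_csv), "range_low": range_low, "range_high": range_high},
    )
    logger.info("ttr: %d patients, median %.1f%%", summary.n, summary.median)
    return {
        "per_patient": [r.to_dict() for r in results],
        "summary": summary.to_dict(),
    }


def run_simulate(
    out_dir: str | Path = ".",
    *,
    arm: Literal["intervention", "control"] = "intervention",
    n_patients: int = 100,
    n_months: int = 12,
    seed: int = 0,
    config: ModelConfig | str | Path | None = None,
) -> dict:
    """Simulate a synthetic cohort and write its trajectory CSV + sidecar.

    Writes ``trajectories.csv`` (the long format ``run_ttr`` consumes) and
    ``simulation_spec.json`` recording the generating spec including the
    seed, plus ``manifest.json``.
    """
    cfg = _resolve_config(config)
    spec = SimulationSpec(
        arm=cfg.arm(arm), n_patients=n_patients, n_months=n_months, seed=seed
    )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    trajset = simulate_cohort(spec)
    trajset.to_csv(out_dir / "trajectories.csv")
    _write_json(out_dir / "simulation_spec.json", {"arm_name": arm, **spec.to_dict()})
    _write_manifest(
        out_dir,
        "simulate",
        cfg,
        {"arm": arm, "n_patients": n_patients, "n_months": n_months},
        seed=seed,
    )
    logger.info("simulate: %d patients x %d months (%s arm)", n_patients,
                n_months, arm)
    return {"n_patients": len(trajset), "out_dir": str(out_dir)}
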