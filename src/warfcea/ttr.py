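"""Rosendaal time-in-therapeutic-range (TTR) for INR measurement series.

The Rosendaal method assumes the INR changes linearly in calendar time
between successive measurements and apportions each between-visit interval
to time below, within and above the therapeutic range (here 2.5-3.5 for
mechanical mitral valve prostheses, boundaries inclusive). TTR is the
within-range share of the first-to-last-measurement span, as a percentage.

Anticoagulation-control categories follow the NICE convention that a TTR
below 65% marks poor control; the printed category labels "<65%" and ">75%"
are strict, so 65 and 75 belong to the middle bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InputFormatError, InsufficientDataError, SeriesOrderError

CATEGORY_POOR = "<65%"
CATEGORY_MODERATE = "65%-75%"
CATEGORY_GOOD = ">75%"
CATEGORIES = (CATEGORY_POOR, CATEGORY_MODERATE, CATEGORY_GOOD)

DEFAULT_RANGE = (2.5, 3.5)


@dataclass(frozen=True)
class INRSeries:
    """Ordered (day, INR) measurements for one patient."""

    patient_id: str
    days: np.ndarray
    inr: np.ndarray

    def __post_init__(self) -> None:
        days = np.asarray(self.days, dtype=float)
        inr = np.asarray(self.inr, dtype=float)
        if days.shape != inr.shape or days.ndim != 1:
            raise ValueError("days and inr must be 1-d arrays of equal length")
        if len(days) and days.min() < 0:
            raise ValueError("measurement days must be non-negative")
        if (np.diff(days) <= 0).any():
            raise SeriesOrderError(
                f"patient {self.patient_id}: days must be strictly increasing"
            )
        if (inr <= 0).any():
            raise ValueError(f"patient {self.patient_id}: INR values must be > 0")
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "inr", inr)

    def __len__(self) -> int:
        return len(self.days)

    @classmethod
    def from_pairs(
        cls, pairs: Sequence[tuple[float, float]], patient_id: str = "p"
    ) -> "INRSeries":
        arr = np.asarray(pairs, dtype=float).reshape(-1, 2)
        return cls(patient_id=patient_id, days=arr[:, 0], inr=arr[:, 1])


@dataclass(frozen=True)
class TTRResult:
    """Per-patient TTR decomposition; the three shares partition 100%."""

    patient_id: str
    ttr_percent: float
    percent_below: float
    percent_above: float
    total_days: float
    category: str = field(init=False)

    def __post_init__(self) -> None:
        total = self.ttr_percent + self.percent_below + self.percent_above
        if abs(total - 100.0) > 1e-9:
            raise ValueError(f"shares must sum to 100%, got {total!r}")
        object.__setattr__(self, "category", categorize_ttr(self.ttr_percent))

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "ttr_percent": self.ttr_percent,
            "percent_below": self.percent_below,
            "percent_above": self.percent_above,
            "total_days": self.total_days,
            "category": self.category,
        }


def _segment_split(
    v0: float, v1: float, dt: float, low: float, high: float
) -> tuple[float, float, float]:
    """Time (below, within, above) for one linearly interpolated segment."""
    if v0 == v1:
        if v0 < low:
            return dt, 0.0, 0.0
        if v0 > high:
            return 0.0, 0.0, dt
        return 0.0, dt, 0.0
    a, b = min(v0, v1), max(v0, v1)
    scale = dt / (b - a)
    below = max(0.0, min(b, low) - a) * scale
    within = max(0.0, min(b, high) - max(a, low)) * scale
    return below, within, dt - below - within


def rosendaal_ttr(
    series: INRSeries,
    range_low: float = DEFAULT_RANGE[0],
    range_high: float = DEFAULT_RANGE[1],
    *,
    max_gap_days: float | None = None,
) -> TTRResult:
    """Score one patient's INR series by Rosendaal linear interpolation.

    ``max_gap_days``, when set, excludes between-visit intervals longer than
    the cap from both numerator and denominator (off by default: the trial
    protocol set no cap, visit spacing varied with INR results).
    """
    if len(series) < 2:
        raise InsufficientDataError(
            f"patient {series.patient_id}: need >= 2 measurements, "
            f"have {len(series)}"
        )
    below = within = above = 0.0
    for i in range(len(series) - 1):
        dt = series.days[i + 1] - series.days[i]
        if max_gap_days is not None and dt > max_gap_days:
            continue
        b, w, a = _segment_split(
            series.inr[i], series.inr[i + 1], dt, range_low, range_high
        )
        below += b
        within += w
        above += a
    total = below + within + above
    if total <= 0:
        raise InsufficientDataError(
            f"patient {series.patient_id}: no scoreable observation time"
        )
    return TTRResult(
        patient_id=series.patient_id,
        ttr_percent=100.0 * within / total,
        percent_below=100.0 * below / total,
        percent_above=100.0 * above / total,
        total_days=total,
    )


def categorize_ttr(ttr_percent: float) -> str:
    """Bin a TTR percentage into the poor / moderate / good control bands."""
    if not (0.0 <= ttr_percent <= 100.0):
        raise ValueError(f"TTR must lie in [0, 100], got {ttr_percent}")
    if ttr_percent < 65.0:
        return CATEGORY_POOR
    if ttr_percent <= 75.0:
        return CATEGORY_MODERATE
    return CATEGORY_GOOD


@dataclass(frozen=True)
class CohortTTRSummary:
    """Median/IQR of TTR plus category counts for a patient cohort."""

    n: int
    median: float
    iqr_low: float
    iqr_high: float
    category_counts: dict[str, int]
    category_percent: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "median": self.median,
            "iqr_low": self.iqr_low,
            "iqr_high": self.iqr_high,
            "category_counts": dict(self.category_counts),
            "category_percent": dict(self.category_percent),
        }


def cohort_ttr_summary(results: Iterable[TTRResult]) -> CohortTTRSummary:
    """Summarize per-patient TTRs: median, IQR and category breakdown.

    Quantiles use the linear-interpolation convention between order
    statistics (numpy default).
    """
    results = list(results)
    if not results:
        raise ValueError("cannot summarize an empty collection of TTR results")
    values = np.array([r.ttr_percent for r in results])
    counts = {c: 0 for c in CATEGORIES}
    for r in results:
        counts[r.category] += 1
    n = len(results)
    return CohortTTRSummary(
        n=n,
        median=float(np.median(values)),
        iqr_low=float(np.percentile(values, 25)),
        iqr_high=float(np.percentile(values, 75)),
        category_counts=counts,
        category_percent={c: 100.0 * k / n for c, k in counts.items()},
    )


def read_inr_csv(path: str | Path) -> list[INRSeries]:
    """Read a long-format CSV of (patient_id, day, inr) into per-patient series.

    Rows must be numeric; a malformed row raises an error naming its line
    number (1-based, header included).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"patient_id": str})
    except Exception as exc:
        raise InputFormatError(f"cannot read {path}: {exc}") from exc
    required = {"patient_id", "day", "inr"}
    if not required.issubset(df.columns):
        raise InputFormatError(
            f"{path}: missing column(s) {sorted(required - set(df.columns))}"
        )
    for col in ("day", "inr"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise InputFormatError(f"{path}: malformed {col!r} value at line {line}")
        df[col] = coerced
    series = []
    for pid, grp in df.groupby("patient_id", sort=True):
        grp = grp.sort_values("day")
        series.append(
            INRSeries(
                patient_id=str(pid),
                days=grp["day"].to_numpy(),
                inr=grp["inr"].to_numpy(),
            )
        )
    return series


def results_dataframe(results: Iterable[TTRResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])
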