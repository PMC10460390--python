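"""Glycaemic-variability and sensor-accuracy statistics.

Per subject:

* CV (%) = 100 x SD / mean of the retained glucose readings (sample SD,
  denominator n-1). Pooled over all retained days by default; a per-day mode
  averages the daily CVs instead.
* MODD (mean of daily differences) = mean of |BG_t - BG_{t-1440 min}| over
  the k slot pairs observed at the same clock time on consecutive calendar
  days. Days separated by a dropped day contribute no pairs; k = 0 flags the
  statistic as undefined. Computed in mg/dL; divide by 18.016 for mmol/L.

From paired sensor/capillary points:

* ARD of a pair = 100 x |sensor - capillary| / capillary; MARD is the mean
  ARD, reported overall, by capillary range (<70, 70-180, >180 mg/dL) and by
  wear day, along with the surveillance-style agreement rates (within
  15 mg/dL of capillary below 100 mg/dL, within 15 % at or above).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ingest_qc import SubjectSeries

MGDL_PER_MMOLL = 18.016

RANGE_LABELS = ("<70", "70-180", ">180")

PAIRED_COLUMNS = ("subject_id", "day", "sensor_mgdl", "capillary_mgdl")


@dataclass
class VariabilityResult:
    """Subject-level glycaemic variability; ``modd`` is ``None`` when no
    consecutive-day slot pairs exist (``n_modd_pairs == 0``)."""

    subject_id: str
    cv: float | None
    modd: float | None
    n_modd_pairs: int

    @property
    def modd_mmol(self) -> float | None:
        return None if self.modd is None else self.modd / MGDL_PER_MMOLL


@dataclass(frozen=True)
class PairedPoint:
    """One simultaneous sensor / capillary reference pair."""

    subject_id: str
    day: int
    sensor: float
    capillary: float

    def __post_init__(self) -> None:
        if not (self.sensor > 0 and self.capillary > 0):
            raise ValueError("paired glucose values must be positive")


@dataclass
class MARDReport:
    overall_mard: float
    n_pairs: int
    mard_by_range: dict[str, float | None]
    n_by_range: dict[str, int]
    mard_by_day: dict[int, float]
    n_by_day: dict[int, int]
    pct_within15_low: float | None  # |sensor-capillary| <= 15 mg/dL, capillary < 100
    n_low: int
    pct_within15_high: float | None  # ARD <= 15 %, capillary >= 100
    n_high: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _observed_day_values(series: SubjectSeries) -> list[np.ndarray]:
    return [c.values[c.observed_mask] for c in series.day_curves]


def cv_percent(series: SubjectSeries, mode: str = "pooled") -> float:
    """Coefficient of variation (%), ``100 * sd / mean`` with sample SD.

    ``pooled`` (default) concatenates all retained readings; ``per_day_mean``
    averages the daily CVs over days with at least two readings.
    """
    if mode == "pooled":
        values = np.concatenate(_observed_day_values(series))
        if values.size < 2:
            raise ValueError("cv_percent needs at least 2 glucose values")
        return 100.0 * float(np.std(values, ddof=1)) / float(np.mean(values))
    if mode == "per_day_mean":
        daily = [
            100.0 * float(np.std(v, ddof=1)) / float(np.mean(v))
            for v in _observed_day_values(series)
            if v.size >= 2
        ]
        if not daily:
            raise ValueError("cv_percent needs at least one day with 2+ values")
        return float(np.mean(daily))
    raise ValueError(f"unknown cv mode {mode!r}")


def modd(series: SubjectSeries) -> VariabilityResult:
    """Mean of daily differences over matched slots 1440 min apart.

    Only identical slots on *consecutive* calendar days pair up (the literal
    24 h lag), both slots observed. ``cv`` is left unset; see
    :func:`subject_variability` for the combined record.
    """
    if series.n_days < 2:
        raise ValueError("modd needs at least 2 retained days")
    by_day = {c.calendar_day: c for c in series.day_curves}
    total = 0.0
    k = 0
    for day, cur in by_day.items():
        prev = by_day.get(day - 1)
        if prev is None:
            continue
        both = cur.observed_mask & prev.observed_mask
        total += float(np.abs(cur.values[both] - prev.values[both]).sum())
        k += int(both.sum())
    return VariabilityResult(series.subject_id, None, total / k if k else None, k)


def subject_variability(series: SubjectSeries, cv_mode: str = "pooled") -> VariabilityResult:
    """CV and MODD for one subject in a single record."""
    res = modd(series)
    res.cv = cv_percent(series, mode=cv_mode)
    return res


def variability_table(
    cohort: Sequence[SubjectSeries], cv_mode: str = "pooled"
) -> pd.DataFrame:
    """Tidy per-subject variability table (one row per subject)."""
    rows = []
    for s in cohort:
        r = subject_variability(s, cv_mode=cv_mode)
        rows.append(
            {
                "subject_id": r.subject_id,
                "cv_pct": r.cv,
                "modd_mgdl": r.modd,
                "modd_mmoll": r.modd_mmol,
                "n_modd_pairs": r.n_modd_pairs,
            }
        )
    return pd.DataFrame(rows)


def _mean_or_none(x: np.ndarray) -> float | None:
    return float(x.mean()) if x.size else None


def mard_report(pairs: Iterable[PairedPoint] | pd.DataFrame) -> MARDReport:
    """Sensor-accuracy summary from paired sensor/capillary points.

    Range strata are keyed on the capillary value, with 70 and 180 mg/dL
    assigned to the middle stratum; agreement thresholds are inclusive.
    """
    if isinstance(pairs, pd.DataFrame):
        sensor = pairs["sensor_mgdl"].to_numpy(float)
        cap = pairs["capillary_mgdl"].to_numpy(float)
        day = pairs["day"].to_numpy(int)
    else:
        pairs = list(pairs)
        sensor = np.array([p.sensor for p in pairs], float)
        cap = np.array([p.capillary for p in pairs], float)
        day = np.array([p.day for p in pairs], int)
    if sensor.size == 0:
        raise ValueError("mard_report needs at least one paired point")
    if (cap <= 0).any():
        raise ValueError("capillary reference values must be positive")

    ard = 100.0 * np.abs(sensor - cap) / cap
    in_range = {
        "<70": cap < 70,
        "70-180": (cap >= 70) & (cap <= 180),
        ">180": cap > 180,
    }
    mard_by_range = {lab: _mean_or_none(ard[m]) for lab, m in in_range.items()}
    n_by_range = {lab: int(m.sum()) for lab, m in in_range.items()}
    days = np.unique(day)
    mard_by_day = {int(d): float(ard[day == d].mean()) for d in days}
    n_by_day = {int(d): int((day == d).sum()) for d in days}

    low = cap < 100
    high = ~low
    within_low = np.abs(sensor - cap)[low] <= 15.0
    within_high = ard[high] <= 15.0
    return MARDReport(
        overall_mard=float(ard.mean()),
        n_pairs=int(ard.size),
        mard_by_range=mard_by_range,
        n_by_range=n_by_range,
        mard_by_day=mard_by_day,
        n_by_day=n_by_day,
        pct_within15_low=(100.0 * float(within_low.mean())) if low.any() else None,
        n_low=int(low.sum()),
        pct_within15_high=(100.0 * float(within_high.mean())) if high.any() else None,
        n_high=int(high.sum()),
    )


def read_paired_points(path) -> pd.DataFrame:
    """Read the canonical paired-points CSV."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    if list(df.columns) != list(PAIRED_COLUMNS):
        raise ValueError(f"{path}: expected header {','.join(PAIRED_COLUMNS)}")
    if (df["capillary_mgdl"] <= 0).any() or (df["sensor_mgdl"] <= 0).any():
        raise ValueError(f"{path}: paired glucose values must be positive")
    return df
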