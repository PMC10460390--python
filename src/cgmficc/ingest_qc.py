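"""Ingestion and quality control of continuous glucose monitoring records.

Raw CGM data arrive as long-format (subject, timestamp, glucose) rows sampled
roughly every 5 minutes by a subcutaneous sensor with a hardware range of
40-400 mg/dL, i.e. up to 288 readings per calendar day. This module
discretises them onto a fixed 288-slot daily grid (midnight to midnight, slot
``s`` covering minutes ``[5s, 5s+5)``) and applies the exclusion rules used
throughout the package:

* the sensor-insertion day (calendar day 0) is discarded;
* a day whose data-acquisition failures total more than two hours
  (strictly more than 24 five-minute slots, cumulative) is discarded;
* a day with fewer than three calibration fingersticks is discarded;
* a subject retaining fewer than two days is excluded.

Retained days are completed by linear interpolation of interior gaps and
nearest-value extension at the day edges, so downstream functional analysis
always sees full 288-point curves.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SLOT_MINUTES = 5
SLOTS_PER_DAY = 288
MINUTES_PER_DAY = SLOT_MINUTES * SLOTS_PER_DAY  # 1440
SENSOR_RANGE = (40.0, 400.0)

#: canonical long-format CSV header for both CGM and fingerstick files
CGM_COLUMNS = ("subject_id", "timestamp_min", "glucose_mgdl")


@dataclass(frozen=True)
class GlucoseReading:
    """One interstitial glucose reading.

    ``timestamp`` is integer minutes since the cohort epoch (midnight of the
    insertion day), so ``timestamp // 1440`` is the calendar day and
    ``(timestamp % 1440) // 5`` the within-day grid slot.
    """

    subject_id: str
    timestamp: int
    glucose: float

    @property
    def calendar_day(self) -> int:
        return int(self.timestamp) // MINUTES_PER_DAY

    @property
    def slot(self) -> int:
        return (int(self.timestamp) % MINUTES_PER_DAY) // SLOT_MINUTES


@dataclass(frozen=True)
class FingerstickReading:
    """One capillary (SMBG) glucose measurement used for calibration counting."""

    subject_id: str
    timestamp: int
    glucose: float

    def __post_init__(self) -> None:
        if not self.glucose > 0:
            raise ValueError(f"fingerstick glucose must be positive, got {self.glucose}")

    @property
    def calendar_day(self) -> int:
        return int(self.timestamp) // MINUTES_PER_DAY


@dataclass
class DayCurve:
    """One subject-day glucose curve on the fixed 288-slot grid.

    ``observed_mask`` marks slots backed by an actual sensor reading;
    after :func:`fill_small_gaps` the mask is all ``True`` and the number of
    imputed slots is kept in ``n_imputed``.
    """

    subject_id: str
    calendar_day: int
    values: np.ndarray
    observed_mask: np.ndarray
    n_fingersticks: int = 0
    n_imputed: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.observed_mask = np.asarray(self.observed_mask, dtype=bool)
        if self.values.shape != (SLOTS_PER_DAY,):
            raise ValueError(f"values must have length {SLOTS_PER_DAY}")
        if self.observed_mask.shape != (SLOTS_PER_DAY,):
            raise ValueError(f"observed_mask must have length {SLOTS_PER_DAY}")
        if np.isnan(self.values[self.observed_mask]).any():
            raise ValueError("values must be defined wherever observed_mask is true")

    @property
    def n_missing(self) -> int:
        return int((~self.observed_mask).sum())

    def equals(self, other: "DayCurve") -> bool:
        return (
            self.subject_id == other.subject_id
            and self.calendar_day == other.calendar_day
            and self.n_fingersticks == other.n_fingersticks
            and self.n_imputed == other.n_imputed
            and bool(np.array_equal(self.observed_mask, other.observed_mask))
            and bool(
                np.array_equal(
                    np.where(self.observed_mask, self.values, 0.0),
                    np.where(other.observed_mask, other.values, 0.0),
                )
            )
            and bool(np.allclose(self.values, other.values, equal_nan=True))
        )


@dataclass
class SubjectSeries:
    """One subject's retained day curves plus covariates and glycaemic status.

    This is the unit of subject-level (cluster) bootstrap resampling.
    """

    subject_id: str
    day_curves: list[DayCurve]
    covariates: object | None = None  # cohort.CovariateRecord
    status: object | None = None  # cohort.GlycemicStatus

    @property
    def n_days(self) -> int:
        return len(self.day_curves)


@dataclass
class QCRules:
    """Day- and subject-level exclusion rules.

    Defaults implement the study protocol: drop the insertion day, drop days
    with more than 2 h (24 slots) of cumulative missing data, drop days with
    fewer than 3 calibration fingersticks, and exclude subjects with fewer
    than 2 surviving days. ``clamp=True`` clips out-of-range readings to the
    sensor's hardware range instead of dropping them.
    """

    drop_first_day: bool = True
    max_missing_slots: int = 24
    min_fingersticks_per_day: int = 3
    min_days_per_subject: int = 2
    clamp_range: tuple[float, float] = SENSOR_RANGE
    clamp: bool = True

    @classmethod
    def from_mapping(cls, d: Mapping) -> "QCRules":
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in d:
                kwargs[f.name] = d[f.name]
        if "clamp_range" in kwargs:
            kwargs["clamp_range"] = tuple(kwargs["clamp_range"])
        return cls(**kwargs)


@dataclass
class QCReport:
    """Tally of every day and subject dropped, by rule.

    Day-level counts are taken before subject-level exclusion: a day that
    survives the day rules counts as retained even if its subject is later
    excluded for having fewer than ``min_days_per_subject`` days, so that for
    every subject ``days_in == days_retained + day1 + gap + calibration``.
    """

    subjects_in: int = 0
    subjects_retained: int = 0
    subjects_dropped: list[str] = field(default_factory=list)
    days_in: int = 0
    days_retained: int = 0
    days_dropped_day1: int = 0
    days_dropped_gap: int = 0
    days_dropped_calibration: int = 0
    n_clamped: int = 0
    per_subject: dict[str, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


# ---------------------------------------------------------------------------
# reading the canonical CSVs
# ---------------------------------------------------------------------------


def _read_long_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    df = pd.read_csv(path, dtype={"subject_id": str})
    if list(df.columns) != list(CGM_COLUMNS):
        raise ValueError(
            f"{path}: expected header {','.join(CGM_COLUMNS)}, got {','.join(map(str, df.columns))}"
        )
    ts = pd.to_numeric(df["timestamp_min"], errors="coerce")
    glc = pd.to_numeric(df["glucose_mgdl"], errors="coerce")
    bad = df["subject_id"].isna() | ts.isna() | glc.isna()
    if bad.any():
        # +2: header line plus 1-based numbering
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise ValueError(f"{path}: malformed row at line {line}")
    df = df.assign(timestamp_min=ts.astype(np.int64), glucose_mgdl=glc.astype(float))
    dup = df.duplicated(subset=["subject_id", "timestamp_min"])
    if dup.any():
        line = int(np.flatnonzero(dup.to_numpy())[0]) + 2
        raise ValueError(f"{path}: duplicate (subject_id, timestamp) at line {line}")
    return df.sort_values(["subject_id", "timestamp_min"], kind="mergesort").reset_index(drop=True)


def read_cgm_long(path: str | Path, clamp: bool = True) -> list[GlucoseReading]:
    """Read the canonical CGM CSV into sorted :class:`GlucoseReading` records.

    Out-of-range values (outside 40-400 mg/dL) are clipped to the nearest
    bound when ``clamp`` is true (with a logged count), and dropped otherwise.
    """
    df = read_cgm_frame(path, clamp=clamp)
    return [
        GlucoseReading(s, int(t), float(g))
        for s, t, g in zip(df["subject_id"], df["timestamp_min"], df["glucose_mgdl"])
    ]


def read_cgm_frame(path: str | Path, clamp: bool = True) -> pd.DataFrame:
    """Vectorised counterpart of :func:`read_cgm_long`; same validation and clamping."""
    df = _read_long_csv(path)
    lo, hi = SENSOR_RANGE
    out = (df["glucose_mgdl"] < lo) | (df["glucose_mgdl"] > hi)
    n_out = int(out.sum())
    if n_out:
        if clamp:
            logger.warning("%s: clamped %d reading(s) to sensor range [%g, %g]", path, n_out, lo, hi)
            df["glucose_mgdl"] = df["glucose_mgdl"].clip(lo, hi)
        else:
            logger.warning("%s: dropped %d out-of-range reading(s)", path, n_out)
            df = df.loc[~out].reset_index(drop=True)
    df.attrs["n_clamped"] = n_out if clamp else 0
    return df


def read_fingersticks(path: str | Path) -> list[FingerstickReading]:
    """Read the canonical fingerstick CSV (same schema as the CGM file)."""
    df = _read_long_csv(path)
    if (df["glucose_mgdl"] <= 0).any():
        raise ValueError(f"{path}: fingerstick glucose must be positive")
    return [
        FingerstickReading(s, int(t), float(g))
        for s, t, g in zip(df["subject_id"], df["timestamp_min"], df["glucose_mgdl"])
    ]


def readings_to_frame(readings: Iterable[GlucoseReading | FingerstickReading]) -> pd.DataFrame:
    rows = [(r.subject_id, r.timestamp, r.glucose) for r in readings]
    return pd.DataFrame(rows, columns=list(CGM_COLUMNS))


# ---------------------------------------------------------------------------
# gridding
# ---------------------------------------------------------------------------


def grid_day(
    readings: Sequence[GlucoseReading],
    subject_id: str | None = None,
    calendar_day: int | None = None,
) -> DayCurve:
    """Discretise one subject-day's readings onto the 288-slot grid.

    Off-grid timestamps are floored to the containing 5-minute slot; readings
    colliding in a slot are averaged. Slots with no reading get
    ``observed_mask=False``. An empty input yields an all-missing curve
    (subject and day must then be given explicitly).
    """
    readings = list(readings)
    if readings:
        sids = {r.subject_id for r in readings}
        days = {r.calendar_day for r in readings}
        if len(sids) > 1 or len(days) > 1:
            raise ValueError("grid_day expects readings from a single subject-day")
        subject_id = subject_id if subject_id is not None else sids.pop()
        calendar_day = calendar_day if calendar_day is not None else days.pop()
    elif subject_id is None or calendar_day is None:
        raise ValueError("empty input: subject_id and calendar_day must be given")
    sums = np.zeros(SLOTS_PER_DAY)
    counts = np.zeros(SLOTS_PER_DAY, dtype=int)
    for r in readings:
        sums[r.slot] += r.glucose
        counts[r.slot] += 1
    mask = counts > 0
    values = np.full(SLOTS_PER_DAY, np.nan)
    values[mask] = sums[mask] / counts[mask]
    return DayCurve(subject_id, int(calendar_day), values, mask)


def grid_cohort(cgm: pd.DataFrame | Iterable[GlucoseReading]) -> dict[str, list[DayCurve]]:
    """Grid a whole cohort's readings into per-subject day curves.

    Accepts either the canonical long-format frame or an iterable of
    :class:`GlucoseReading`; semantics per subject-day match :func:`grid_day`
    (floor-to-slot, collisions averaged).
    """
    if not isinstance(cgm, pd.DataFrame):
        cgm = readings_to_frame(cgm)
    if cgm.empty:
        return {}
    ts = cgm["timestamp_min"].to_numpy(np.int64)
    day = ts // MINUTES_PER_DAY
    slot = (ts % MINUTES_PER_DAY) // SLOT_MINUTES
    g = (
        pd.DataFrame(
            {
                "subject_id": cgm["subject_id"].to_numpy(),
                "day": day,
                "slot": slot,
                "glucose": cgm["glucose_mgdl"].to_numpy(float),
            }
        )
        .groupby(["subject_id", "day", "slot"], sort=True)["glucose"]
        .mean()
        .reset_index()
    )
    out: dict[str, list[DayCurve]] = defaultdict(list)
    for (sid, d), grp in g.groupby(["subject_id", "day"], sort=True):
        values = np.full(SLOTS_PER_DAY, np.nan)
        mask = np.zeros(SLOTS_PER_DAY, dtype=bool)
        sl = grp["slot"].to_numpy(int)
        values[sl] = grp["glucose"].to_numpy(float)
        mask[sl] = True
        out[str(sid)].append(DayCurve(str(sid), int(d), values, mask))
    return dict(out)


def fill_small_gaps(curve: DayCurve) -> DayCurve:
    """Complete a day curve: linear interpolation of interior gaps,
    nearest-observed-value extension at the day edges.

    The returned curve has an all-true mask; the number of imputed slots is
    recorded in ``n_imputed``. Observed values are preserved exactly, and no
    imputed value falls outside the day's observed [min, max].
    """
    mask = curve.observed_mask
    if not mask.any():
        raise ValueError(f"{curve.subject_id} day {curve.calendar_day}: all slots missing")
    if mask.all():
        return dataclasses.replace(
            curve, values=curve.values.copy(), observed_mask=mask.copy()
        )
    idx = np.flatnonzero(mask)
    # np.interp extends with the first/last observed value beyond the ends
    values = np.interp(np.arange(SLOTS_PER_DAY), idx, curve.values[idx])
    values[idx] = curve.values[idx]
    return dataclasses.replace(
        curve,
        values=values,
        observed_mask=np.ones(SLOTS_PER_DAY, dtype=bool),
        n_imputed=curve.n_imputed + curve.n_missing,
    )


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------


def _fingerstick_counts(
    sticks: Iterable[FingerstickReading] | pd.DataFrame | None,
) -> dict[tuple[str, int], int] | None:
    if sticks is None:
        return None
    counts: dict[tuple[str, int], int] = defaultdict(int)
    if isinstance(sticks, pd.DataFrame):
        days = sticks["timestamp_min"].to_numpy(np.int64) // MINUTES_PER_DAY
        for sid, d in zip(sticks["subject_id"], days):
            counts[(str(sid), int(d))] += 1
    else:
        for s in sticks:
            counts[(s.subject_id, s.calendar_day)] += 1
    return counts


def apply_qc(
    curves: Mapping[str, Sequence[DayCurve]] | Iterable[DayCurve],
    sticks: Iterable[FingerstickReading] | pd.DataFrame | None,
    rules: QCRules = QCRules(),
) -> tuple[list[SubjectSeries], QCReport]:
    """Apply the day- and subject-level exclusion rules.

    Day rules are applied in order (insertion day, missing-data, calibration)
    and each dropped day is tallied once under the first rule that hit it.
    Surviving days are gap-filled. When ``sticks`` is ``None`` the
    ``n_fingersticks`` already stored on each curve is trusted, which makes
    ``apply_qc`` idempotent on its own output.
    """
    if not isinstance(curves, Mapping):
        grouped: dict[str, list[DayCurve]] = defaultdict(list)
        for c in curves:
            grouped[c.subject_id].append(c)
        curves = grouped
    counts = _fingerstick_counts(sticks)

    report = QCReport(subjects_in=len(curves))
    series: list[SubjectSeries] = []
    for sid in sorted(curves):
        tally = {"days_in": 0, "retained": 0, "day1": 0, "gap": 0, "calibration": 0}
        retained: list[DayCurve] = []
        for curve in sorted(curves[sid], key=lambda c: c.calendar_day):
            tally["days_in"] += 1
            n_sticks = (
                curve.n_fingersticks if counts is None else counts.get((sid, curve.calendar_day), 0)
            )
            if rules.drop_first_day and curve.calendar_day == 0:
                tally["day1"] += 1
            elif curve.n_missing > rules.max_missing_slots:
                tally["gap"] += 1
            elif n_sticks < rules.min_fingersticks_per_day:
                tally["calibration"] += 1
            else:
                filled = fill_small_gaps(dataclasses.replace(curve, n_fingersticks=n_sticks))
                retained.append(filled)
                tally["retained"] += 1
        report.days_in += tally["days_in"]
        report.days_retained += tally["retained"]
        report.days_dropped_day1 += tally["day1"]
        report.days_dropped_gap += tally["gap"]
        report.days_dropped_calibration += tally["calibration"]
        excluded = len(retained) < rules.min_days_per_subject
        tally["subject_excluded"] = excluded
        report.per_subject[sid] = tally
        if excluded:
            report.subjects_dropped.append(sid)
            logger.info(
                "QC: subject %s excluded (%d day(s) retained, need %d)",
                sid,
                len(retained),
                rules.min_days_per_subject,
            )
        else:
            series.append(SubjectSeries(sid, retained))
    report.subjects_retained = len(series)
    logger.info(
        "QC: %d/%d subjects retained; days in=%d retained=%d "
        "(dropped: day1=%d, gap=%d, calibration=%d)",
        report.subjects_retained,
        report.subjects_in,
        report.days_in,
        report.days_retained,
        report.days_dropped_day1,
        report.days_dropped_gap,
        report.days_dropped_calibration,
    )
    return series, report
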