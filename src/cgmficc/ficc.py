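"""Functional intraclass correlation for daily glucose curves.

Model: the j-th daily curve of subject i is

    Y_ij(t) = mu(t) + eta_i(t) + eps_ij(t),   t on the 288-slot grid,

with a subject-level functional random effect eta_i (covariance operator
K_eta) and a day-level deviation eps_ij (covariance operator K_eps). The
functional ICC is the trace ratio

    ICC = tr(K_eta) / (tr(K_eta) + tr(K_eps)),

the fraction of total day-to-day curve variation attributable to stable
between-subject differences; it measures how reproducible a subject's daily
glucose profile is from one day to the next (< 0.4 poor, 0.4-0.59 fair,
0.60-0.74 good, > 0.74 excellent agreement).

Estimation is a method-of-moments one-way functional ANOVA on traces that
handles unbalanced designs (subjects with different numbers of retained
days); with n subjects, J_i curves each, N = sum J_i:

    tr_W  = SS_within / (N - n)
    MSB   = SS_between / (n - 1)
    c0    = (N - sum_i J_i^2 / N) / (n - 1)
    tr_B  = max(0, (MSB - tr_W) / c0)

Sums run over the grid; the constant quadrature weight cancels in the ratio.
Truncation at zero keeps the estimate in [0, 1]. In the balanced case this
reduces exactly to the trace ratio of the empirical moment estimators of
K_eta and K_eps (the I2C2-style estimator for replicated functional data).

Confidence intervals come from a subject-level (cluster) percentile
bootstrap: whole subjects are resampled with replacement, each carrying all
its curves, and duplicated subjects count as distinct clusters.
"""
from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import cohort as _cohort
from .ingest_qc import SLOT_MINUTES, SLOTS_PER_DAY, SubjectSeries
from .metrics import MGDL_PER_MMOLL, subject_variability

AGREEMENT_BANDS = ((0.4, "poor"), (0.6, "fair"), (0.75, "good"), (1.01, "excellent"))


@dataclass
class CurvePanel:
    """Stacked complete curves with a subject index.

    Rows must be grouped by subject (non-decreasing ``subject_index``) and
    every subject must contribute at least two rows; :func:`build_panel`
    guarantees both.
    """

    Y: np.ndarray  # (N, p)
    subject_index: np.ndarray  # (N,) ints in [0, n)
    grid: np.ndarray  # (p,) slot-start minutes
    subject_ids: tuple[str, ...] | None = None
    day_index: np.ndarray | None = None  # (N,) calendar day per row, optional

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        self.subject_index = np.asarray(self.subject_index, dtype=np.intp)
        self.grid = np.asarray(self.grid, dtype=float)
        if self.Y.ndim != 2 or self.Y.shape[0] != self.subject_index.shape[0]:
            raise ValueError("Y and subject_index shapes disagree")
        if self.grid.shape != (self.Y.shape[1],):
            raise ValueError("grid length must match the number of columns of Y")
        if np.isnan(self.Y).any():
            raise ValueError("panel contains missing values; gap-fill upstream")
        if np.any(np.diff(self.subject_index) < 0):
            raise ValueError("rows must be grouped by subject (sorted subject_index)")
        counts = np.bincount(self.subject_index, minlength=self.n_subjects)
        if counts.size and counts.min() < 2:
            raise ValueError("every subject must contribute at least 2 curves")

    @property
    def n_curves(self) -> int:
        return self.Y.shape[0]

    @property
    def n_subjects(self) -> int:
        return int(self.subject_index.max()) + 1 if self.subject_index.size else 0

    @property
    def p(self) -> int:
        return self.Y.shape[1]


@dataclass
class ICCResult:
    """Point estimate, variance traces (mg^2/dL^2 summed over the grid) and
    bootstrap percentile CI bounds (NaN when no bootstrap was run)."""

    icc: float
    trace_between: float
    trace_within: float
    ci_low: float = math.nan
    ci_high: float = math.nan
    n_subjects: int = 0
    n_curves: int = 0
    B: int = 0
    seed: int | None = None
    degenerate: bool = False

    @property
    def agreement(self) -> str:
        if math.isnan(self.icc):
            return "undefined"
        for upper, label in AGREEMENT_BANDS:
            if self.icc < upper:
                return label
        return "excellent"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def build_panel(cohort: Sequence[SubjectSeries]) -> CurvePanel:
    """Stack a QC'd cohort into a panel in deterministic
    (subject_id, calendar_day) order."""
    if not cohort:
        raise ValueError("empty cohort")
    ordered = sorted(cohort, key=lambda s: s.subject_id)
    rows, sub_idx, day_idx, ids = [], [], [], []
    for i, series in enumerate(ordered):
        if series.n_days < 2:
            raise ValueError(
                f"subject {series.subject_id} has {series.n_days} curve(s); need >= 2"
            )
        ids.append(series.subject_id)
        for curve in sorted(series.day_curves, key=lambda c: c.calendar_day):
            if not curve.observed_mask.all():
                raise ValueError(
                    f"subject {series.subject_id} day {curve.calendar_day} has gaps; "
                    "run fill_small_gaps/apply_qc first"
                )
            rows.append(curve.values)
            sub_idx.append(i)
            day_idx.append(curve.calendar_day)
    grid = np.arange(SLOTS_PER_DAY) * float(SLOT_MINUTES)
    return CurvePanel(
        Y=np.vstack(rows),
        subject_index=np.array(sub_idx),
        grid=grid,
        subject_ids=tuple(ids),
        day_index=np.array(day_idx),
    )


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------


def _demeaned(panel: CurvePanel) -> np.ndarray:
    """Subtract the day-specific mean curve (two-way fixed day effect)."""
    if panel.day_index is None:
        raise ValueError("demean_by_day requires the panel's day_index")
    Y = panel.Y.copy()
    for d in np.unique(panel.day_index):
        rows = panel.day_index == d
        Y[rows] -= Y[rows].mean(axis=0)
    return Y


def _cluster_stats(Y: np.ndarray, subject_index: np.ndarray):
    """Per-subject sufficient statistics: sizes J, curve sums, sum of squared
    row norms, from rows grouped by subject."""
    J = np.bincount(subject_index)
    starts = np.concatenate(([0], np.cumsum(J)[:-1]))
    sums = np.add.reduceat(Y, starts, axis=0)
    sumsq = np.add.reduceat(np.einsum("ij,ij->i", Y, Y), starts)
    return J.astype(float), sums, sumsq


def _icc_from_totals(n, N, total_sq, term, G2, sum_J2):
    """Trace estimates from cluster-stat totals. Vectorised over leading axis.

    term = sum_i J_i ||Ybar_i||^2, G2 = ||sum of all rows||^2,
    sum_J2 = sum_i J_i^2.
    """
    ssb = term - G2 / N
    ssw = total_sq - term
    with np.errstate(invalid="ignore", divide="ignore"):
        tr_w = ssw / (N - n)
        msb = ssb / (n - 1)
        c0 = (N - sum_J2 / N) / (n - 1)
        tr_b = np.maximum(0.0, (msb - tr_w) / c0)
        total = tr_b + tr_w
        icc = np.where(total > 0, tr_b / np.where(total > 0, total, 1.0), np.nan)
    return icc, tr_b, tr_w


def estimate_ficc(panel: CurvePanel, demean_by_day: bool = False) -> ICCResult:
    """Point estimate of the functional ICC (no confidence interval).

    ``demean_by_day=True`` removes the day-specific mean curve first (two-way
    layout with a fixed visit effect); the default removes only the overall
    mean, which the trace formulas do implicitly.
    """
    n = panel.n_subjects
    if n < 2:
        raise ValueError("estimate_ficc needs at least 2 subjects")
    Y = _demeaned(panel) if demean_by_day else panel.Y
    J, sums, sumsq = _cluster_stats(Y, panel.subject_index)
    means = sums / J[:, None]
    term = float((J * np.einsum("ij,ij->i", means, means)).sum())
    G = sums.sum(axis=0)
    icc, tr_b, tr_w = _icc_from_totals(
        float(n),
        float(J.sum()),
        float(sumsq.sum()),
        term,
        float(G @ G),
        float((J * J).sum()),
    )
    icc, tr_b, tr_w = float(icc), float(tr_b), float(tr_w)
    return ICCResult(
        icc=icc,
        trace_between=tr_b,
        trace_within=tr_w,
        n_subjects=n,
        n_curves=panel.n_curves,
        degenerate=math.isnan(icc),
    )


def bootstrap_ci(
    panel: CurvePanel,
    B: int = 1000,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    demean_by_day: bool = False,
) -> ICCResult:
    """Point estimate plus subject-level percentile bootstrap 95 % CI.

    Each replicate resamples the n subjects with replacement; a duplicated
    subject enters as a distinct cluster with all its curves. Degenerate
    replicate estimates (all curves identical) are recorded as NaN and
    excluded from the percentiles. Deterministic for a fixed seed.
    """
    if B < 1:
        raise ValueError("B must be >= 1 (>= 100 for reported CIs)")
    point = estimate_ficc(panel, demean_by_day=demean_by_day)
    n = panel.n_subjects
    Y = _demeaned(panel) if demean_by_day else panel.Y
    J, sums, sumsq = _cluster_stats(Y, panel.subject_index)
    means = sums / J[:, None]
    w_term = J * np.einsum("ij,ij->i", means, means)  # J_i ||Ybar_i||^2
    J2 = J * J

    rng = np.random.default_rng(seed)
    choices = rng.integers(0, n, size=(B, n))
    offset = choices + np.arange(B)[:, None] * n
    counts = np.bincount(offset.ravel(), minlength=B * n).reshape(B, n).astype(float)

    Ns = counts @ J
    total_sq = counts @ sumsq
    term = counts @ w_term
    G = counts @ sums  # (B, p) grand sums per replicate
    G2 = np.einsum("ij,ij->i", G, G)
    sum_J2 = counts @ J2
    icc_b, _, _ = _icc_from_totals(float(n), Ns, total_sq, term, G2, sum_J2)

    finite = icc_b[np.isfinite(icc_b)]
    if finite.size:
        lo, hi = np.percentile(finite, [2.5, 97.5])
    else:
        lo = hi = math.nan
    seed_int = seed if isinstance(seed, (int, np.integer)) else None
    return dataclasses.replace(
        point, ci_low=float(lo), ci_high=float(hi), B=B, seed=seed_int
    )


# ---------------------------------------------------------------------------
# stratified reporting
# ---------------------------------------------------------------------------


@dataclass
class StratumRow:
    axis: str
    label: str
    n: int
    pct: float
    icc: ICCResult | None
    cv: float | None = None
    cv_lo: float | None = None
    cv_hi: float | None = None
    modd: float | None = None
    modd_lo: float | None = None
    modd_hi: float | None = None
    flagged: bool = False  # too few subjects for an estimate


@dataclass
class StratifiedICCTable:
    rows: list[StratumRow] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            recs.append(
                {
                    "axis": r.axis,
                    "stratum": r.label,
                    "n": r.n,
                    "pct": r.pct,
                    "icc": r.icc.icc if r.icc else np.nan,
                    "ci_low": r.icc.ci_low if r.icc else np.nan,
                    "ci_high": r.icc.ci_high if r.icc else np.nan,
                    "cv": r.cv,
                    "cv_lo": r.cv_lo,
                    "cv_hi": r.cv_hi,
                    "modd": r.modd,
                    "modd_lo": r.modd_lo,
                    "modd_hi": r.modd_hi,
                    "modd_mmoll": None if r.modd is None else r.modd / MGDL_PER_MMOLL,
                    "flagged": r.flagged,
                }
            )
        return pd.DataFrame(recs)


def _subject_label(series: SubjectSeries, axis: str) -> str | None:
    if axis == "status":
        return series.status.value if series.status is not None else None
    if series.covariates is None:
        return None
    if axis == "sex":
        return series.covariates.sex.value
    labels = _cohort.assign_strata(series.covariates)
    return getattr(labels, axis)


def _mean_boot_ci(values: np.ndarray, B: int, rng: np.random.Generator):
    """Percentile bootstrap CI for a mean of subject-level values."""
    m = values.size
    if m == 0:
        return None, None, None
    idx = rng.integers(0, m, size=(B, m))
    means = values[idx].mean(axis=1)
    lo, hi = np.percentile(means, [2.5, 97.5])
    return float(values.mean()), float(lo), float(hi)


def stratified_report(
    cohort: Sequence[SubjectSeries],
    axes: Sequence[str],
    B: int = 1000,
    seed: int = 0,
    demean_by_day: bool = False,
    cv_mode: str = "pooled",
    min_subjects: int = 2,
) -> StratifiedICCTable:
    """ICC, group CV and group MODD (with subject-level bootstrap percentile
    CIs) for every stratum of every requested axis.

    Group CV/MODD are means of subject-level values; MODD averages exclude
    subjects with no valid consecutive-day pairs. Strata with fewer than
    ``min_subjects`` subjects are flagged and carry no estimates. The single
    integer ``seed`` drives one reproducible stream spawned per stratum in
    deterministic axis/label order.
    """
    var = {s.subject_id: subject_variability(s, cv_mode=cv_mode) for s in cohort}
    root = np.random.SeedSequence(seed)
    table = StratifiedICCTable()
    n_total = len(cohort)
    stream_pos = 0  # deterministic position over axis x canonical label order
    for axis in axes:
        if axis not in _cohort.AXIS_LEVELS:
            raise ValueError(f"unknown stratification axis {axis!r}")
        groups: dict[str, list[SubjectSeries]] = {}
        for s in cohort:
            lab = _subject_label(s, axis)
            if lab is not None:
                groups.setdefault(lab, []).append(s)
        for label in _cohort.AXIS_LEVELS[axis]:
            stream_pos += 1
            members = groups.get(label)
            if not members:
                continue
            child = np.random.SeedSequence(entropy=root.entropy, spawn_key=(stream_pos,))
            rng = np.random.default_rng(child)
            row = StratumRow(
                axis=axis, label=label, n=len(members), pct=100.0 * len(members) / n_total,
                icc=None,
            )
            if len(members) < min_subjects:
                row.flagged = True
                table.rows.append(row)
                continue
            panel = build_panel(members)
            row.icc = bootstrap_ci(panel, B=B, seed=rng, demean_by_day=demean_by_day)
            cvs = np.array([var[s.subject_id].cv for s in members], float)
            row.cv, row.cv_lo, row.cv_hi = _mean_boot_ci(cvs, B, rng)
            modds = np.array(
                [var[s.subject_id].modd for s in members if var[s.subject_id].modd is not None],
                float,
            )
            row.modd, row.modd_lo, row.modd_hi = _mean_boot_ci(modds, B, rng)
            table.rows.append(row)
    return table
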