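"""Synthetic CGM cohorts with a known (closed-form) true functional ICC.

The generator emulates the study design the pipeline targets: a free-living
adult cohort split into three glycaemic-status groups, each subject wearing
a blinded sensor for 6 calendar days (day 0 is the insertion day that QC
later drops) sampled on the 288-slot grid, with at least 3 daily calibration
fingersticks and paired capillary points carrying multiplicative sensor
error.

Curves follow the multilevel functional model

    Y_ij(t) = m_g(t) + eta_i(t) + eps_ij(t) + w_ij(t),

with a group mean m_g (smooth baseline plus Gaussian meal excursions),
subject effect eta_i = sum_k a_ik phi_k, day effect eps_ij = sum_k b_ijk
phi_k on a basis orthonormal on the grid, and white measurement noise w.
Because the basis is grid-orthonormal the true traces are exact:

    tr K_eta = sum_k sigma_between_k^2
    tr K_eps = sum_k sigma_within_k^2 + p * sigma_noise^2

(white noise varies day to day, so it is charged to the within component),
and the true ICC is their ratio — which parameter-recovery tests can use as
exact ground truth. Missing gaps are carved *after* the truth is recorded,
so QC behaviour is testable against known planted gaps.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import GlycemicStatus, classify_status
from .ficc import CurvePanel
from .ingest_qc import MINUTES_PER_DAY, SENSOR_RANGE, SLOT_MINUTES, SLOTS_PER_DAY

GROUP_ORDER = ("normoglycaemia", "prediabetes", "diabetes")


@dataclass(frozen=True)
class MealBump:
    """One Gaussian meal excursion: peak time (min after midnight), peak
    amplitude (mg/dL) and width (Gaussian SD, min)."""

    peak_min: float
    amplitude: float
    width_min: float


#: breakfast / lunch / dinner excursions shared by all groups
DEFAULT_BUMPS = (
    MealBump(480.0, 40.0, 45.0),
    MealBump(840.0, 50.0, 45.0),
    MealBump(1260.0, 45.0, 45.0),
)

#: per-basis day-level SDs (mg/dL on grid-orthonormal coefficients); the
#: implied pointwise within-day SD is ~10 mg/dL for the reference group
BASE_SIGMA_WITHIN = (110.0, 85.0, 65.0, 50.0, 40.0, 32.0, 26.0, 20.0)

#: group baselines echo the fasting levels of the three status groups
DEFAULT_BASELINES = {"normoglycaemia": 85.0, "prediabetes": 100.0, "diabetes": 134.0}

#: glycaemic variability grows with dysglycaemia; within-day SDs are scaled
DEFAULT_WITHIN_SCALE = {"normoglycaemia": 1.0, "prediabetes": 1.1, "diabetes": 2.0}

#: generator setpoints for the groups' true ICCs (reproducibility ordering
#: diabetes > prediabetes > normoglycaemia)
DEFAULT_TARGET_ICC = {"normoglycaemia": 0.30, "prediabetes": 0.37, "diabetes": 0.46}

DEFAULT_N_PER_GROUP = {"normoglycaemia": 390, "prediabetes": 121, "diabetes": 70}


@dataclass
class GroupParams:
    baseline: float
    sigma_between: np.ndarray  # (K,)
    sigma_within: np.ndarray  # (K,)

    def __post_init__(self) -> None:
        self.sigma_between = np.asarray(self.sigma_between, float)
        self.sigma_within = np.asarray(self.sigma_within, float)
        if (self.sigma_between < 0).any() or (self.sigma_within < 0).any():
            raise ValueError("sigmas must be non-negative")


@dataclass
class SimConfig:
    """Full generator configuration; ``seed`` is mandatory and controls every
    random draw, so identical configs give bit-identical cohorts."""

    seed: int
    n_per_group: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_N_PER_GROUP))
    n_days: int = 6  # calendar days 0..5; day 0 is dropped by QC
    p: int = SLOTS_PER_DAY
    K: int = 8
    bumps: tuple[MealBump, ...] = DEFAULT_BUMPS
    groups: dict[str, GroupParams] = field(default_factory=dict)
    sigma_noise: float = 3.0
    gap_prob: float = 0.3  # per subject-day probability of one planted gap
    gap_len_range: tuple[int, int] = (2, 36)  # slots, uniform; >24 triggers QC drop
    fingersticks_per_day: int = 3
    fingerstick_times: tuple[int, ...] = (450, 810, 1230)  # 07:30, 13:30, 20:30
    fingerstick_jitter_min: int = 30
    sensor_error_cv: float = 0.10  # relative SD of capillary vs sensor curve

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.K > self.p:
            raise ValueError("K must not exceed p")


@dataclass
class GroupTruth:
    trace_between: float
    trace_within: float
    icc: float


@dataclass
class SimTruth:
    """Closed-form ground truth implied by a :class:`SimConfig` (exact
    because the basis is orthonormal on the grid)."""

    per_group: dict[str, GroupTruth]
    sigma_noise: float
    p: int

    def to_dict(self) -> dict:
        return {
            "per_group": {g: dataclasses.asdict(t) for g, t in self.per_group.items()},
            "sigma_noise": self.sigma_noise,
            "p": self.p,
        }


def orthonormal_basis(p: int, K: int) -> np.ndarray:
    """Deterministic p x K basis with columns exactly orthonormal on the grid
    (constant function first, then Fourier pairs, grid-orthonormalised)."""
    if K > p:
        raise ValueError(f"K={K} exceeds grid size p={p}")
    t = (np.arange(p) + 0.5) / p
    cols = [np.ones(p)]
    f = 1
    while len(cols) < K:
        cols.append(np.cos(2 * np.pi * f * t))
        if len(cols) < K:
            cols.append(np.sin(2 * np.pi * f * t))
        f += 1
    Q, R = np.linalg.qr(np.column_stack(cols))
    return Q * np.sign(np.diag(R))


def mean_curve(p: int, baseline: float, bumps: Sequence[MealBump] = DEFAULT_BUMPS) -> np.ndarray:
    """Smooth diurnal mean: flat baseline plus Gaussian meal excursions."""
    t = np.arange(p) * (MINUTES_PER_DAY / p) + 0.5 * (MINUTES_PER_DAY / p)
    m = np.full(p, float(baseline))
    for b in bumps:
        m += b.amplitude * np.exp(-0.5 * ((t - b.peak_min) / b.width_min) ** 2)
    return m


def group_truth(params: GroupParams, sigma_noise: float, p: int) -> GroupTruth:
    tb = float((params.sigma_between**2).sum())
    tw = float((params.sigma_within**2).sum() + p * sigma_noise**2)
    if tb + tw == 0:
        raise ValueError("both variance traces are zero; true ICC undefined")
    return GroupTruth(tb, tw, tb / (tb + tw))


def true_icc(cfg: SimConfig) -> SimTruth:
    return SimTruth(
        per_group={g: group_truth(pr, cfg.sigma_noise, cfg.p) for g, pr in cfg.groups.items()},
        sigma_noise=cfg.sigma_noise,
        p=cfg.p,
    )


def solve_between_scale(
    target_icc: float, trace_between: float, trace_within: float
) -> float:
    """Factor c such that scaling the between SDs by c gives the target
    trace ratio: c^2 tb / (c^2 tb + tw) = target."""
    if not 0 < target_icc < 1:
        raise ValueError("target ICC must lie strictly in (0, 1)")
    if trace_between <= 0 or trace_within <= 0:
        raise ValueError("both traces must be positive to solve for a scale")
    return float(np.sqrt(target_icc * trace_within / ((1 - target_icc) * trace_between)))


def solve_scales_for_icc(
    target: float | Mapping[str, float], cfg: SimConfig
) -> SimConfig:
    """Return a config whose between-subject SDs are uniformly rescaled so the
    closed-form true ICC equals ``target`` (per group when a mapping)."""
    targets = {g: target for g in cfg.groups} if np.isscalar(target) else dict(target)
    groups = {}
    for g, pr in cfg.groups.items():
        if g in targets:
            tr = group_truth(pr, cfg.sigma_noise, cfg.p)
            c = solve_between_scale(targets[g], tr.trace_between, tr.trace_within)
            pr = GroupParams(pr.baseline, pr.sigma_between * c, pr.sigma_within.copy())
        groups[g] = pr
    return dataclasses.replace(cfg, groups=groups)


def default_config(
    seed: int,
    n_per_group: Mapping[str, int] | None = None,
    target_icc: Mapping[str, float] | None = None,
    **overrides,
) -> SimConfig:
    """Study-condition defaults: cohort sizes 390/121/70, six days on the
    288-slot grid, and group true ICCs set to 0.30 / 0.37 / 0.46."""
    cfg = SimConfig(
        seed=seed,
        n_per_group=dict(n_per_group or DEFAULT_N_PER_GROUP),
        **overrides,
    )
    base_w = np.array(BASE_SIGMA_WITHIN[: cfg.K])
    cfg.groups = {
        g: GroupParams(
            baseline=DEFAULT_BASELINES[g],
            sigma_between=base_w.copy(),  # rescaled below to the target ratio
            sigma_within=base_w * DEFAULT_WITHIN_SCALE[g],
        )
        for g in GROUP_ORDER
        if cfg.n_per_group.get(g, 0) > 0
    }
    return solve_scales_for_icc(dict(target_icc or DEFAULT_TARGET_ICC), cfg)


# ---------------------------------------------------------------------------
# curve simulation
# ---------------------------------------------------------------------------


def simulate_curves(
    n_subjects: int,
    n_days: int,
    params: GroupParams,
    sigma_noise: float,
    rng: np.random.Generator,
    p: int = SLOTS_PER_DAY,
    K: int = 8,
    bumps: Sequence[MealBump] = DEFAULT_BUMPS,
    clamp: bool = True,
) -> tuple[np.ndarray, int]:
    """Draw an (n_subjects, n_days, p) array of curves from the multilevel
    model; returns the curves and the number of clamped grid values."""
    phi = orthonormal_basis(p, K)
    m = mean_curve(p, params.baseline, bumps)
    a = rng.normal(size=(n_subjects, K)) * params.sigma_between[:K]
    b = rng.normal(size=(n_subjects, n_days, K)) * params.sigma_within[:K]
    noise = rng.normal(size=(n_subjects, n_days, p)) * sigma_noise
    curves = m[None, None, :] + (a @ phi.T)[:, None, :] + b @ phi.T + noise
    n_clamped = 0
    if clamp:
        lo, hi = SENSOR_RANGE
        n_clamped = int(((curves < lo) | (curves > hi)).sum())
        np.clip(curves, lo, hi, out=curves)
    return curves, n_clamped


def simulate_panel(
    n_subjects: int,
    n_days: int,
    true_icc: float,
    seed: int | np.random.Generator,
    p: int = SLOTS_PER_DAY,
    K: int = 8,
    baseline: float = 85.0,
    sigma_within: Sequence[float] | None = None,
    sigma_noise: float = 3.0,
    clamp: bool = False,
) -> CurvePanel:
    """Convenience generator: a complete balanced panel whose closed-form true
    ICC equals ``true_icc`` exactly (no missingness, no QC needed).

    Clamping is off by default so the ground truth is not perturbed.
    """
    rng = np.random.default_rng(seed)
    sw = np.array(sigma_within if sigma_within is not None else BASE_SIGMA_WITHIN[:K], float)
    params = GroupParams(baseline, sw.copy(), sw)
    tr = group_truth(params, sigma_noise, p)
    c = solve_between_scale(true_icc, tr.trace_between, tr.trace_within)
    params = GroupParams(baseline, sw * c, sw)
    curves, _ = simulate_curves(
        n_subjects, n_days, params, sigma_noise, rng, p=p, K=K, clamp=clamp
    )
    Y = curves.reshape(n_subjects * n_days, p)
    subject_index = np.repeat(np.arange(n_subjects), n_days)
    grid = np.arange(p) * (MINUTES_PER_DAY / p)
    return CurvePanel(Y=Y, subject_index=subject_index, grid=grid)


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------

# group-level covariate distributions (mean, SD) echoing the three status
# groups of the emulated cohort; values are clipped into each group's
# ADA-consistent region so classify_status always recovers the group
_COV_PARAMS = {
    "normoglycaemia": dict(age=(43, 13), bmi=(26.7, 4.6), fpg=(84, 8), a1c=(5.2, 0.2), male=0.35),
    "prediabetes": dict(age=(57, 12), bmi=(31.1, 4.8), fpg=(100, 10), a1c=(5.7, 0.3), male=0.40),
    "diabetes": dict(age=(61, 12), bmi=(31.2, 5.1), fpg=(134, 35), a1c=(7.1, 1.2), male=0.50),
}


def _draw_covariates(
    group: str, subject_ids: Sequence[str], rng: np.random.Generator
) -> pd.DataFrame:
    pr = _COV_PARAMS[group]
    n = len(subject_ids)
    male = rng.random(n) < pr["male"]
    age = np.clip(rng.normal(*pr["age"], n), 18, 87)
    bmi = np.clip(rng.normal(*pr["bmi"], n), 17, 55)
    height = np.where(male, rng.normal(1.75, 0.07, n), rng.normal(1.62, 0.07, n))
    weight = bmi * height**2
    fpg = rng.normal(*pr["fpg"], n)
    a1c = rng.normal(*pr["a1c"], n)
    prior_dx = np.zeros(n, dtype=bool)
    if group == "normoglycaemia":
        fpg = np.clip(fpg, 60.0, 99.0)
        a1c = np.clip(a1c, 4.2, 5.6)
    elif group == "prediabetes":
        fpg = np.clip(fpg, 80.0, 125.0)
        a1c = np.clip(a1c, 5.0, 6.4)
        # need at least one analyte in the prediabetes band
        neither = (fpg < 100) & (a1c < 5.7)
        fpg = np.where(neither, rng.uniform(100, 125, n), fpg)
    else:  # diabetes: previously diagnosed, analytes clipped high enough
        prior_dx[:] = True
        fpg = np.clip(fpg, 80.0, 320.0)
        a1c = np.clip(a1c, 5.5, 12.0)

    alco_kind = rng.random(n)
    alcohol = np.where(
        alco_kind < 0.39, 0.0, np.where(alco_kind < 0.90, rng.uniform(1, 140, n), rng.uniform(141, 400, n))
    )
    smoking = rng.choice(["non", "ex", "current"], size=n, p=[0.50, 0.25, 0.25])
    activity = rng.choice(
        ["inactive", "minimally_active", "hepa"], size=n, p=[0.36, 0.38, 0.26]
    )
    meals = rng.choice([2, 3, 4, 5, 6], size=n, p=[0.21, 0.42, 0.26, 0.08, 0.03])
    kcal = np.clip(rng.normal(2100, 500, n), 1200, 4000)
    carb = np.clip(rng.normal(49, 5, n), 30, 70)

    df = pd.DataFrame(
        {
            "subject_id": list(subject_ids),
            "age": np.round(age, 1),
            "sex": np.where(male, "male", "female"),
            "weight_kg": np.round(weight, 1),
            "height_m": np.round(height, 3),
            "fpg_mgdl": np.round(fpg, 1),
            "a1c_pct": np.round(a1c, 2),
            "prior_dx": prior_dx,
            "alcohol_g_wk": np.round(alcohol, 1),
            "smoking": smoking,
            "activity": activity,
            "meals_day": meals,
            "kcal_day": np.round(kcal, 0),
            "carb_pct": np.round(carb, 1),
        }
    )
    # safety: the drawn analytes must classify back into the intended group
    for row in df.itertuples(index=False):
        got = classify_status(a1c=row.a1c_pct, fpg=row.fpg_mgdl, prior_dx=bool(row.prior_dx))
        assert got == GlycemicStatus(group), (row.subject_id, got, group)
    return df


# ---------------------------------------------------------------------------
# full cohort simulation
# ---------------------------------------------------------------------------


@dataclass
class SimResult:
    """Everything the pipeline ingests plus the generator's ground truth."""

    cgm: pd.DataFrame  # canonical long format
    fingersticks: pd.DataFrame
    covariates: pd.DataFrame
    paired: pd.DataFrame  # subject_id, day, sensor_mgdl, capillary_mgdl
    truth: SimTruth
    config: SimConfig
    n_clamped: int
    n_grid_values: int

    @property
    def clamp_fraction(self) -> float:
        return self.n_clamped / max(self.n_grid_values, 1)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "cgm": out / "cgm.csv",
            "fingersticks": out / "fingersticks.csv",
            "covariates": out / "covariates.csv",
            "paired": out / "paired_points.csv",
            "sim_truth": out / "sim_truth.json",
        }
        self.cgm.to_csv(paths["cgm"], index=False)
        self.fingersticks.to_csv(paths["fingersticks"], index=False)
        self.covariates.to_csv(paths["covariates"], index=False)
        self.paired.to_csv(paths["paired"], index=False)
        truth = self.truth.to_dict()
        truth["clamp_fraction"] = self.clamp_fraction
        paths["sim_truth"].write_text(json.dumps(truth, indent=2))
        return paths


def simulate_cohort(cfg: SimConfig) -> SimResult:
    """Generate a full synthetic cohort: CGM long-format readings with
    planted gaps, calibration fingersticks, covariates consistent with each
    group's ADA classification, and paired capillary points."""
    if not cfg.groups:
        raise ValueError("config has no groups; use default_config()")
    rng = np.random.default_rng(cfg.seed)
    truth = true_icc(cfg)

    cgm_parts, stick_rows, paired_rows, cov_parts = [], [], [], []
    n_clamped = 0
    n_grid = 0
    counter = 0
    slot_minutes = MINUTES_PER_DAY // cfg.p
    for group in GROUP_ORDER:
        if group not in cfg.groups or cfg.n_per_group.get(group, 0) == 0:
            continue
        n_g = cfg.n_per_group[group]
        ids = [f"S{counter + i + 1:04d}" for i in range(n_g)]
        counter += n_g
        curves, nc = simulate_curves(
            n_g, cfg.n_days, cfg.groups[group], cfg.sigma_noise, rng,
            p=cfg.p, K=cfg.K, bumps=cfg.bumps,
        )
        n_clamped += nc
        n_grid += curves.size
        cov_parts.append(_draw_covariates(group, ids, rng))

        # planted missingness (after truth recording)
        keep = np.ones((n_g, cfg.n_days, cfg.p), dtype=bool)
        has_gap = rng.random((n_g, cfg.n_days)) < cfg.gap_prob
        lo, hi = cfg.gap_len_range
        for i in range(n_g):
            for d in range(cfg.n_days):
                if has_gap[i, d]:
                    length = int(rng.integers(lo, hi + 1))
                    start = int(rng.integers(0, cfg.p - length + 1))
                    keep[i, d, start : start + length] = False

        slots = np.arange(cfg.p)
        for i, sid in enumerate(ids):
            for d in range(cfg.n_days):
                k = keep[i, d]
                ts = d * MINUTES_PER_DAY + slots[k] * slot_minutes
                cgm_parts.append(
                    pd.DataFrame(
                        {
                            "subject_id": sid,
                            "timestamp_min": ts.astype(np.int64),
                            "glucose_mgdl": np.round(curves[i, d, k], 1),
                        }
                    )
                )
                # fingersticks + paired points (sensor value from the true,
                # gap-free curve: the meter reading happened regardless)
                for t0 in cfg.fingerstick_times[: cfg.fingersticks_per_day]:
                    jit = int(rng.integers(-cfg.fingerstick_jitter_min, cfg.fingerstick_jitter_min + 1))
                    tmin = int(np.clip(t0 + jit, 0, MINUTES_PER_DAY - 1))
                    slot = tmin // slot_minutes
                    sensor = float(curves[i, d, slot])
                    capillary = sensor * (1.0 + rng.normal(0.0, cfg.sensor_error_cv))
                    capillary = float(np.clip(capillary, 20.0, 600.0))
                    stick_rows.append((sid, d * MINUTES_PER_DAY + tmin, round(capillary, 1)))
                    paired_rows.append((sid, d, round(sensor, 1), round(capillary, 1)))

    cgm = pd.concat(cgm_parts, ignore_index=True)
    fingersticks = pd.DataFrame(
        stick_rows, columns=["subject_id", "timestamp_min", "glucose_mgdl"]
    )
    paired = pd.DataFrame(
        paired_rows, columns=["subject_id", "day", "sensor_mgdl", "capillary_mgdl"]
    )
    covariates = pd.concat(cov_parts, ignore_index=True)
    return SimResult(
        cgm=cgm,
        fingersticks=fingersticks,
        covariates=covariates,
        paired=paired,
        truth=truth,
        config=cfg,
        n_clamped=n_clamped,
        n_grid_values=n_grid,
    )
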