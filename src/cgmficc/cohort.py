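"""Cohort covariates, ADA glycaemic status, and stratification labels.

Glycaemic status follows the American Diabetes Association criteria applied
to DCCT-aligned A1C (%) and fasting plasma glucose (mg/dL), with a prior
clinical diagnosis overriding: diabetes if previously diagnosed, A1C > 6.4 %
or FPG > 125 mg/dL; prediabetes if A1C in [5.7, 6.4] % or FPG in
[100, 125] mg/dL; normoglycaemia otherwise. The three outcomes partition the
(A1C, FPG, diagnosis) space and are monotone in both analytes.

Stratification axes mirror the report tables: age group, BMI class
(normal < 25, overweight 25-30, obese > 30 kg/m^2), alcohol class
(abstainer < 1, light 1-140, heavy > 140 g/week), smoking, IPAQ activity
class (taken as a given label, not re-scored), meals per day, calorie and
carbohydrate intake.
"""
from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

logger = logging.getLogger(__name__)

COVARIATE_COLUMNS = (
    "subject_id",
    "age",
    "sex",
    "weight_kg",
    "height_m",
    "fpg_mgdl",
    "a1c_pct",
    "prior_dx",
    "alcohol_g_wk",
    "smoking",
    "activity",
    "meals_day",
    "kcal_day",
    "carb_pct",
)


class GlycemicStatus(enum.Enum):
    NORMO = "normoglycaemia"
    PREDIABETES = "prediabetes"
    DIABETES = "diabetes"


class Sex(enum.Enum):
    FEMALE = "female"
    MALE = "male"


class Smoking(enum.Enum):
    NON = "non"
    EX = "ex"
    CURRENT = "current"


class Activity(enum.Enum):
    INACTIVE = "inactive"
    MINIMAL = "minimally_active"
    HEPA = "hepa"


@dataclass
class CovariateRecord:
    """Per-subject covariates (units in field names where not obvious).

    ``fpg_mgdl`` is fasting plasma glucose; ``a1c_pct`` is DCCT-aligned
    glycated haemoglobin. Lifestyle fields may be missing (``None``); the
    corresponding stratum label is then absent.
    """

    subject_id: str
    age: float
    sex: Sex
    weight_kg: float | None
    height_m: float | None
    fpg_mgdl: float
    a1c_pct: float
    prior_diabetes_dx: bool = False
    alcohol_g_per_week: float | None = None
    smoking: Smoking | None = None
    activity: Activity | None = None
    meals_per_day: int | None = None
    kcal_per_day: float | None = None
    carb_pct: float | None = None
    homa_ir: float | None = None  # carried, never computed here

    def __post_init__(self) -> None:
        if isinstance(self.sex, str):
            self.sex = Sex(self.sex)
        if isinstance(self.smoking, str):
            self.smoking = Smoking(self.smoking)
        if isinstance(self.activity, str):
            self.activity = Activity(self.activity)


@dataclass(frozen=True)
class StratumLabels:
    """One deterministic label per stratification axis (None where the
    underlying covariate is missing)."""

    age_group: str | None = None
    bmi_class: str | None = None
    alcohol_class: str | None = None
    smoking_class: str | None = None
    activity_class: str | None = None
    meals_class: str | None = None
    kcal_class: str | None = None
    carb_class: str | None = None


#: canonical row order of each stratification axis in reports
AXIS_LEVELS: dict[str, tuple[str, ...]] = {
    "sex": ("female", "male"),
    "status": ("normoglycaemia", "prediabetes", "diabetes"),
    "age_group": ("18-39", "40-59", "60-81"),
    "bmi_class": ("normal", "overweight", "obese"),
    "alcohol_class": ("abstainer", "light", "heavy"),
    "smoking_class": ("non", "ex", "current"),
    "activity_class": ("inactive", "minimally_active", "hepa"),
    "meals_class": ("2-3", "4", "5+"),
    "kcal_class": ("<2000", "2000-2500", "2500+"),
    "carb_class": ("<45", "45-54", "55+"),
}


def bmi(weight_kg: float, height_m: float) -> float:
    """Body mass index, weight (kg) / height (m) squared."""
    if not height_m > 0:
        raise ValueError(f"height must be positive, got {height_m}")
    return weight_kg / height_m**2


def classify_status(
    cov: CovariateRecord | None = None,
    *,
    a1c: float | None = None,
    fpg: float | None = None,
    prior_dx: bool = False,
) -> GlycemicStatus:
    """ADA glycaemic status from A1C (%), FPG (mg/dL) and prior diagnosis.

    Diabetes rules use strict inequalities (A1C > 6.4, FPG > 125), so the
    boundary values fall to prediabetes; the prediabetes intervals are
    inclusive on both ends.
    """
    if cov is not None:
        a1c, fpg, prior_dx = cov.a1c_pct, cov.fpg_mgdl, cov.prior_diabetes_dx
    if a1c is None or fpg is None or pd.isna(a1c) or pd.isna(fpg):
        raise ValueError("classify_status requires both a1c and fpg")
    if prior_dx or a1c > 6.4 or fpg > 125:
        return GlycemicStatus.DIABETES
    if 5.7 <= a1c <= 6.4 or 100 <= fpg <= 125:
        return GlycemicStatus.PREDIABETES
    return GlycemicStatus.NORMO


def _age_group(age: float) -> str:
    if age < 40:
        return "18-39"
    if age < 60:
        return "40-59"
    return "60-81"


def _bmi_class(b: float) -> str:
    if b < 25:
        return "normal"
    if b <= 30:
        return "overweight"
    return "obese"


def _alcohol_class(g_per_week: float) -> str:
    # abstainers and very occasional drinkers (< 1 g/week) pooled
    if g_per_week < 1:
        return "abstainer"
    if g_per_week <= 140:
        return "light"
    return "heavy"


def _meals_class(meals: int) -> str:
    if meals <= 3:
        return "2-3"
    if meals == 4:
        return "4"
    return "5+"


def _kcal_class(kcal: float) -> str:
    if kcal < 2000:
        return "<2000"
    if kcal < 2500:
        return "2000-2500"
    return "2500+"


def _carb_class(carb: float) -> str:
    if carb < 45:
        return "<45"
    if carb < 55:
        return "45-54"
    return "55+"


def assign_strata(cov: CovariateRecord) -> StratumLabels:
    """Map a covariate record to its stratification labels.

    Missing covariates yield ``None`` for the affected axis (logged at DEBUG);
    every present covariate maps to exactly one label.
    """

    def have(x) -> bool:
        return x is not None and not pd.isna(x)

    labels: dict[str, str | None] = {}
    labels["age_group"] = _age_group(cov.age) if have(cov.age) else None
    if have(cov.weight_kg) and have(cov.height_m):
        labels["bmi_class"] = _bmi_class(bmi(cov.weight_kg, cov.height_m))
    else:
        labels["bmi_class"] = None
    labels["alcohol_class"] = (
        _alcohol_class(cov.alcohol_g_per_week) if have(cov.alcohol_g_per_week) else None
    )
    labels["smoking_class"] = cov.smoking.value if cov.smoking is not None else None
    labels["activity_class"] = cov.activity.value if cov.activity is not None else None
    labels["meals_class"] = _meals_class(int(cov.meals_per_day)) if have(cov.meals_per_day) else None
    labels["kcal_class"] = _kcal_class(cov.kcal_per_day) if have(cov.kcal_per_day) else None
    labels["carb_class"] = _carb_class(cov.carb_pct) if have(cov.carb_pct) else None
    for axis, lab in labels.items():
        if lab is None:
            logger.debug("subject %s: no %s label (missing covariate)", cov.subject_id, axis)
    return StratumLabels(**labels)


def read_covariates(path: str | Path) -> dict[str, CovariateRecord]:
    """Read the canonical covariate CSV into records keyed by subject id."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"covariate file not found: {path}")
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = set(COVARIATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing covariate columns {sorted(missing)}")
    out: dict[str, CovariateRecord] = {}
    for row in df.itertuples(index=False):
        rec = covariate_from_mapping(row._asdict())
        out[rec.subject_id] = rec
    return out


def covariate_from_mapping(d: Mapping) -> CovariateRecord:
    def opt(key, cast=float):
        v = d.get(key)
        if v is None or (isinstance(v, float) and pd.isna(v)) or v == "":
            return None
        return cast(v)

    return CovariateRecord(
        subject_id=str(d["subject_id"]),
        age=float(d["age"]),
        sex=Sex(str(d["sex"])),
        weight_kg=opt("weight_kg"),
        height_m=opt("height_m"),
        fpg_mgdl=float(d["fpg_mgdl"]),
        a1c_pct=float(d["a1c_pct"]),
        prior_diabetes_dx=bool(d.get("prior_dx", False)),
        alcohol_g_per_week=opt("alcohol_g_wk"),
        smoking=opt("smoking", Smoking),
        activity=opt("activity", Activity),
        meals_per_day=opt("meals_day", int),
        kcal_per_day=opt("kcal_day"),
        carb_pct=opt("carb_pct"),
        homa_ir=opt("homa_ir"),
    )
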