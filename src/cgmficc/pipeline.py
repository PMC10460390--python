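"""End-to-end reproducible pipeline: ingest/QC -> cohort labels -> metrics ->
functional ICC -> report tables.

Outputs written to the run directory:

* ``qc_report.json`` — every day/subject dropped, by rule;
* ``table1.csv`` — per-status covariate and variability summary (means, SD);
* ``icc_by_status.csv`` — functional ICC with bootstrap 95 % CI per group;
* ``table2.csv`` — stratified ICC/CV/MODD with CIs (normoglycaemic subjects
  by default, matching the report the pipeline emulates);
* ``variability.csv`` — tidy per-subject CV/MODD;
* ``mard.csv`` — sensor accuracy overall, by range, by day, agreement rates;
* ``manifest.json`` — package version, config, seed and a config hash, from
  which the whole run can be regenerated.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    CovariateRecord,
    GlycemicStatus,
    bmi,
    classify_status,
    read_covariates,
    covariate_from_mapping,
)
from .ficc import bootstrap_ci, build_panel, stratified_report
from .ingest_qc import QCRules, SubjectSeries, apply_qc, grid_cohort, read_cgm_frame, _read_long_csv
from .metrics import MGDL_PER_MMOLL, mard_report, read_paired_points, variability_table
from .simulate import SimConfig, default_config, simulate_cohort

logger = logging.getLogger(__name__)

DEFAULT_STRATA_AXES = (
    "sex",
    "age_group",
    "bmi_class",
    "alcohol_class",
    "smoking_class",
    "activity_class",
    "meals_class",
    "kcal_class",
    "carb_class",
)


@dataclass
class PipelineConfig:
    """Either ``simulate`` (generator settings) or ``inputs`` (paths to the
    four canonical CSVs) must be given — exactly one of the two."""

    out_dir: str | Path = "cgmficc_run"
    simulate: dict | None = None
    inputs: dict | None = None  # keys: cgm, fingersticks, covariates, paired
    qc: QCRules = field(default_factory=QCRules)
    bootstrap_B: int = 1000
    seed: int = 0
    demean_by_day: bool = False
    strata_axes: tuple[str, ...] = DEFAULT_STRATA_AXES
    table2_all_subjects: bool = False  # widen Table 2 beyond normoglycaemia
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError("exactly one of 'simulate' and 'inputs' must be configured")
        if isinstance(self.qc, Mapping):
            self.qc = QCRules.from_mapping(self.qc)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        d.update(overrides)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "strata_axes" in d:
            d["strata_axes"] = tuple(d["strata_axes"])
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(d["out_dir"])
        d["strata_axes"] = list(d["strata_axes"])
        return d


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _load_inputs(cfg: PipelineConfig):
    """Return (cgm frame, fingersticks frame, covariates dict, paired frame,
    truth-or-None)."""
    if cfg.simulate is not None:
        sim_kwargs = dict(cfg.simulate)
        sim_kwargs.setdefault("seed", cfg.seed)
        sim = simulate_cohort(default_config(**sim_kwargs))
        covs = {
            r["subject_id"]: covariate_from_mapping(r)
            for r in sim.covariates.to_dict("records")
        }
        return sim.cgm, sim.fingersticks, covs, sim.paired, sim
    paths = cfg.inputs
    for key in ("cgm", "fingersticks", "covariates", "paired"):
        if key not in paths:
            raise ValueError(f"inputs config is missing the '{key}' path")
        if not Path(paths[key]).exists():
            raise FileNotFoundError(f"{key} input file not found: {paths[key]}")
    cgm = read_cgm_frame(paths["cgm"], clamp=cfg.qc.clamp)
    sticks = _read_long_csv(paths["fingersticks"])
    covs = read_covariates(paths["covariates"])
    paired = read_paired_points(paths["paired"])
    return cgm, sticks, covs, paired, None


def _attach_covariates(
    series: Sequence[SubjectSeries], covs: Mapping[str, CovariateRecord]
) -> list[SubjectSeries]:
    out = []
    for s in series:
        cov = covs.get(s.subject_id)
        if cov is None:
            logger.warning("subject %s has no covariate record; excluded from cohort", s.subject_id)
            continue
        s.covariates = cov
        s.status = classify_status(cov)
        out.append(s)
    return out


def _table1(cohort: Sequence[SubjectSeries], var: pd.DataFrame) -> pd.DataFrame:
    var = var.set_index("subject_id")
    rows = []
    for status in GlycemicStatus:
        members = [s for s in cohort if s.status == status]
        if not members:
            continue
        covs = [s.covariates for s in members]
        ids = [s.subject_id for s in members]
        v = var.loc[ids]

        def ms(x):
            x = np.asarray(x, float)
            x = x[~np.isnan(x)]
            return (float(x.mean()), float(x.std(ddof=1))) if x.size > 1 else (float("nan"),) * 2

        males = sum(c.sex.value == "male" for c in covs)
        age = ms([c.age for c in covs])
        bmis = ms([bmi(c.weight_kg, c.height_m) for c in covs if c.weight_kg and c.height_m])
        fpg = ms([c.fpg_mgdl for c in covs])
        a1c = ms([c.a1c_pct for c in covs])
        cv = ms(v["cv_pct"])
        modd_mg = ms(v["modd_mgdl"])
        rows.append(
            {
                "status": status.value,
                "n": len(members),
                "males_n": males,
                "males_pct": 100.0 * males / len(members),
                "age_mean": age[0], "age_sd": age[1],
                "bmi_mean": bmis[0], "bmi_sd": bmis[1],
                "fpg_mean": fpg[0], "fpg_sd": fpg[1],
                "a1c_mean": a1c[0], "a1c_sd": a1c[1],
                "cv_mean": cv[0], "cv_sd": cv[1],
                "modd_mgdl_mean": modd_mg[0], "modd_mgdl_sd": modd_mg[1],
                "modd_mmoll_mean": modd_mg[0] / MGDL_PER_MMOLL,
                "modd_mmoll_sd": modd_mg[1] / MGDL_PER_MMOLL,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage and write the report bundle; returns the in-memory
    results keyed like the output files."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cgm, sticks, covs, paired, sim = _load_inputs(cfg)
    if sim is not None:
        sim.write(out / "simulated_inputs")
    logger.info("ingest: %d CGM rows, %d subjects with covariates", len(cgm), len(covs))

    curves = grid_cohort(cgm)
    series, qc_report = apply_qc(curves, sticks, cfg.qc)
    qc_report.to_json(out / "qc_report.json")

    cohort = _attach_covariates(series, covs)
    logger.info("cohort: %d subjects after QC and covariate matching", len(cohort))

    var = variability_table(cohort)
    var.to_csv(out / "variability.csv", index=False)

    table1 = _table1(cohort, var)
    table1.to_csv(out / "table1.csv", index=False)

    # per-status functional ICC with bootstrap CIs
    icc_rows = []
    ss = np.random.SeedSequence(cfg.seed)
    for i, status in enumerate(GlycemicStatus):
        members = [s for s in cohort if s.status == status]
        if len(members) < 2:
            continue
        panel = build_panel(members)
        res = bootstrap_ci(
            panel,
            B=cfg.bootstrap_B,
            seed=np.random.SeedSequence(entropy=ss.entropy, spawn_key=(1000 + i,)),
            demean_by_day=cfg.demean_by_day,
        )
        logger.info(
            "ICC[%s] = %.3f (95%% CI %.3f-%.3f, n=%d, %s agreement)",
            status.value, res.icc, res.ci_low, res.ci_high, res.n_subjects, res.agreement,
        )
        icc_rows.append(
            {
                "status": status.value,
                "n": res.n_subjects,
                "n_curves": res.n_curves,
                "icc": res.icc,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "agreement": res.agreement,
            }
        )
    icc_by_status = pd.DataFrame(icc_rows)
    icc_by_status.to_csv(out / "icc_by_status.csv", index=False)

    # stratified table (normoglycaemic subjects unless widened)
    table2_cohort = (
        cohort
        if cfg.table2_all_subjects
        else [s for s in cohort if s.status == GlycemicStatus.NORMO]
    )
    table2 = stratified_report(
        table2_cohort,
        axes=cfg.strata_axes,
        B=cfg.bootstrap_B,
        seed=cfg.seed,
        demean_by_day=cfg.demean_by_day,
    ).to_frame()
    table2.to_csv(out / "table2.csv", index=False)

    mard = mard_report(paired)
    mard_frame = _mard_frame(mard)
    mard_frame.to_csv(out / "mard.csv", index=False)

    manifest = {
        "package": "cgmficc",
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "config_hash": _config_hash(cfg),
        "n_subjects_retained": len(cohort),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    logger.info("report bundle written to %s", out)
    return {
        "qc_report": qc_report,
        "cohort": cohort,
        "table1": table1,
        "icc_by_status": icc_by_status,
        "table2": table2,
        "variability": var,
        "mard": mard,
        "manifest": manifest,
        "sim": sim,
        "out_dir": out,
    }


def _mard_frame(m) -> pd.DataFrame:
    rows = [{"cell": "overall", "mard_pct": m.overall_mard, "n": m.n_pairs}]
    for lab, val in m.mard_by_range.items():
        rows.append({"cell": f"range {lab}", "mard_pct": val, "n": m.n_by_range[lab]})
    for day, val in sorted(m.mard_by_day.items()):
        rows.append({"cell": f"day {day}", "mard_pct": val, "n": m.n_by_day[day]})
    rows.append({"cell": "within15mgdl_cap<100", "mard_pct": m.pct_within15_low, "n": m.n_low})
    rows.append({"cell": "within15pct_cap>=100", "mard_pct": m.pct_within15_high, "n": m.n_high})
    return pd.DataFrame(rows)


def plot_profiles(
    cohort: Sequence[SubjectSeries],
    subject_ids: Sequence[str],
    out_dir: str | Path,
) -> list[Path]:
    """Overlay each requested subject's retained daily curves (colour-coded by
    day) and save one PNG per subject."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    by_id = {s.subject_id: s for s in cohort}
    unknown = [sid for sid in subject_ids if sid not in by_id]
    if unknown:
        raise ValueError(f"unknown subject id(s): {unknown}")
    if not subject_ids:
        logger.warning("plot_profiles: empty subject list, nothing to plot")
        return []
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hours = np.arange(288) * 5 / 60.0
    paths = []
    for sid in subject_ids:
        series = by_id[sid]
        fig, ax = plt.subplots(figsize=(8, 4))
        cmap = plt.get_cmap("viridis")
        for k, curve in enumerate(series.day_curves):
            ax.plot(
                hours,
                curve.values,
                color=cmap(k / max(len(series.day_curves) - 1, 1)),
                label=f"day {curve.calendar_day}",
                lw=1.0,
            )
        ax.set(xlabel="hour of day", ylabel="glucose (mg/dL)", title=f"subject {sid}")
        ax.legend(fontsize=7)
        path = out / f"profile_{sid}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths
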