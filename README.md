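# cgmficc

Functional intraclass correlation analysis of continuous glucose monitoring
(CGM) curves.

## The problem

A subcutaneous CGM sensor records interstitial glucose every 5 minutes
(288 readings per day, hardware range 40–400 mg/dL) over a multi-day wear.
A natural clinical question is *reproducibility*: how similar is a person's
daily glucose curve from one day to the next? If a single monitored day
already characterises a subject, short wears suffice; if not, clinical
decisions need longer monitoring. `cgmficc` answers this from a functional
data analysis standpoint, treating each day's 288-point trace as one
functional observation, for cohorts spanning normoglycaemia, prediabetes and
diabetes (ADA criteria on A1C and fasting plasma glucose).

## The statistic

Daily curves follow a multilevel functional ANOVA

```
Y_ij(t) = μ(t) + η_i(t) + ε_ij(t)
```

with a subject-level random curve η_i (covariance operator K_η) and a
day-level deviation ε_ij (covariance K_ε). The functional intraclass
correlation coefficient is the trace ratio

```
ICC = tr(K_η) / (tr(K_η) + tr(K_ε))  ∈ [0, 1]
```

— the fraction of total day-to-day curve variation that is stable
between-subject signal (< 0.4 poor, 0.4–0.59 fair, 0.60–0.74 good, > 0.74
excellent agreement). Estimation is a method-of-moments one-way functional
ANOVA on traces that handles unbalanced designs (subjects keep different
numbers of days after quality control); 95 % confidence intervals come from
a subject-level (cluster) percentile bootstrap that resamples whole subjects
with all their days. The package also computes the standard
glycaemic-variability metrics (CV = 100·SD/mean; MODD = mean absolute
difference between readings 1440 min apart on consecutive days) and
sensor-accuracy summaries (MARD overall / by glycaemic range / by wear day,
and %-within-15 agreement rates).

Because real CGM study data of this kind are not publicly deposited, the
package ships a first-class synthetic cohort generator built on a
grid-orthonormal basis, so the between/within variance traces — and hence
the true ICC — are known in closed form and every pipeline stage is testable
against exact ground truth.

## Worked example

```python
from cgmficc import bootstrap_ci, estimate_ficc, simulate_panel

# 150 subjects x 5 days x 288 slots with known true ICC 0.46
panel = simulate_panel(n_subjects=150, n_days=5, true_icc=0.46, seed=2024)
point = estimate_ficc(panel)
res = bootstrap_ci(panel, B=1000, seed=5)
```

prints (`python examples/03_functional_icc.py`):

```
true ICC           : 0.46 (generator closed form)
estimated ICC      : 0.470  (fair agreement)
trace between      : 28,346 mg^2/dL^2 (summed over grid)
trace within       : 31,954 mg^2/dL^2
bootstrap 95% CI   : [0.431, 0.504]  (B=1000 subject resamples)
```

The estimate recovers the generator's exact truth (0.46) within sampling
error, and the CI — built by resampling whole subjects to respect
within-subject dependence — covers it. `examples/` contains three more
narrative scripts: cohort simulation with closed-form truth, QC accounting
plus CV/MODD/MARD, and the full stratified pipeline.

## Command line

```sh
cgmficc simulate --out data/ --seed 1          # synthetic cohort CSVs + truth
cgmficc run --config pipeline.yaml --out run/  # full pipeline -> report bundle
cgmficc report run/                            # print the headline tables
```

The pipeline writes `qc_report.json`, `table1.csv` (per-status cohort
summary), `icc_by_status.csv`, `table2.csv` (ICC/CV/MODD with CIs stratified
by demographics and lifestyle within the normoglycaemic group), `mard.csv`
and a `manifest.json` from which any run can be regenerated byte-identically.

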