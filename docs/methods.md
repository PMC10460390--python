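# Methods

## Data model and quality control

CGM records enter as long-format rows `(subject_id, timestamp_min,
glucose_mgdl)` with integer timestamps in minutes since the cohort epoch
(midnight of the sensor-insertion day). Each subject-day is discretised onto
a fixed 288-slot grid: slot `s` covers minutes `[5s, 5s+5)` of the local
calendar day (midnight-to-midnight convention, matching how daily dietary
totals are conventionally aggregated). Off-grid timestamps are floored to
the containing slot; multiple readings in one slot are averaged — a
deterministic, input-order-independent rule. Values outside the sensor's
hardware range 40–400 mg/dL are clamped to the nearest bound by default
(the deployed device cannot report outside this range); a switch drops them
instead.

Exclusion rules, in the order applied to each day:

1. **Insertion day** — calendar day 0 is discarded (sensor equilibration
   makes first-day readings systematically less accurate).
2. **Missing data** — a day whose missing slots total strictly more than 24
   (i.e. more than 2 h cumulative, not necessarily consecutive) is
   discarded.
3. **Calibration** — a day with fewer than 3 capillary fingersticks is
   discarded. Only the count is enforced; the device's internal
   recalibration of sensor values is not re-simulated.

Subjects retaining fewer than 2 days are excluded. Each dropped day is
tallied once under the first rule that hit it, so per subject
`days_in = retained + day1 + gap + calibration` exactly.

Retained days are completed before functional analysis: interior gaps are
linearly interpolated between the flanking observed slots, and runs touching
either day edge are filled with the nearest observed value. With at most 24
imputed slots on a 288-slot curve the imputation is bounded by the QC rule
itself. Observed values are never altered, and imputed values cannot leave
the day's observed [min, max]. The original observation mask is consumed by
this step (the imputed-slot count is kept); MODD therefore pairs slots on
the completed curves. Whether gap-filled or gap-restricted curves are the
better input to the ICC is genuinely open; interpolation was chosen because
the trace estimator needs complete grids and the bounded imputation error is
small against day-level variation.

## Cohort classification

ADA glycaemic status from DCCT-aligned A1C (%) and fasting plasma glucose
(mg/dL): **diabetes** if previously diagnosed, A1C > 6.4 or FPG > 125;
**prediabetes** if A1C ∈ [5.7, 6.4] or FPG ∈ [100, 125]; **normoglycaemia**
otherwise. The diabetes rules keep the strict inequalities of the printed
criteria, so the boundary values A1C = 6.4 and FPG = 125 classify as
prediabetes; the classification is total, mutually exclusive and monotone in
both analytes (property-tested). Stratum boundaries close half-open cases
toward the explicitly named interval: BMI 25 and 30 → overweight; alcohol
< 1 g/week → abstainer (pooling very occasional drinkers), [1, 140] → light,
> 140 → heavy; kcal 2500 → "2500+"; carbohydrate 45 % → "45–54". IPAQ
activity arrives as a given label and is not re-scored.

## Variability and accuracy metrics

* **CV** (%) = 100 × SD/mean with sample SD (n−1), pooled over all retained
  readings of a subject by default. The pooled form is the global formula;
  a `per_day_mean` mode (mean of daily CVs) is kept for sensitivity
  analysis.
* **MODD** (mg/dL) = mean of |BG_t − BG_{t−1440 min}| over the k slot pairs
  at identical clock slots on *consecutive* calendar days — the 1440-min lag
  taken literally, so days flanking a dropped day contribute no pairs and
  k = 0 flags the statistic undefined. Reports carry both mg/dL and mmol/L
  (÷ 18.016); clinical MODD values near 0.7–1.5 are mmol/L-scale.
* **MARD** (%) = mean of 100·|sensor − capillary|/capillary, overall, by
  capillary range (70 and 180 mg/dL assigned to the middle "70–180"
  stratum) and by wear day; agreement rates use |Δ| ≤ 15 mg/dL below a
  capillary of 100 mg/dL and relative ARD ≤ 15 % at or above, thresholds
  inclusive.

All three equal naive-loop reference implementations to 1e-10 relative
error on randomized fixtures.

## The trace-ratio ICC estimator

With n subjects, J_i retained curves for subject i, N = ΣJ_i, and sums over
the 288-slot grid (the constant quadrature weight cancels in the ratio):

```
tr̂_W = Σ_i Σ_j Σ_t (Y_ij(t) − Ȳ_i(t))² / (N − n)
MSB  = Σ_i J_i Σ_t (Ȳ_i(t) − μ̂(t))² / (n − 1)
c0   = (N − Σ_i J_i²/N) / (n − 1)
tr̂_B = max(0, (MSB − tr̂_W) / c0)
ICC  = tr̂_B / (tr̂_B + tr̂_W)
```

This is the unbalanced one-way ANOVA method of moments applied to traces.
In the balanced case it coincides exactly with the trace ratio of the
empirical moment estimators of K_η and K_ε (the estimator family used for
replicated functional/imaging data), which an independently coded
brute-force covariance oracle pins down in the tests. Truncating a negative
between-trace at zero keeps ICC ∈ [0, 1]; when both traces are zero (all
curves identical) the result is flagged degenerate (NaN). A
`demean_by_day` option subtracts the day-specific mean curve first (two-way
layout with a fixed visit effect); the default removes only the overall
mean, because nothing in the design ties a calendar day to a common cohort
event and the day-mean estimate at modest n adds noise. As a ratio
estimator the ICC carries a small finite-sample bias (downward at small n,
roughly −0.02 at n ≈ 30 under the default generator settings), vanishing at
study scale.

## Bootstrap confidence intervals

Subject-level (cluster) percentile bootstrap, default B = 1000: each
replicate draws n subjects with replacement, a duplicated subject entering
as a distinct cluster with all its curves, and re-applies the full
estimator; the CI is the 2.5th/97.5th percentile of the replicate ICCs.
Degenerate replicates are recorded as NaN and excluded from the
percentiles. The implementation works on per-subject sufficient statistics
(J_i, curve sums, squared norms), making each replicate O(n·p) and the
whole bootstrap a handful of matrix products; a naive loop bootstrap
reproduces it exactly in the tests. A single integer seed drives one
documented stream; stratified reports spawn one child stream per stratum at
a deterministic position so results are independent of which strata happen
to be populated. Empirical coverage of the 95 % interval, measured over 200
simulated cohorts at n = 60, J = 4, true ICC 0.4, lies within [0.90, 0.99]
— percentile intervals for a truncated ratio run slightly below nominal at
moderate n, which is the expected behaviour of this CI family. Group CV and
MODD confidence intervals use the same machinery on subject-level values.

## Synthetic cohort generator

The generator defines the study conditions the package is validated under:
three status groups of 390/121/70 subjects, 6 calendar days each (day 0
sacrificed to QC), the 288-slot grid, ≥3 fingersticks/day, and paired
capillary points. Curves follow

```
Y_ij(t) = m_g(t) + Σ_k a_ik φ_k(t) + Σ_k b_ijk φ_k(t) + w_ij(t)
```

with `a_ik ~ N(0, σ²_between,k)`, `b_ijk ~ N(0, σ²_within,k)`, white noise
w (σ = 3 mg/dL), and φ a Fourier system orthonormalised on the grid
(deterministic, QR with positive-diagonal sign convention). Orthonormality
makes the truth exact: `tr K_η = Σ σ²_between,k`,
`tr K_ε = Σ σ²_within,k + p·σ²_noise` — white noise varies day to day, so it
is charged to the within component. `solve_scales_for_icc` rescales the
between SDs so the closed-form ICC hits any target exactly; group setpoints
default to 0.46/0.37/0.30 (diabetes/prediabetes/normoglycaemia), encoding
the qualitative finding the pipeline must reproduce — reproducibility
ordering diabetes > prediabetes > normoglycaemia — as generator inputs, not
as estimated values.

Group mean curves are a flat baseline (85/100/134 mg/dL, echoing the
groups' fasting levels) with Gaussian meal excursions at 08:00/14:00/21:00
of amplitude 40/50/45 mg/dL and SD 45 min. Base within-day per-basis SDs
(110…20 mg/dL across K = 8 basis functions, scaled ×1.1 for prediabetes and
×2 for diabetes) give a pointwise within-day SD near 10 mg/dL for
normoglycaemia — realistic short-term variability. Missingness plants at
most one gap per subject-day (probability 0.3, length uniform on 2–36
slots), carved *after* the truth is recorded so QC can be tested against
known planted gaps; gaps above 24 slots are exactly the days QC must drop.
Capillary values are `curve × (1 + N(0, 0.10))`, a multiplicative error
model giving MARD ≈ 8 %. Covariates are drawn per group from distributions
echoing the emulated cohort (age 43/57/61 ± SD, BMI 26.7/31.1/31.2, FPG
84/100/134, A1C 5.2/5.7/7.1) and clipped into each group's ADA-consistent
region, so classification always recovers the intended group; lifestyle
covariates are drawn once from plausible population frequencies.

What the generator does *not* emulate: physiological glucose–insulin
dynamics, sensor drift and recalibration, day-1 accuracy degradation,
meal-time heterogeneity between subjects, and the full diurnal variance
profile of real cohorts — the flat-baseline-plus-bumps mean makes the
simulated pooled CV (~20 %) larger than typical normoglycaemic values,
because between- and within-day effects are layered on top of a shared meal
pattern. Passing tests therefore demonstrate correctness of the estimators
and pipeline under a faithful covariance structure, not calibration of
variability metrics to any real population.

## Numerical and design choices

* Integration over the grid is a plain sum over 288 equal slots; weights
  cancel in the ratio.
* All stacking, resampling and stratum orders are deterministic given input
  order and seed; panel rows sort by (subject_id, calendar_day), and the
  same config + seed regenerate report CSVs byte-identically.
* Problem sizes used by the validation suite — 150 × 5 curves for
  parameter recovery (|error| ≤ 0.04 per setpoint), 200 cohorts of 60 × 4
  for bootstrap coverage, n = 200 × 6 for the between-zero degenerate
  bound — are chosen so Monte-Carlo noise is comfortably inside each bound
  while the whole suite stays in the seconds range; the sufficient-statistic
  bootstrap is what makes the coverage study cheap.
* Degenerate inputs: all-identical curves → flagged NaN; a stratum with
  fewer than 2 subjects → flagged row without estimates; MODD with no
  consecutive-day pairs → flagged undefined rather than zero.

## Known limitations

* The percentile bootstrap is a standard cluster bootstrap; no studentised
  or bias-corrected variant is implemented.
* No multilevel FPCA (eigenfunctions), no smoothing-based covariance
  estimation, no more-than-two-level nesting.
* Timezone/DST arithmetic and vendor-native export parsing are out of
  scope; timestamps are assumed already on a local-midnight epoch.
* HOMA-IR is carried as an optional covariate, never computed.
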