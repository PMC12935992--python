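# Methods

## Exposure standardization

MC-PEI sums daily dose per kg ideal body weight, each day multiplied by that
day's metabolic vulnerability index (MVI). The MVI is re-evaluated daily
from that day's organ-dysfunction flags, and the under-2 indicator is
evaluated against age; all lab cutoffs are strict inequalities, so boundary
values (bilirubin 34 µmol/L, AST 200 IU/L, creatinine 100 µmol/L, urine
output 0.5 mL/kg/h) are non-dysfunctional. When labs are recorded instead of
flags, a missing lab on a day is carried forward from the last observation
within the same admission, never across patients; a day with *both* labs of
a pair missing is an error — the analysis is complete-case throughout, with
no imputation machinery.

Ideal body weight branches: infancy-chart median (< 1 y), reference median
weight-for-age (≥ 1 y, BMI ≤ 85th centile), or the McLaren method
(median weight at the height-age where the reference median height equals
the child's height) above the 85th BMI centile, which requires height. The
bundled growth tables (`data/growth_reference_synthetic.csv`) are compact
*synthetic approximations* of published pediatric medians at month/year
resolution, smooth-interpolated with monotone (PCHIP) splines; they are
adequate for dose standardization but are not the official charts. Dose
records at hourly granularity are summed to 24-h periods before the formula,
which is defined per day.

## Severity residualization

MC-PEI is regressed on status-epilepticus duration, PELOD-2 score and
seizure density (cubic B-splines, df = 6 per term, mild ridge penalty
α = 10 ≈ 5 effective df) plus EEG suppression as a linear binary term, using
a Gaussian additive model. The two right-skewed markers (status-epilepticus
duration, seizure density) are log-transformed before splining — a
variance-stabilizing choice that stops spline knots crowding the long tail.
Out-of-fold predictions clip test markers into the training range (constant
extrapolation at the boundary). Model quality is the mean out-of-fold R²
over 10 shuffled folds (each fold's own mean in the denominator), reported
alongside the in-sample R²; the cross-validated figure is the honest one and
runs slightly below the generative severity share because it pays estimation
error. In the exactly noise-free limit the penalized IRLS fitter refuses a
zero-residual solution, so the model falls back to unpenalized least squares
on the same basis.

DR = observed − predicted MC-PEI; negative values mean less exposure than
illness severity predicts. Tertiles are assigned by empirical rank with the
remainder absorbed by the lower groups (74 → 25/25/24) and ties at a cut all
going to the lower group — deterministic and permutation-equivariant; the
cut convention matters because tertile edges move under alternatives.

Standardized mean differences use average-variance pooling for continuous
rows and the pooled binomial SD for binary rows; |SMD| < 0.10 is read as
excellent balance.

## Causal estimators

Propensity weights: multinomial logistic regression of DR tertile on age,
sex, SE duration, EEG suppression, PELOD-2, MRI severity, immunotherapy,
burst-suppression duration, peak CRP and course-mean MVI (which acts both
inside MC-PEI and as an independent metabolic covariate). Weights are
stabilized (marginal class probability in the numerator — reduces variance
without changing the estimand) and truncated at the 1st/99th percentiles of
the weight distribution. Separation is detected by diverging standardized
coefficients or vanishing fitted probabilities and raised as an error rather
than silently producing extreme weights.

The weighted outcome model is FSIQ on DR/100 alone (WLS, HC1 sandwich CI); a
covariate-augmented doubly-robust variant sits behind a flag. The unweighted
multivariable OLS uses the same covariates and scaling. 2SLS enters calendar
year as a continuous linear instrument, reports the first-stage partial F,
and warns below F = 10; point estimates match the textbook two-stage
projection (cross-checked against an independent implementation in tests)
with an HC0 sandwich for inference. Note the year instrument is deliberately
weak-ish under the default calibration (F ≈ 30 at n = 600) and per-cohort IV
estimates are wide — as they would be in practice with a nine-level
calendar instrument.

The equivalent-IQ translation multiplies |β per 100 mg/kg| by 20, i.e. a
2,000 mg/kg exposure contrast — the span separating the extreme tertiles.

## Threshold analysis

The segmented model FSIQ ~ β₀ + β₁·x + β₂·(x−ψ)₊ is fit by weighted least
squares at every candidate ψ on a grid (default: 50 mg/kg steps between the
10th and 90th exposure percentiles; the evaluation setting uses
1,000–3,500 mg/kg), selecting the ψ with lowest AIC where the breakpoint
counts as one extra parameter; grid search is deterministic and
reproducible, unlike iterative breakpoint refinement. The mean function is
continuous at ψ by construction, and the slope above the break is β₁ + β₂
with a delta-method CI.

Because illness severity drives both exposure and outcome, the *unadjusted*
segmented fit is confounded; the model therefore adjusts linearly for the
severity-model prediction plus the remaining measured confounders
(log burst-suppression duration, log peak CRP, P-MOD score, MRI severity,
age) — `severity_adjustment_matrix` — alongside the IPTW weights. Segment
slopes are then identified from exposure variation net of severity.

Breakpoint location is intrinsically imprecise at this design: simulations
with outcome SD 12.5, slopes −0.12/−0.55 and n = 600 show a per-cohort SD of
roughly 600 mg/kg for the AIC-selected ψ even without any confounding, and a
drift toward the exposure-distribution bulk when the truth sits off-center.
Single-cohort breakpoints should be read with that in mind; calibration
checks therefore average ψ over replicate cohorts.

## Sensitivity suite

Each variant re-runs the full chain with one modification. The 7-day window
truncates infusion records at day 7 *before* recomputing MC-PEI and
refitting the severity model. Log-DR uses log(DR − min(DR) + 1) since DR can
be negative; its coefficient is per log-unit, not per 100 mg/kg. The
random-forest DR uses 500 trees with out-of-bag predictions (the analogue of
cross-validation for the additive model). Variants with fewer than 20
patients are skipped with a warning and recorded.

E-value: E = RR + √(RR(RR−1)) after inverting RR < 1. Converting a
continuous β to an approximate risk ratio is conventional, not exact: the
package uses d = |β|·(contrast/100)/SD and RR ≈ exp(0.91·d) with the
2,000 mg/kg contrast, and always reports the convention next to the number.

Cochran–Armitage uses equally spaced scores and no continuity correction;
its z equals the score–outcome correlation times √N on expanded
individual-level data, which the tests exploit as an enumeration oracle.
Power is the Monte-Carlo rejection rate of the pooled two-sample t-test,
validated within ±0.02 of the noncentral-t closed form. Under the
8-point/SD-12.5/25-vs-24 configuration both give ≈ 0.61 — materially lower
than figures sometimes quoted for this design; the simulation here is the
plain reading of those parameters. Weighted quantile regression solves the
check-loss linear program directly (statsmodels' quantile regression does
not accept weights). Leave-one-out uses the exact WLS downdating identity
with propensity weights held fixed.

## Synthetic cohort generator

One latent standard-normal severity factor drives all markers through
monotone transforms with independent noise (marker marginals match the
study-population medians/IQRs; the correlation structure beyond the shared
factor is a free calibration choice since only marginals are reported).
"Seizure density" is generated in events/h on an arbitrary scale, and the
"P-MOD score" as a correlated alternative severity score; neither has a
published operational definition.

Exposure decomposes as `target = g(markers) + practice`, where `g` is
additive in the same transformed markers the severity model uses (so the
additive model can in principle recover it exactly) and
`practice = instrument_strength·(year − 2018) + N(0, practice_sd)` is the
only pathway from calendar year to outcome — making year a valid instrument
by construction. The scale of `g` is solved in-sample so severity explains
exactly `severity_r2_target` (default 0.71) of exposure variance. Daily
records then realize the target: ramp from 5 mg/kg/h by 1 mg/kg/h per
10 min to the 10 mg/kg/h cap, hold, and taper by 0.5 mg/kg/h every 6 h to
2 mg/kg/h, with per-day dysfunction flags drawn at the configured daily
rates; the course is scaled (never above the cap) so the realized
MVI-weighted exposure equals the target exactly, with a 1-day minimum
course. FSIQ = baseline − severity_effect·z + piecewise(MC-PEI) +
N(0, outcome_sd), with the continuous piecewise response (default breakpoint
2,000 mg/kg, slopes −0.12/−0.55 per 100 mg/kg) applied to the realized
exposure. Intellectual disability is FSIQ < 70; school re-entry follows a
logistic link on FSIQ; active epilepsy is weakly severity-linked with a high
base rate; catheter-related infection is independent of the practice
component (negative control).

Key defaults and why: outcome SD 12.5 IQ points and severity-R² 0.71 are the
study conditions; `practice_sd = 700` gives a total exposure SD ≈ 1,300
mg/kg, matching the study population's interquartile spread;
`exposure_mean = 2,200` centers the exposure bulk near the breakpoint, where
simulations show the AIC breakpoint estimator is unbiased (an off-center
bulk drags the weakly-identified ψ toward it); severity→outcome effect 8 IQ
points per severity SD makes illness severity a strong confounder of raw
exposure, as in the clinical setting; obesity probability 0.243 and daily
liver/renal flag rates 0.40/0.30 reproduce plausible MVI levels (course
means ≈ 1.1–1.2). Default seed 20140101; identical config + seed yields
byte-identical tables.

What the generator does **not** emulate: EEG waveforms, within-day dosing
detail, informative loss to follow-up, measurement error in FSIQ beyond the
Gaussian residual, center-level clustering, or violations of the
instrument's exclusion restriction. Passing tests therefore demonstrate that
the estimators recover the structure they assume, not that the assumptions
hold in any real cohort.

Presets: `default_paper` (calibrated effects, n = 600 evaluation scale),
`null` (both slopes zero, for type-I calibration), `linear_only` (equal
slopes, no break), `strong_confounding` (severity share 0.90, tighter
practice spread, stronger severity→outcome effect).

## Numerical choices and degenerate inputs

Percentile-type conventions, tie rules and truncation bounds are stated
where they bite (tertiles, weight clipping, grid edges). Errors are raised —
not patched — for: missing lab pairs, non-positive IBW, negative doses,
all-identical residuals, zero pooled SDs, constant instruments, constant
control outcomes, perfect separation, grids outside the data support, and
degenerate trend tables.

## Limitations

The pipeline quantifies association under the stated identification
assumptions; with real data, unmeasured severity dimensions (e.g. CSF
cytokines, genotype) remain possible confounders — that is what the E-value
bounds. Breakpoint estimates from a single cohort of this size are
imprecise (see above). The growth reference is a synthetic approximation.
Censoring-type sensitivity analyses (e.g. inverse-probability-of-censoring
weighting) are out of scope, as is any pharmacokinetic concentration
modeling.
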