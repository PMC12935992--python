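# mcpei — metabolism-corrected propofol exposure and dose-residual analysis

Children with febrile infection-related epilepsy syndrome (FIRES) receive
days-to-weeks of continuous propofol for super-refractory status epilepticus.
Whether the anesthetic itself — rather than the illness that necessitates it —
harms long-term cognition is confounded by indication: sicker children get
more drug. `mcpei` implements a two-stage pharmacovigilance pipeline that
separates *practice-driven* from *severity-driven* exposure and estimates the
dose–response of practice-driven exposure on full-scale IQ (FSIQ).

It is written for PICU pharmaco-epidemiologists and biostatisticians; all
stages run on three plain CSV tables (patients, daily infusion records,
outcomes) and a calibrated synthetic-cohort generator makes every stage
testable without patient data.

## The model

**Exposure standardization.** Daily doses are standardized to ideal body
weight (IBW) and corrected for metabolic vulnerability:

```
MC-PEI = Σ_t  dose_t(mg) / IBW(kg) × MVI_t
MVI_t  = 1 + 0.20·liver_t + 0.15·renal_t + 0.10·(age<2 y)   ∈ [1.00, 1.45]
```

with liver dysfunction = bilirubin > 34 µmol/L or AST > 200 IU/L, renal
dysfunction = creatinine > 100 µmol/L or urine output < 0.5 mL/kg/h, all
evaluated per 24-h period. IBW uses an infancy chart (< 1 y), reference
median weight-for-age, or the McLaren height-age method when BMI > 85th
centile.

**Severity residualization.** A penalized-spline additive model predicts
MC-PEI from status-epilepticus duration, EEG background suppression, PELOD-2
and seizure density (10-fold cross-validated R²). The dose residual

```
DR = observed MC-PEI − predicted MC-PEI
```

is the practice-driven component; patients are stratified into DR tertiles.

**Causal estimation.** The DR → FSIQ slope (per 100 mg/kg) is estimated by
(i) IPTW — stabilized inverse-probability weights from a multinomial
logistic model of DR tertile on baseline covariates, truncated at the
1st/99th percentiles, then weighted least squares with sandwich CIs;
(ii) unweighted multivariable OLS; (iii) 2SLS with treatment calendar year
instrumenting practice intensity. A segmented model
`FSIQ ~ β₀ + β₁·MC-PEI + β₂·(MC-PEI − ψ)₊` with AIC-selected breakpoint ψ
detects the exposure threshold beyond which decline accelerates.

**Sensitivity suite.** Pre-specified variants (excluding infants < 24 mo,
7-day exposure window, log-DR, omitting seizure-duration adjustment,
random-forest DR), E-value, negative-control outcome (catheter-related
infection), Cochran–Armitage trend tests, quantile regression, leave-one-out
influence, and Monte-Carlo power estimation.

## Worked example

```bash
mcpei run-all --preset default_paper --n 600 --seed 20140101 --out-dir results/demo
```

prints

```
{"iptw_beta_per100": -0.342, "piecewise_psi_mgkg": 2350.0, "out_dir": "results/demo"}
```

and writes `exposure.csv`, `dose_residuals.csv`, `balance_table.csv`,
`effects.csv`, `piecewise.json`, `sensitivity.csv`, `outcome_table.csv` and a
reproducibility `manifest.json`. In this run each 100 mg/kg of
practice-driven exposure costs 0.34 IQ points (`effects.csv`:
β = −0.342, 95% CI −0.53 to −0.15, p = 0.0004; equivalent to ≈ 6.8 IQ points
over a 2,000 mg/kg contrast), and the segmented fit places the inflection at
2,350 mg/kg for this single cohort — breakpoint location is the noisiest
quantity in the pipeline, which is why calibration checks average it over
replicate cohorts (see below).

The same stages are available individually (`mcpei simulate`, `exposure`,
`residualize`, `estimate`, `threshold`, `sensitivity`, `report`) and as
library functions (`mcpei.generate_cohort`, `mcpei.fit_severity_model`,
`mcpei.iptw_effect`, `mcpei.fit_piecewise`, ...). A bedside monitoring mode
flags when a running cumulative MC-PEI reaches the 2,000 mg/kg
multidisciplinary-review threshold:

```bash
mcpei threshold --value 2100
# MC-PEI 2100 mg/kg: ALERT - multidisciplinary review
```

## Input schemas

`patients.csv`: patient_id, age_years, sex (M/F), weight_kg, height_cm,
bmi_percentile, year, se_duration_h, pelod2, eeg_suppression,
seizure_density, burst_suppression_h, crp_peak, mri_severity (0/1/2),
pmod_score, immunotherapy, midazolam_mgkg, ketamine_mgkg.
`infusion_days.csv`: patient_id, day (1..n contiguous), propofol_mg,
liver_flag, renal_flag.
`outcomes.csv`: patient_id, fsiq, intellectual_disability, school_reentry,
active_epilepsy, catheter_infection.

See `docs/methods.md` for model details, generator calibration, numerical
choices, and limitations.
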