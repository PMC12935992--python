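"""Synthetic cohorts for the propofol dose-residual pipeline.

Emulates the data structure the analysis assumes for children with febrile
infection-related epilepsy syndrome (FIRES) on prolonged propofol infusion:

* one latent illness-severity factor drives all severity markers (status-
  epilepticus duration, PELOD-2, EEG background suppression, seizure density,
  burst-suppression duration, peak CRP, MRI severity, P-MOD analogue,
  immunotherapy use);
* total exposure decomposes into a severity-predicted part (an additive
  function of four observed markers, so a smooth additive model can recover
  it) plus a practice-driven offset -- the quantity the dose residual (DR)
  is meant to isolate;
* the practice offset is the only pathway from treatment calendar year to
  outcome, making year a valid instrument by construction;
* FSIQ is built from a continuous piecewise-linear dose-response in realized
  MC-PEI (default breakpoint 2,000 mg/kg, slopes -0.12 / -0.55 IQ points per
  100 mg/kg) plus a severity effect and Gaussian noise (default SD 12.5);
* catheter-related infection is generated independent of practice-driven
  exposure (negative-control outcome).

Daily infusion records follow the titration protocol: start 5 mg/kg/h,
+1 mg/kg/h every 10 min to a 10 mg/kg/h cap, wean by 0.5 mg/kg/h every 6 h
down to 2 mg/kg/h.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .exposure import ideal_body_weight, median_height_for_age, median_weight_for_age

SCHEMA_VERSION = "1.0"
DEFAULT_SEED = 20140101

YEAR_MIN, YEAR_MAX = 2014, 2022


@dataclass(frozen=True)
class TitrationProtocol:
    """Hourly-rate protocol for the continuous propofol infusion."""

    start_rate: float = 5.0  # mg/kg/h
    step: float = 1.0  # mg/kg/h per titration step
    step_minutes: float = 10.0
    cap: float = 10.0  # mg/kg/h, never exceeded
    wean_step: float = 0.5  # mg/kg/h per wean interval
    wean_interval_h: float = 6.0
    wean_floor: float = 2.0  # mg/kg/h at extubation

    def __post_init__(self) -> None:
        if not (0 < self.start_rate <= self.cap):
            raise ValueError("start_rate must be in (0, cap]")
        if self.step <= 0 or self.wean_step <= 0:
            raise ValueError("titration steps must be positive")

    def ramp_day_rate_hours(self) -> float:
        """Rate-hours (mg/kg) accrued on the first 24-h period."""
        rates = np.arange(self.start_rate, self.cap, self.step)
        ramp_h = len(rates) * self.step_minutes / 60.0
        return float(rates.sum() * self.step_minutes / 60.0 + self.cap * (24.0 - ramp_h))

    def hold_day_rate_hours(self) -> float:
        return self.cap * 24.0

    def taper_rates(self) -> np.ndarray:
        return np.arange(self.cap - self.wean_step, self.wean_floor - 1e-9, -self.wean_step)


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic cohort, with study-condition defaults."""

    n_patients: int = 74
    seed: int = DEFAULT_SEED
    breakpoint_true: float = 2000.0  # mg/kg
    slope_below_true: float = -0.12  # IQ points per 100 mg/kg
    slope_above_true: float = -0.55
    practice_sd: float = 700.0  # mg/kg patient-level practice spread
    severity_r2_target: float = 0.71  # fraction of MC-PEI variance from severity
    outcome_sd: float = 12.5  # IQ points
    fsiq_baseline: float = 73.0
    severity_outcome_effect: float = 8.0  # IQ points per severity SD
    instrument_strength: float = 60.0  # mg/kg practice shift per calendar year
    exposure_mean: float = 2200.0  # mg/kg location of the exposure distribution
    obesity_prob: float = 0.243  # P(BMI > 85th centile)
    flag_probs: tuple[float, float] = (0.40, 0.30)  # daily (liver, renal)
    zero_effect: bool = False
    protocol: TitrationProtocol = field(default_factory=TitrationProtocol)

    def __post_init__(self) -> None:
        if self.n_patients < 10:
            raise ValueError("n_patients must be at least 10")
        if not (0.0 < self.severity_r2_target < 1.0):
            raise ValueError("severity_r2_target must be in (0, 1)")
        for p in (*self.flag_probs, self.obesity_prob):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.outcome_sd < 0 or self.practice_sd < 0:
            raise ValueError("standard deviations must be non-negative")

    @property
    def effective_slopes(self) -> tuple[float, float]:
        if self.zero_effect:
            return (0.0, 0.0)
        return (self.slope_below_true, self.slope_above_true)

    @classmethod
    def from_file(cls, path) -> "GeneratorConfig":
        """Load a config from YAML/JSON; 'flag_probs' may be a 2-list."""
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "flag_probs" in data:
            data["flag_probs"] = tuple(data["flag_probs"])
        return cls(**data)


@dataclass
class CohortTables:
    """Linked patients / infusion_days / outcomes tables plus generative truth."""

    patients: pd.DataFrame
    infusion_days: pd.DataFrame
    outcomes: pd.DataFrame
    truth: pd.DataFrame
    config: GeneratorConfig
    schema_version: str = SCHEMA_VERSION

    def write(self, out_dir, header: str | None = None) -> None:
        """Write the three CSV tables (truth stays in memory unless asked)."""
        import os

        os.makedirs(out_dir, exist_ok=True)
        prefix = header or f"# mcpei schema={self.schema_version} seed={self.config.seed}\n"
        for name, df in (
            ("patients", self.patients),
            ("infusion_days", self.infusion_days),
            ("outcomes", self.outcomes),
        ):
            path = os.path.join(out_dir, f"{name}.csv")
            with open(path, "w") as fh:
                fh.write(prefix)
                df.to_csv(fh, index=False)


def piecewise_response(mcpei, breakpoint: float, slope_below: float, slope_above: float):
    """Continuous piecewise-linear FSIQ shift (IQ points) at a given exposure.

    Slopes are per 100 mg/kg; the function is 0 at zero exposure and
    continuous at the breakpoint.
    """
    x = np.asarray(mcpei, dtype=float)
    below = np.minimum(x, breakpoint)
    above = np.maximum(x - breakpoint, 0.0)
    return slope_below / 100.0 * below + slope_above / 100.0 * above


def _course_rate_hours(
    target_weighted: float,
    mvi_for_day,
    protocol: TitrationProtocol,
) -> tuple[np.ndarray, np.ndarray]:
    """Build a daily course whose MVI-weighted rate-hours sum to the target.

    ``mvi_for_day(d)`` draws the day-d MVI.  The course follows
    ramp -> hold-at-cap -> taper; hold length is extended until the weighted
    sum reaches the target, then all daily doses are scaled down uniformly so
    the realized MVI-weighted exposure equals the target exactly (scaling is
    always <= 1, so the hourly cap is never exceeded).
    Returns (rate_hours per day, mvi per day).
    """
    target = max(float(target_weighted), 50.0)
    ramp = protocol.ramp_day_rate_hours()
    hold = protocol.hold_day_rate_hours()
    taper = protocol.taper_rates()
    # taper rate-hours split into 24-h chunks
    taper_hours = np.full(len(taper), protocol.wean_interval_h)
    taper_rh = taper * taper_hours
    edges = np.cumsum(taper_hours)
    taper_days: list[float] = []
    start = 0.0
    while start < edges[-1] - 1e-9:
        end = start + 24.0
        frac = np.clip((np.minimum(edges, end) - np.maximum(edges - taper_hours, start)), 0, None)
        taper_days.append(float(np.sum(taper * frac)))
        start = end

    mvi1 = mvi_for_day(0)
    if target <= ramp * mvi1:
        return np.array([target / mvi1]), np.array([mvi1])

    rh = [ramp]
    mvi = [mvi1]
    total = ramp * mvi1
    day = 1
    # extend hold until ramp+hold+taper can cover the target
    while True:
        taper_mvi = [mvi_for_day(day + k) for k in range(len(taper_days))]
        with_taper = total + sum(r * m for r, m in zip(taper_days, taper_mvi))
        if with_taper >= target or day > 400:
            rh.extend(taper_days)
            mvi.extend(taper_mvi)
            total = with_taper
            break
        m = mvi_for_day(day)
        rh.append(hold)
        mvi.append(m)
        total += hold * m
        day += 1
    rh_arr = np.asarray(rh)
    mvi_arr = np.asarray(mvi)
    scale = target / total  # <= 1 by construction
    return rh_arr * scale, mvi_arr


def simulate_infusion_course(
    severity_z: float,
    practice_offset: float,
    protocol: TitrationProtocol | None = None,
    rng: np.random.Generator | None = None,
    flag_probs: tuple[float, float] = (0.40, 0.30),
    under2: bool = False,
    base_exposure: float = 2300.0,
    severity_scale: float = 700.0,
) -> pd.DataFrame:
    """One patient's daily infusion course.

    Target MVI-weighted exposure is ``base + severity_scale*z + offset``
    (floored at a 1-day minimum course); more severe illness and a larger
    practice offset both lengthen the course.  Returns a frame with
    ``day, rate_hours, liver_flag, renal_flag, mvi``; the daily dose in mg is
    ``rate_hours * IBW``.
    """
    protocol = protocol or TitrationProtocol()
    rng = rng or np.random.default_rng(DEFAULT_SEED)
    target = base_exposure + severity_scale * float(severity_z) + float(practice_offset)

    flags: list[tuple[int, int]] = []

    def mvi_for_day(d: int) -> float:
        while len(flags) <= d:
            flags.append(
                (
                    int(rng.random() < flag_probs[0]),
                    int(rng.random() < flag_probs[1]),
                )
            )
        liver, renal = flags[d]
        return 1.0 + 0.20 * liver + 0.15 * renal + 0.10 * int(under2)

    rh, mvi = _course_rate_hours(target, mvi_for_day, protocol)
    n = len(rh)
    return pd.DataFrame(
        {
            "day": np.arange(1, n + 1),
            "rate_hours": rh,
            "liver_flag": [flags[d][0] for d in range(n)],
            "renal_flag": [flags[d][1] for d in range(n)],
            "mvi": mvi,
        }
    )


def _standardize(x: np.ndarray) -> np.ndarray:
    s = x.std()
    if s < 1e-12:
        return np.zeros_like(x)
    return (x - x.mean()) / s


def generate_cohort(config: GeneratorConfig | None = None) -> CohortTables:
    """Generate linked patients / infusion_days / outcomes tables.

    Deterministic for a fixed config+seed.  The exposure-noise split is
    solved in-sample so the severity-predicted part explains exactly
    ``severity_r2_target`` of MC-PEI variance.
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients

    # --- latent severity and markers (monotone in severity_z) -------------
    z = rng.normal(size=n)
    se_duration = np.exp(np.log(270.0) + 0.45 * z + rng.normal(0, 0.25, n))
    pelod2 = np.clip(np.round(13.0 + 2.5 * z + rng.normal(0, 1.2, n)), 0, 30)
    eeg = (rng.random(n) < expit(1.3 * z - 0.35)).astype(int)
    seizure_density = np.exp(np.log(2.5) + 0.5 * z + rng.normal(0, 0.35, n))
    burst_supp = np.exp(np.log(72.0) + 0.30 * z + rng.normal(0, 0.30, n))
    crp = np.exp(np.log(152.0) + 0.25 * z + rng.normal(0, 0.40, n))
    mri_latent = z + rng.normal(0, 0.8, n)
    mri = np.digitize(mri_latent, [-0.425, 0.863])  # 0 normal/mild, 1 moderate, 2 severe
    pmod = 12.0 + 2.2 * z + rng.normal(0, 1.5, n)
    immunotherapy = (rng.random(n) < expit(0.85 + 0.4 * z)).astype(int)
    midazolam = np.exp(3.3 + 0.3 * z + rng.normal(0, 0.5, n))
    ketamine = np.exp(2.2 + 0.35 * z + rng.normal(0, 0.6, n))

    # --- demographics / anthropometrics -----------------------------------
    age = np.clip(np.exp(np.log(7.2) + 0.559 * rng.normal(size=n)), 0.3, 14.0)
    sex = np.where(rng.random(n) < 0.53, "M", "F")
    med_h = np.array([median_height_for_age(a, s) for a, s in zip(age, sex)])
    med_w = np.array([median_weight_for_age(a, s) for a, s in zip(age, sex)])
    height = med_h * np.exp(rng.normal(0, 0.035, n))
    obese = rng.random(n) < cfg.obesity_prob
    bmi_pct = np.where(obese, 86.0 + 13.0 * rng.random(n), 3.0 + 82.0 * rng.random(n))
    weight = med_w * np.exp(0.0045 * (bmi_pct - 50.0) + rng.normal(0, 0.04, n))
    year = rng.integers(YEAR_MIN, YEAR_MAX + 1, size=n)

    # --- exposure decomposition: severity-predicted part + practice offset -
    practice = cfg.instrument_strength * (year - (YEAR_MIN + YEAR_MAX) / 2.0)
    practice = practice + rng.normal(0, cfg.practice_sd, n)
    sd_prac = practice.std()
    r2 = cfg.severity_r2_target
    sd_g = np.sqrt(r2 / (1.0 - r2)) * sd_prac if sd_prac > 1e-9 else 700.0
    u = (
        0.50 * _standardize(np.log(se_duration))
        + 0.25 * _standardize(pelod2)
        + 0.10 * _standardize(eeg.astype(float))
        + 0.15 * _standardize(np.log(seizure_density))
    )
    g = cfg.exposure_mean + sd_g * _standardize(u)
    target = np.maximum(g + practice, 150.0)

    # --- infusion courses ---------------------------------------------------
    ibw = np.array(
        [
            ideal_body_weight(a, s, height_cm=h, bmi_percentile=b).ibw_kg
            for a, s, h, b in zip(age, sex, height, bmi_pct)
        ]
    )
    under2 = age < 2.0
    patient_ids = [f"P{i + 1:04d}" for i in range(n)]
    inf_rows = []
    realized = np.empty(n)
    for i in range(n):
        flags: list[tuple[int, int]] = []

        def mvi_for_day(d: int, _flags=flags, _u2=under2[i]) -> float:
            while len(_flags) <= d:
                _flags.append(
                    (
                        int(rng.random() < cfg.flag_probs[0]),
                        int(rng.random() < cfg.flag_probs[1]),
                    )
                )
            lv, rn_ = _flags[d]
            return 1.0 + 0.20 * lv + 0.15 * rn_ + 0.10 * int(_u2)

        rh, mvi = _course_rate_hours(target[i], mvi_for_day, cfg.protocol)
        realized[i] = float(np.sum(rh * mvi))
        for d in range(len(rh)):
            inf_rows.append(
                {
                    "patient_id": patient_ids[i],
                    "day": d + 1,
                    "propofol_mg": rh[d] * ibw[i],
                    "liver_flag": flags[d][0],
                    "renal_flag": flags[d][1],
                }
            )

    # --- outcomes -----------------------------------------------------------
    sb, sa = cfg.effective_slopes
    dose_effect = piecewise_response(realized, cfg.breakpoint_true, sb, sa)
    fsiq = (
        cfg.fsiq_baseline
        - cfg.severity_outcome_effect * z
        + dose_effect
        + rng.normal(0, cfg.outcome_sd, n)
    )
    intellectual_disability = (fsiq < 70.0).astype(int)
    school_reentry = (rng.random(n) < expit((fsiq - 75.0) / 7.0)).astype(int)
    active_epilepsy = (rng.random(n) < expit(1.25 + 0.25 * z)).astype(int)
    catheter_infection = (rng.random(n) < 0.20).astype(int)  # independent of practice

    patients = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "age_years": age,
            "sex": sex,
            "weight_kg": weight,
            "height_cm": height,
            "bmi_percentile": bmi_pct,
            "year": year,
            "se_duration_h": se_duration,
            "pelod2": pelod2,
            "eeg_suppression": eeg,
            "seizure_density": seizure_density,
            "burst_suppression_h": burst_supp,
            "crp_peak": crp,
            "mri_severity": mri,
            "pmod_score": pmod,
            "immunotherapy": immunotherapy,
            "midazolam_mgkg": midazolam,
            "ketamine_mgkg": ketamine,
        }
    )
    outcomes = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "fsiq": fsiq,
            "intellectual_disability": intellectual_disability,
            "school_reentry": school_reentry,
            "active_epilepsy": active_epilepsy,
            "catheter_infection": catheter_infection,
        }
    )
    truth = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "severity_z": z,
            "severity_pred_mgkg": g,
            "practice_offset_mgkg": practice,
            "mcpei_true_mgkg": realized,
            "ibw_kg": ibw,
        }
    )
    infusion_days = pd.DataFrame(inf_rows)
    return CohortTables(patients, infusion_days, outcomes, truth, cfg)


_PRESETS = {
    "default_paper": dict(n_patients=600),
    "null": dict(n_patients=600, zero_effect=True),
    "linear_only": dict(n_patients=600, slope_below_true=-0.35, slope_above_true=-0.35),
    "strong_confounding": dict(
        n_patients=600,
        severity_r2_target=0.90,
        practice_sd=260.0,
        severity_outcome_effect=12.0,
    ),
}


def scenario_presets() -> dict[str, GeneratorConfig]:
    """Named generator configurations for the standard study scenarios."""
    return {name: GeneratorConfig(**kw) for name, kw in _PRESETS.items()}


def get_preset(name: str, **overrides) -> GeneratorConfig:
    try:
        base = scenario_presets()[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(_PRESETS)}"
        ) from None
    return replace(base, **overrides) if overrides else base
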