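"""Metabolism-corrected propofol exposure intensity (MC-PEI).

Cumulative propofol exposure is standardized to ideal body weight (IBW) and
corrected day by day for metabolic vulnerability:

    MC-PEI = sum_t [ dose_t(mg) / IBW(kg) ] * MVI_t

where ``t`` indexes 24-hour periods from infusion initiation to
discontinuation and the metabolic vulnerability index (MVI) is

    MVI_t = 1 + 0.20 * liver_t + 0.15 * renal_t + 0.10 * under2_t,

bounded in [1.00, 1.45].  Organ-dysfunction flags are evaluated daily:
liver dysfunction is bilirubin > 34 umol/L or AST > 200 IU/L; renal
dysfunction is creatinine > 100 umol/L or urine output < 0.5 mL/kg/h
(strict inequalities; boundary values are non-dysfunctional).

IBW branches: infancy chart median (< 1 y), reference median weight-for-age
(>= 1 y, BMI <= 85th centile), or the McLaren height-age method when BMI
exceeds the 85th centile.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

MVI_LIVER = 0.20
MVI_RENAL = 0.15
MVI_UNDER2 = 0.10

BILIRUBIN_CUTOFF_UMOL_L = 34.0
AST_CUTOFF_IU_L = 200.0
CREATININE_CUTOFF_UMOL_L = 100.0
URINE_OUTPUT_CUTOFF_ML_KG_H = 0.5

BMI_OBESITY_PERCENTILE = 85.0


@dataclass(frozen=True)
class OrganFlags:
    """Daily binary vulnerability indicators."""

    liver: int
    renal: int
    under2: int

    def __post_init__(self) -> None:
        for name in ("liver", "renal", "under2"):
            v = getattr(self, name)
            if v not in (0, 1):
                raise ValueError(f"{name} flag must be 0 or 1, got {v!r}")


@dataclass
class ExposureSummary:
    """Per-patient exposure: IBW, daily MVI path, cumulative MC-PEI."""

    patient_id: object
    ibw_kg: float
    daily_mvi: np.ndarray
    daily_dose_perkg: np.ndarray
    mcpei: float
    raw_cumulative_perkg: float
    n_days: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_days = len(self.daily_mvi)


def classify_liver_dysfunction(bilirubin_umol_l, ast_iu_l):
    """1 iff bilirubin > 34 umol/L or AST > 200 IU/L (strict).

    Missing values (NaN/None) are tolerated one at a time; both missing is an
    error -- the analysis assumes complete cases, never imputation.
    """
    b = np.nan if bilirubin_umol_l is None else float(bilirubin_umol_l)
    a = np.nan if ast_iu_l is None else float(ast_iu_l)
    if np.isnan(b) and np.isnan(a):
        raise ValueError("both bilirubin and AST missing; cannot classify liver dysfunction")
    if (b < 0) or (a < 0):
        raise ValueError("lab values must be non-negative")
    return int((b > BILIRUBIN_CUTOFF_UMOL_L) or (a > AST_CUTOFF_IU_L))


def classify_renal_dysfunction(creatinine_umol_l, urine_output_ml_kg_h):
    """1 iff creatinine > 100 umol/L or urine output < 0.5 mL/kg/h (strict)."""
    c = np.nan if creatinine_umol_l is None else float(creatinine_umol_l)
    u = np.nan if urine_output_ml_kg_h is None else float(urine_output_ml_kg_h)
    if np.isnan(c) and np.isnan(u):
        raise ValueError("both creatinine and urine output missing; cannot classify renal dysfunction")
    if (c < 0) or (u < 0):
        raise ValueError("lab values must be non-negative")
    return int((c > CREATININE_CUTOFF_UMOL_L) or (u < URINE_OUTPUT_CUTOFF_ML_KG_H))


def compute_mvi(flags: OrganFlags) -> float:
    """MVI = 1 + 0.20*liver + 0.15*renal + 0.10*under2, in [1.00, 1.45]."""
    return 1.0 + MVI_LIVER * flags.liver + MVI_RENAL * flags.renal + MVI_UNDER2 * flags.under2


@lru_cache(maxsize=1)
def _growth_reference() -> pd.DataFrame:
    path = importlib.resources.files("mcpei.data") / "growth_reference_synthetic.csv"
    with importlib.resources.as_file(path) as p:
        return pd.read_csv(p, comment="#")


@lru_cache(maxsize=4)
def _interpolators(sex: str):
    ref = _growth_reference()
    sub = ref[ref["sex"] == sex].sort_values("age_months")
    w = PchipInterpolator(sub["age_months"], sub["median_weight_kg"])
    h = PchipInterpolator(sub["age_months"], sub["median_height_cm"])
    return w, h


def _norm_sex(sex) -> str:
    s = str(sex).upper()[:1]
    if s not in ("M", "F"):
        raise ValueError(f"sex must be 'M' or 'F', got {sex!r}")
    return s


def median_weight_for_age(age_years: float, sex) -> float:
    """Reference median weight (kg) at a given age, smooth-interpolated."""
    w, _ = _interpolators(_norm_sex(sex))
    months = age_years * 12.0
    if months < 0 or months > 168:
        raise ValueError(f"age {age_years} y outside reference range (0-14 y)")
    return float(w(months))


def median_height_for_age(age_years: float, sex) -> float:
    _, h = _interpolators(_norm_sex(sex))
    months = age_years * 12.0
    if months < 0 or months > 168:
        raise ValueError(f"age {age_years} y outside reference range (0-14 y)")
    return float(h(months))


@dataclass(frozen=True)
class IBWResult:
    ibw_kg: float
    method: str  # 'infant_chart' | 'weight_for_age' | 'mclaren'


def ideal_body_weight(
    age_years: float,
    sex,
    height_cm: float | None = None,
    bmi_percentile: float | None = None,
) -> IBWResult:
    """Ideal body weight with explicit branch selection.

    * age < 1 y: infancy-chart median weight for age (``infant_chart``);
    * BMI <= 85th centile and age >= 1 y: reference median weight-for-age;
    * BMI > 85th centile: McLaren method -- the median weight at the
      "height-age" where the reference median height equals the child's
      height (requires ``height_cm``).
    """
    if age_years < 1.0 / 12.0:
        raise ValueError("age below reference range (minimum 1 month)")
    sex = _norm_sex(sex)
    if age_years < 1.0:
        return IBWResult(median_weight_for_age(age_years, sex), "infant_chart")
    if bmi_percentile is not None and bmi_percentile > BMI_OBESITY_PERCENTILE:
        if height_cm is None:
            raise ValueError("McLaren method requires height_cm for BMI > 85th centile")
        w_interp, h_interp = _interpolators(sex)
        grid = np.linspace(0.0, 168.0, 1681)
        heights = h_interp(grid)
        # height-age: reference median height equals the child's height
        h_clipped = float(np.clip(height_cm, heights.min(), heights.max()))
        height_age_months = float(np.interp(h_clipped, heights, grid))
        return IBWResult(float(w_interp(height_age_months)), "mclaren")
    return IBWResult(median_weight_for_age(age_years, sex), "weight_for_age")


def locf(values: pd.Series) -> pd.Series:
    """Carry forward the last observed lab within one admission (never across
    patients -- callers apply this per patient)."""
    return values.ffill()


def compute_mcpei(
    daily_dose_mg,
    ibw_kg: float,
    liver_flags,
    renal_flags,
    under2_flags,
    actual_weight_kg: float | None = None,
    patient_id=None,
) -> ExposureSummary:
    """Apply the MC-PEI formula over a sequence of infusion days.

    ``daily_dose_mg`` is the total propofol delivered in each 24-h period;
    per-day MVI is computed from that day's flags.  ``actual_weight_kg``
    feeds the uncorrected cumulative mg/kg used for comparison reporting
    (defaults to IBW when absent).
    """
    dose = np.asarray(daily_dose_mg, dtype=float)
    if dose.ndim != 1 or dose.size < 1:
        raise ValueError("need at least one infusion day")
    if np.any(dose < 0):
        raise ValueError("negative daily dose")
    if not ibw_kg > 0:
        raise ValueError(f"ibw_kg must be positive, got {ibw_kg}")
    liver = np.asarray(liver_flags, dtype=int)
    renal = np.asarray(renal_flags, dtype=int)
    under2 = np.asarray(under2_flags, dtype=int)
    if not (len(liver) == len(renal) == len(under2) == dose.size):
        raise ValueError("flag sequences must match the number of infusion days")
    for arr, name in ((liver, "liver"), (renal, "renal"), (under2, "under2")):
        if np.any((arr != 0) & (arr != 1)):
            raise ValueError(f"{name} flags must be binary")
    mvi = 1.0 + MVI_LIVER * liver + MVI_RENAL * renal + MVI_UNDER2 * under2
    perkg = dose / ibw_kg
    mcpei = float(np.sum(perkg * mvi))
    denom = actual_weight_kg if actual_weight_kg is not None else ibw_kg
    if not denom > 0:
        raise ValueError("actual_weight_kg must be positive")
    raw = float(np.sum(dose) / denom)
    return ExposureSummary(
        patient_id=patient_id,
        ibw_kg=float(ibw_kg),
        daily_mvi=mvi,
        daily_dose_perkg=perkg,
        mcpei=mcpei,
        raw_cumulative_perkg=raw,
    )


def derive_flags_from_labs(infusion_days: pd.DataFrame) -> pd.DataFrame:
    """Daily dysfunction flags from lab columns (bilirubin, ast, creatinine,
    urine_output), carrying each lab forward within a patient's admission."""
    lab_cols = {"bilirubin", "ast", "creatinine", "urine_output"}
    missing = lab_cols - set(infusion_days.columns)
    if missing:
        raise ValueError(
            f"need liver_flag/renal_flag or lab columns; missing {sorted(missing)}"
        )
    df = infusion_days.sort_values(["patient_id", "day"]).copy()
    for c in lab_cols:
        df[c] = df.groupby("patient_id", sort=False)[c].transform(locf)
    df["liver_flag"] = [
        classify_liver_dysfunction(b, a) for b, a in zip(df["bilirubin"], df["ast"])
    ]
    df["renal_flag"] = [
        classify_renal_dysfunction(c, u)
        for c, u in zip(df["creatinine"], df["urine_output"])
    ]
    return df


def summarize_exposure(
    patients: pd.DataFrame,
    infusion_days: pd.DataFrame,
    max_day: int | None = None,
) -> pd.DataFrame:
    """Cohort-level exposure table: one row per patient.

    ``patients`` needs columns ``patient_id, age_years, sex, weight_kg,
    height_cm, bmi_percentile``; ``infusion_days`` needs ``patient_id, day,
    propofol_mg, liver_flag, renal_flag``.  ``max_day`` truncates the course
    (used by the 7-day sensitivity window).  Returns columns
    ``patient_id, ibw_kg, mcpei_mgkg, raw_mgkg, n_days``.
    """
    required_p = {"patient_id", "age_years", "sex", "weight_kg", "height_cm", "bmi_percentile"}
    missing = required_p - set(patients.columns)
    if missing:
        raise ValueError(f"patients table missing columns: {sorted(missing)}")
    inf = infusion_days
    if not {"liver_flag", "renal_flag"} <= set(inf.columns):
        inf = derive_flags_from_labs(inf)
    required_i = {"patient_id", "day", "propofol_mg", "liver_flag", "renal_flag"}
    missing = required_i - set(inf.columns)
    if missing:
        raise ValueError(f"infusion_days table missing columns: {sorted(missing)}")

    if max_day is not None:
        inf = inf[inf["day"] <= max_day]
    orphan = set(inf["patient_id"]) - set(patients["patient_id"])
    if orphan:
        raise ValueError(f"infusion days reference unknown patients: {sorted(orphan)[:5]}")

    rows = []
    grouped = inf.sort_values("day").groupby("patient_id", sort=False)
    for _, p in patients.iterrows():
        pid = p["patient_id"]
        try:
            days = grouped.get_group(pid)
        except KeyError:
            continue
        ibw = ideal_body_weight(
            p["age_years"], p["sex"], height_cm=p["height_cm"], bmi_percentile=p["bmi_percentile"]
        ).ibw_kg
        under2 = np.full(len(days), int(p["age_years"] < 2.0))
        summ = compute_mcpei(
            days["propofol_mg"].to_numpy(),
            ibw,
            days["liver_flag"].to_numpy(),
            days["renal_flag"].to_numpy(),
            under2,
            actual_weight_kg=p["weight_kg"],
            patient_id=pid,
        )
        rows.append(
            {
                "patient_id": pid,
                "ibw_kg": summ.ibw_kg,
                "mcpei_mgkg": summ.mcpei,
                "raw_mgkg": summ.raw_cumulative_perkg,
                "n_days": summ.n_days,
            }
        )
    return pd.DataFrame(rows)
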