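"""Dose-response estimation for the practice-driven exposure residual.

Three estimators of the DR -> FSIQ effect, all reported per 100 mg/kg DR:

* IPTW: stabilized inverse-probability weights from a multinomial logistic
  model of DR tertile on baseline covariates, truncated at the 1st/99th
  weight percentiles, then weighted least squares with a sandwich CI;
* unweighted multivariable OLS;
* instrumental-variable 2SLS with treatment calendar year as the instrument
  for practice intensity (first-stage F reported; weak-instrument warning
  below F = 10).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

#: baseline covariate columns used by the propensity model; MVI serves both
#: as a component of MC-PEI and as an independent metabolic covariate.
PROPENSITY_COVARIATES = (
    "age_years",
    "sex_male",
    "se_duration_h",
    "eeg_suppression",
    "pelod2",
    "mri_severity",
    "immunotherapy",
    "burst_suppression_h",
    "crp_peak",
    "mean_mvi",
)

IQ_SPAN_MGKG = 2000.0  # exposure contrast behind the "equivalent IQ" column


class WeakInstrumentWarning(UserWarning):
    pass


@dataclass
class EffectEstimate:
    beta_per100: float
    ci_low: float
    ci_high: float
    p_value: float
    method: str
    n: int
    adjusted_r2: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.beta_per100 <= self.ci_high):
            raise ValueError("CI must bracket the point estimate")


@dataclass
class PropensityWeights:
    weights: np.ndarray
    probabilities: np.ndarray  # n x 3 simplex rows
    truncation_bounds: tuple[float, float]
    classes: tuple


def design_matrix(patients: pd.DataFrame, infusion_days: pd.DataFrame) -> pd.DataFrame:
    """Propensity covariate frame (patient_id + PROPENSITY_COVARIATES)."""
    df = patients.copy()
    df["sex_male"] = (df["sex"].astype(str).str.upper().str[0] == "M").astype(int)
    df = df.merge(
        mean_mvi_per_patient(infusion_days, patients).reset_index(), on="patient_id"
    )
    return df[["patient_id", *PROPENSITY_COVARIATES]]


def mean_mvi_per_patient(infusion_days: pd.DataFrame, patients: pd.DataFrame) -> pd.Series:
    """Course-mean MVI per patient from daily flags and age."""
    df = infusion_days.merge(patients[["patient_id", "age_years"]], on="patient_id")
    mvi = (
        1.0
        + 0.20 * df["liver_flag"]
        + 0.15 * df["renal_flag"]
        + 0.10 * (df["age_years"] < 2.0).astype(int)
    )
    return mvi.groupby(df["patient_id"]).mean().rename("mean_mvi")


def fit_propensity_weights(
    tertiles,
    covariates: pd.DataFrame,
    stabilized: bool = True,
    truncate: tuple[float, float] = (1.0, 99.0),
) -> PropensityWeights:
    """Stabilized multinomial-logistic IPT weights, percentile-truncated.

    weight_i = P(T = t_i) / Phat(T = t_i | X_i) (marginal numerator dropped
    when ``stabilized`` is False), then clipped at its own ``truncate``
    percentiles.
    """
    t = np.asarray(tertiles)
    classes, t_idx = np.unique(t, return_inverse=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 exposure groups")
    counts = np.bincount(t_idx)
    if counts.min() < 3:
        raise ValueError("need at least 3 patients per tertile")
    X = StandardScaler().fit_transform(np.asarray(covariates, dtype=float))
    if np.isnan(X).any():
        raise ValueError("missing covariate values; complete cases required")
    clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=5000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # lbfgs convergence chatter on separation
        clf.fit(X, t_idx)
    probs = clf.predict_proba(X)
    p_obs = probs[np.arange(len(t)), t_idx]
    # separation: coefficients diverge on standardized covariates and the
    # model classifies (near-)perfectly -> weights would be meaningless
    if p_obs.min() < 1e-8 or np.max(np.abs(clf.coef_)) > 10.0:
        raise ValueError(
            "perfect separation in the propensity model; "
            "inspect covariates for a deterministic predictor of tertile"
        )
    marginal = counts / counts.sum()
    num = marginal[t_idx] if stabilized else 1.0
    w = num / p_obs
    lo, hi = np.percentile(w, truncate)
    w = np.clip(w, lo, hi)
    return PropensityWeights(w, probs, (float(lo), float(hi)), tuple(classes))


def _wls_effect(
    y, x_per100, weights=None, covariates=None, method="iptw", cov_type="HC1"
) -> EffectEstimate:
    X = np.column_stack([np.ones(len(y)), np.asarray(x_per100, float)])
    names = ["const", "dr_per100"]
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        X = np.column_stack([X, C])
        names += [f"c{i}" for i in range(C.shape[1])]
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("collinear design matrix")
    w = np.ones(len(y)) if weights is None else np.asarray(weights, float)
    if not np.all(np.isfinite(w)) or np.any(w <= 0):
        raise ValueError("weights must be finite and positive")
    model = sm.WLS(np.asarray(y, float), X, weights=w)
    res = model.fit(cov_type=cov_type) if cov_type else model.fit()
    ci = res.conf_int()[1]
    return EffectEstimate(
        beta_per100=float(res.params[1]),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        p_value=float(res.pvalues[1]),
        method=method,
        n=len(y),
        adjusted_r2=float(res.rsquared_adj),
        extra={"params": dict(zip(names, map(float, res.params)))},
    )


def iptw_effect(fsiq, dr, weights, covariates=None) -> EffectEstimate:
    """Weighted least squares of FSIQ on DR/100 with sandwich (HC1) CI.

    The default weighted outcome model contains DR only; pass ``covariates``
    for the covariate-augmented (doubly robust) variant.
    """
    return _wls_effect(fsiq, np.asarray(dr, float) / 100.0, weights, covariates, "iptw")


def ols_effect(fsiq, dr, covariates=None) -> EffectEstimate:
    """Unweighted multivariable linear model, same per-100 mg/kg scaling."""
    return _wls_effect(
        fsiq, np.asarray(dr, float) / 100.0, None, covariates, "ols", cov_type=None
    )


def iv_2sls_effect(fsiq, dr, instrument, covariates=None) -> EffectEstimate:
    """Two-stage least squares with calendar year instrumenting DR.

    Exogenous covariates appear in both stages; SEs are the HC0 sandwich for
    the 2SLS estimator.  Emits :class:`WeakInstrumentWarning` when the
    first-stage partial F for the instrument falls below 10.
    """
    y = np.asarray(fsiq, float)
    d = np.asarray(dr, float) / 100.0
    zi = np.asarray(instrument, float)
    n = len(y)
    if np.ptp(zi) < 1e-12:
        raise ValueError("instrument is constant")
    C = None if covariates is None else np.asarray(covariates, float)
    exog_parts = [np.ones(n)] + ([] if C is None else [C])
    W = np.column_stack(exog_parts)  # included exogenous regressors
    X = np.column_stack([W, d])  # structural regressors, endog last
    Z = np.column_stack([W, zi])  # instruments

    # first stage + partial F for the excluded instrument
    fs = sm.OLS(d, Z).fit()
    fs_restricted = sm.OLS(d, W).fit()
    df_resid = n - Z.shape[1]
    f_stat = (
        (fs_restricted.ssr - fs.ssr) / 1.0 / (fs.ssr / df_resid) if fs.ssr > 0 else np.inf
    )
    if f_stat < 10:
        warnings.warn(
            f"weak instrument: first-stage F = {f_stat:.2f} < 10", WeakInstrumentWarning
        )

    # 2SLS point estimate and HC0 sandwich
    Pz = Z @ np.linalg.lstsq(Z.T @ Z, Z.T, rcond=None)[0]
    Xhat = Pz @ X
    XtX = Xhat.T @ X
    beta = np.linalg.solve(XtX, Xhat.T @ y)
    resid = y - X @ beta
    meat = (Xhat * (resid**2)[:, None]).T @ Xhat
    bread = np.linalg.inv(XtX)
    V = bread @ meat @ bread.T
    se = np.sqrt(np.diag(V))
    k = X.shape[1] - 1  # endogenous regressor index
    z975 = stats.norm.ppf(0.975)
    b = float(beta[k])
    p = 2.0 * stats.norm.sf(abs(b / se[k]))
    ss_tot = np.sum((y - y.mean()) ** 2)
    adj_r2 = 1.0 - (np.sum(resid**2) / (n - X.shape[1])) / (ss_tot / (n - 1))
    return EffectEstimate(
        beta_per100=b,
        ci_low=b - z975 * se[k],
        ci_high=b + z975 * se[k],
        p_value=float(p),
        method="iv_2sls",
        n=n,
        adjusted_r2=float(adj_r2),
        extra={"first_stage_F": float(f_stat)},
    )


def age_interaction_effect(fsiq, dr, age, covariates=None, weights=None) -> EffectEstimate:
    """DR x age interaction: change in the per-100 mg/kg slope per year of age."""
    d = np.asarray(dr, float) / 100.0
    a = np.asarray(age, float)
    inter = d * a
    base = np.column_stack([d, a, inter])
    if covariates is not None:
        base = np.column_stack([base, np.asarray(covariates, float)])
    X = np.column_stack([np.ones(len(d)), base])
    w = np.ones(len(d)) if weights is None else np.asarray(weights, float)
    res = sm.WLS(np.asarray(fsiq, float), X, weights=w).fit(cov_type="HC1")
    ci = res.conf_int()[3]
    return EffectEstimate(
        beta_per100=float(res.params[3]),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        p_value=float(res.pvalues[3]),
        method="dr_x_age_interaction",
        n=len(d),
        adjusted_r2=float(res.rsquared_adj),
        extra={"main_dr_per100": float(res.params[1])},
    )


def effect_to_iq_span(beta_per100: float, span: float = IQ_SPAN_MGKG) -> float:
    """Equivalent IQ difference over an exposure span: |beta| * span / 100."""
    if not np.isfinite(beta_per100):
        raise ValueError("beta must be finite")
    return abs(beta_per100) * span / 100.0
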