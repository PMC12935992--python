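"""Piecewise (segmented) dose-response of FSIQ on MC-PEI.

For each candidate breakpoint psi on a grid, fit the continuous broken-stick
model FSIQ ~ b0 + b1*x + b2*(x - psi)+ by (optionally IPTW-weighted) least
squares and keep the psi minimizing AIC, counting the breakpoint as one
extra parameter.  Slopes are reported per 100 mg/kg; the no-break linear
model's AIC is returned for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats


@dataclass
class PiecewiseFit:
    psi: float  # breakpoint, mg/kg
    slope_below: float  # IQ points per 100 mg/kg
    slope_above: float
    slope_below_ci: tuple[float, float]
    slope_above_ci: tuple[float, float]
    slope_below_p: float
    slope_above_p: float
    aic: float
    linear_aic: float
    grid: np.ndarray
    grid_aic: np.ndarray
    n: int

    @property
    def prefers_break(self) -> bool:
        return self.aic < self.linear_aic


def severity_adjustment_matrix(patients, severity_pred) -> np.ndarray:
    """Confounder columns for the adjusted dose-response model.

    The severity-model prediction summarizes the four residualization
    markers; the remaining measured confounders (burst-suppression duration,
    peak CRP, daily organ-dysfunction analogue score, MRI severity) and age
    enter directly, with log transforms for the right-skewed columns.
    """
    p = patients
    return np.column_stack(
        [
            np.asarray(severity_pred, float),
            np.log(p["burst_suppression_h"].to_numpy(float)),
            np.log(p["crp_peak"].to_numpy(float)),
            p["pmod_score"].to_numpy(float),
            p["mri_severity"].to_numpy(float),
            p["age_years"].to_numpy(float),
        ]
    )


def default_grid(mcpei, step: float = 50.0, lo_pct: float = 10.0, hi_pct: float = 90.0):
    lo, hi = np.percentile(np.asarray(mcpei, float), [lo_pct, hi_pct])
    start = np.ceil(lo / step) * step
    return np.arange(start, hi + 1e-9, step)


def fit_piecewise(fsiq, mcpei, weights=None, grid=None, covariates=None) -> PiecewiseFit:
    """AIC grid search for the breakpoint of a continuous piecewise line.

    ``covariates`` (severity/confounder columns) enter every candidate model
    linearly, so the segment slopes are identified from exposure variation
    net of illness severity -- the adjusted form of the dose-response model.
    """
    y = np.asarray(fsiq, float)
    x = np.asarray(mcpei, float)
    n = len(y)
    if n < 20:
        raise ValueError(f"need at least 20 patients, got {n}")
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    if grid is None:
        grid = default_grid(x)
    grid = np.asarray(grid, float)
    if grid.size == 0 or grid.min() <= x.min() or grid.max() >= x.max():
        raise ValueError("breakpoint grid must lie strictly inside the exposure range")
    C = None if covariates is None else np.asarray(covariates, float)

    def _design(cols):
        parts = [np.ones(n)] + cols
        if C is not None:
            parts.append(C)
        return np.column_stack(parts)

    linear = sm.WLS(y, _design([x]), weights=w).fit()
    linear_aic = float(linear.aic)

    best = None
    aics = np.empty(len(grid))
    for i, psi in enumerate(grid):
        X = _design([x, np.maximum(x - psi, 0.0)])
        res = sm.WLS(y, X, weights=w).fit()
        aic = float(res.aic) + 2.0  # breakpoint counts as one extra parameter
        aics[i] = aic
        if best is None or aic < best[0]:
            best = (aic, psi, res)
    aic, psi, res = best

    b1, b2 = res.params[1], res.params[2]
    cov = res.cov_params()
    se_below = np.sqrt(cov[1, 1])
    se_above = np.sqrt(cov[1, 1] + cov[2, 2] + 2.0 * cov[1, 2])
    dfree = res.df_resid
    tcrit = stats.t.ppf(0.975, dfree)
    slope_above = b1 + b2
    p_below = 2.0 * stats.t.sf(abs(b1 / se_below), dfree)
    p_above = 2.0 * stats.t.sf(abs(slope_above / se_above), dfree) if se_above > 0 else np.nan
    scale = 100.0
    return PiecewiseFit(
        psi=float(psi),
        slope_below=float(b1 * scale),
        slope_above=float(slope_above * scale),
        slope_below_ci=(float((b1 - tcrit * se_below) * scale), float((b1 + tcrit * se_below) * scale)),
        slope_above_ci=(
            float((slope_above - tcrit * se_above) * scale),
            float((slope_above + tcrit * se_above) * scale),
        ),
        slope_below_p=float(p_below),
        slope_above_p=float(p_above),
        aic=float(aic),
        linear_aic=linear_aic,
        grid=grid,
        grid_aic=aics,
        n=n,
    )


def threshold_alert(mcpei_running: float, threshold: float = 2000.0) -> bool:
    """True once the running cumulative MC-PEI reaches the review threshold."""
    if mcpei_running < 0:
        raise ValueError("running exposure must be non-negative")
    return bool(mcpei_running >= threshold)
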