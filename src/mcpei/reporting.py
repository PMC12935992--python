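"""Pipeline orchestration, group-comparison tests, and report tables.

``run_pipeline`` sequences simulate/ingest -> exposure -> residualize ->
estimate -> threshold -> sensitivity -> report, writing the standard output
files (exposure.csv, dose_residuals.csv, balance_table.csv, effects.csv,
piecewise.json, sensitivity.csv, outcome_table.csv, manifest.json).  Every
output carries the run seed and a hash of the configuration so a run can be
reproduced bit for bit from its manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from . import causal, residualize, sensitivity as sens, simulate, threshold
from .exposure import summarize_exposure

log = logging.getLogger("mcpei")

OUTPUT_FILES = (
    "exposure.csv",
    "dose_residuals.csv",
    "balance_table.csv",
    "effects.csv",
    "piecewise.json",
    "sensitivity.csv",
    "outcome_table.csv",
    "manifest.json",
)


@dataclass
class PipelineConfig:
    """Everything a full run needs; hashable for the manifest."""

    preset: str | None = "default_paper"
    patients_path: str | None = None
    infusion_path: str | None = None
    outcomes_path: str | None = None
    n_patients: int | None = None
    seed: int = simulate.DEFAULT_SEED
    out_dir: str = "mcpei_results"
    stabilized_weights: bool = True
    doubly_robust: bool = False
    grid_step: float = 50.0
    quantiles: tuple[float, ...] = (0.25, 0.5, 0.75)
    run_sensitivity: bool = True
    power_reps: int = 10_000

    def config_hash(self) -> str:
        payload = {k: v for k, v in dataclasses.asdict(self).items() if k != "out_dir"}
        digest = hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode())
        return digest.hexdigest()[:16]

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def group_tests(groups, kind: str = "continuous") -> tuple[float, float]:
    """Kruskal-Wallis (continuous rows) or Pearson chi-square (categorical).

    ``groups``: list of value arrays (continuous) or list of count vectors
    (categorical).  Chi-square uses no continuity correction.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if kind == "continuous":
        for g in groups:
            if len(g) < 2:
                raise ValueError("empty or singleton group")
        stat, p = stats.kruskal(*groups)
        return float(stat), float(p)
    if kind == "categorical":
        table = np.asarray(groups, float)
        if table.ndim == 1 or np.any(table.sum(axis=1) == 0):
            raise ValueError("each group needs counts over at least one level")
        stat, p, *_ = stats.chi2_contingency(table, correction=False)
        return float(stat), float(p)
    raise ValueError("kind must be 'continuous' or 'categorical'")


_OUTCOME_ROWS = ("intellectual_disability", "school_reentry", "active_epilepsy")


def build_outcome_table(
    outcomes: pd.DataFrame,
    tertiles,
    adjust: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Secondary-outcome table by DR tertile.

    Per-tertile counts and percentages, crude high-vs-low odds ratio,
    optional covariate-adjusted OR (logistic high-vs-low indicator plus the
    ``adjust`` columns), and the Cochran-Armitage trend p across ordered
    tertiles.  Crude and adjusted ORs are emitted side by side and labelled.
    """
    t = np.asarray(tertiles)
    rows = []
    for col in _OUTCOME_ROWS:
        if col not in outcomes.columns:
            continue
        y = outcomes[col].to_numpy(int)
        events, totals = [], []
        cells = {}
        for g in residualize.TERTILE_LABELS:
            yg = y[t == g]
            events.append(int(yg.sum()))
            totals.append(len(yg))
            pct = 100.0 * yg.mean() if len(yg) else np.nan
            cells[g] = f"{int(yg.sum())} ({pct:.1f}%)"
        z, trend_p = sens.cochran_armitage_trend(events, totals)
        hl = (t == "high") | (t == "low")
        y_hl = y[hl]
        x_hl = (t[hl] == "high").astype(int)
        a = y[(t == "high")].sum()
        b = (t == "high").sum() - a
        c = y[(t == "low")].sum()
        d = (t == "low").sum() - c
        if min(a, b, c, d) == 0 or y.min() == y.max():
            or_crude, or_lo, or_hi = np.nan, np.nan, np.nan
            flag = "OR undefined (zero cell)"
        else:
            or_crude = (a * d) / (b * c)
            se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
            zc = stats.norm.ppf(0.975)
            or_lo = np.exp(np.log(or_crude) - zc * se)
            or_hi = np.exp(np.log(or_crude) + zc * se)
            flag = ""
        or_adj = np.nan
        if adjust is not None and not np.isnan(or_crude):
            X = sm.add_constant(
                np.column_stack([x_hl, np.asarray(adjust, float)[hl]])
            )
            try:
                res = sm.Logit(y_hl, X).fit(disp=0)
                or_adj = float(np.exp(res.params[1]))
            except Exception:  # separation on a small stratum
                or_adj = np.nan
        rows.append(
            {
                "outcome": col,
                "low": cells["low"],
                "middle": cells["middle"],
                "high": cells["high"],
                "or_crude_high_vs_low": or_crude,
                "or_crude_ci_low": or_lo,
                "or_crude_ci_high": or_hi,
                "or_adjusted_high_vs_low": or_adj,
                "trend_z": z,
                "trend_p": trend_p,
                "note": flag,
            }
        )
    return pd.DataFrame(rows)


def _write_csv(df: pd.DataFrame, path: str, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def _write_json(obj, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=float)


def load_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write all outputs; returns the bundle."""
    os.makedirs(config.out_dir, exist_ok=True)
    chash = config.config_hash()
    header = f"# mcpei seed={config.seed} config_hash={chash}\n"
    meta = {"seed": config.seed, "config_hash": chash}

    def stage(name):
        log.info("stage: %s", name)

    try:
        stage("ingest")
        if config.patients_path:
            patients = load_table(config.patients_path)
            infusion = load_table(config.infusion_path)
            outcomes = load_table(config.outcomes_path)
            for col in ("patient_id", "age_years", "sex", "weight_kg", "height_cm",
                        "bmi_percentile", "year"):
                if col not in patients.columns:
                    raise ValueError(f"patients table missing required column {col!r}")
            truth = None
        else:
            cfg = simulate.get_preset(
                config.preset or "default_paper",
                seed=config.seed,
                **({"n_patients": config.n_patients} if config.n_patients else {}),
            )
            tables = simulate.generate_cohort(cfg)
            tables.write(config.out_dir, header=header)
            patients, infusion, outcomes = tables.patients, tables.infusion_days, tables.outcomes
            truth = tables.truth
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'ingest' failed: {exc}") from exc

    bundle = {"meta": meta}
    try:
        stage("exposure")
        exposure = summarize_exposure(patients, infusion)
        _write_csv(exposure, os.path.join(config.out_dir, "exposure.csv"), header)
        bundle["exposure"] = exposure
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'exposure' failed: {exc}") from exc

    try:
        stage("residualize")
        merged = patients.merge(exposure, on="patient_id").merge(outcomes, on="patient_id")
        fit = residualize.fit_severity_model(
            merged["mcpei_mgkg"].to_numpy(), merged, seed=config.seed
        )
        dr_records = residualize.dose_residual_table(
            merged[["patient_id", "mcpei_mgkg"]], fit
        )
        _write_csv(dr_records, os.path.join(config.out_dir, "dose_residuals.csv"), header)
        bal_dr = residualize.balance_table(patients, exposure, dr_records, "dr")
        bal_raw = residualize.balance_table(patients, exposure, dr_records, "raw_dose")
        bal_dr.insert(0, "stratifier", "dr")
        bal_raw.insert(0, "stratifier", "raw_dose")
        balance = pd.concat([bal_dr, bal_raw], ignore_index=True)
        _write_csv(balance, os.path.join(config.out_dir, "balance_table.csv"), header)
        bundle.update(severity_fit=fit, dr_records=dr_records, balance=balance)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'residualize' failed: {exc}") from exc

    try:
        stage("estimate")
        cov = causal.design_matrix(merged, infusion)
        X = cov[list(causal.PROPENSITY_COVARIATES)]
        weights = causal.fit_propensity_weights(
            dr_records["tertile"].to_numpy(), X, stabilized=config.stabilized_weights
        )
        fsiq = merged["fsiq"].to_numpy()
        dr = dr_records["dr"].to_numpy()
        iptw = causal.iptw_effect(
            fsiq, dr, weights.weights,
            covariates=X if config.doubly_robust else None,
        )
        ols = causal.ols_effect(fsiq, dr, covariates=X)
        iv = causal.iv_2sls_effect(fsiq, dr, merged["year"].to_numpy(), covariates=X)
        inter = causal.age_interaction_effect(
            fsiq, dr, merged["age_years"].to_numpy(), weights=weights.weights
        )
        effects = pd.DataFrame(
            [
                {
                    "method": e.method,
                    "beta_per100": e.beta_per100,
                    "ci_low": e.ci_low,
                    "ci_high": e.ci_high,
                    "p_value": e.p_value,
                    "adj_r2": e.adjusted_r2,
                    "equivalent_iq_span": causal.effect_to_iq_span(e.beta_per100),
                    "n": e.n,
                }
                for e in (iptw, ols, iv, inter)
            ]
        )
        _write_csv(effects, os.path.join(config.out_dir, "effects.csv"), header)
        bundle.update(weights=weights, effects=effects, iptw=iptw, ols=ols, iv=iv)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'estimate' failed: {exc}") from exc

    try:
        stage("threshold")
        pw = threshold.fit_piecewise(
            fsiq, merged["mcpei_mgkg"].to_numpy(), weights=weights.weights,
            grid=threshold.default_grid(merged["mcpei_mgkg"], step=config.grid_step),
            covariates=threshold.severity_adjustment_matrix(merged, fit.predicted),
        )
        pw_json = {
            "psi_mgkg": pw.psi,
            "slope_below_per100": pw.slope_below,
            "slope_above_per100": pw.slope_above,
            "slope_below_ci": list(pw.slope_below_ci),
            "slope_above_ci": list(pw.slope_above_ci),
            "slope_below_p": pw.slope_below_p,
            "slope_above_p": pw.slope_above_p,
            "aic": pw.aic,
            "linear_aic": pw.linear_aic,
            **meta,
        }
        _write_json(pw_json, os.path.join(config.out_dir, "piecewise.json"))
        bundle["piecewise"] = pw
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'threshold' failed: {exc}") from exc

    try:
        stage("sensitivity")
        if config.run_sensitivity:
            report = sens.run_sensitivity_variants(
                patients, infusion, outcomes, seed=config.seed
            )
            rr = sens.beta_to_rr(iptw.beta_per100, outcome_sd=float(np.std(fsiq, ddof=1)))
            report.evalue_rr = rr
            report.evalue = sens.evalue_from_rr(rr)
            report.leave_one_out_range = sens.leave_one_out(fsiq, dr, weights.weights)
            report.quantile_betas = sens.quantile_effects(
                fsiq, dr, weights.weights, config.quantiles
            )
            report.negative_control = sens.negative_control(
                merged["catheter_infection"].to_numpy(), dr
            )
            t = dr_records["tertile"].to_numpy()
            id_events = [
                int(merged.loc[t == g, "intellectual_disability"].sum())
                for g in residualize.TERTILE_LABELS
            ]
            id_totals = [int((t == g).sum()) for g in residualize.TERTILE_LABELS]
            z, p_trend = sens.cochran_armitage_trend(id_events, id_totals)
            report.trend_tests = {"intellectual_disability": {"z": z, "p": p_trend}}
            n_low = id_totals[0]
            n_high = id_totals[2]
            report.power = {
                "diff_iq": 8.0,
                "sd_iq": 12.5,
                "n1": n_low,
                "n2": n_high,
                "alpha": 0.05,
                "power": sens.power_simulation(
                    8.0, 12.5, n_low, n_high, reps=config.power_reps, seed=config.seed
                ),
            }
            _write_csv(
                report.to_frame(), os.path.join(config.out_dir, "sensitivity.csv"), header
            )
            _write_json(
                {
                    "evalue": report.evalue,
                    "approx_rr": report.evalue_rr,
                    "leave_one_out_beta_range": report.leave_one_out_range,
                    "quantile_betas": report.quantile_betas,
                    "negative_control": report.negative_control,
                    "trend_tests": report.trend_tests,
                    "power": report.power,
                    **meta,
                },
                os.path.join(config.out_dir, "sensitivity_extras.json"),
            )
            bundle["sensitivity"] = report
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'sensitivity' failed: {exc}") from exc

    try:
        stage("report")
        outcome_table = build_outcome_table(
            merged,
            dr_records["tertile"].to_numpy(),
            adjust=merged[["age_years"]].assign(
                sex_male=(merged["sex"].astype(str).str.upper().str[0] == "M").astype(int)
            ),
        )
        _write_csv(outcome_table, os.path.join(config.out_dir, "outcome_table.csv"), header)
        manifest = {
            **meta,
            "preset": config.preset,
            "n_patients": int(len(patients)),
            "schema_version": simulate.SCHEMA_VERSION,
            "outputs": sorted(
                f for f in os.listdir(config.out_dir) if f.endswith((".csv", ".json"))
            ),
            "config": {k: v for k, v in dataclasses.asdict(config).items()},
        }
        _write_json(manifest, os.path.join(config.out_dir, "manifest.json"))
        bundle.update(outcome_table=outcome_table, manifest=manifest, truth=truth)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'report' failed: {exc}") from exc

    return bundle
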