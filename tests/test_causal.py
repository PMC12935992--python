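"""Propensity weights, IPTW/OLS/2SLS estimators, effect translation."""

import numpy as np
import pandas as pd
import pytest

import mcpei.causal as causal
from mcpei.causal import (
    WeakInstrumentWarning,
    effect_to_iq_span,
    fit_propensity_weights,
    age_interaction_effect,
    iptw_effect,
    iv_2sls_effect,
    ols_effect,
)
from mcpei.sensitivity import primary_chain
from mcpei.simulate import generate_cohort, get_preset


def _random_tertiles(rng, n):
    return rng.choice(["low", "middle", "high"], size=n)


class TestPropensityWeights:
    def test_independent_covariates_give_unit_weights(self):
        rng = np.random.default_rng(0)
        n = 900
        t = _random_tertiles(rng, n)
        X = pd.DataFrame(rng.normal(size=(n, 4)))
        pw = fit_propensity_weights(t, X)
        assert pw.weights.mean() == pytest.approx(1.0, abs=0.05)
        assert np.all(np.abs(pw.weights - 1.0) < 0.5)

    def test_truncation_clips_to_bounds(self, default_chain):
        pw = default_chain.weights
        lo, hi = pw.truncation_bounds
        assert pw.weights.min() >= lo - 1e-12
        assert pw.weights.max() <= hi + 1e-12

    def test_probabilities_are_simplex_rows(self, default_chain):
        np.testing.assert_allclose(default_chain.weights.probabilities.sum(axis=1), 1.0)

    def test_perfect_separation_raises(self):
        rng = np.random.default_rng(1)
        n = 90
        t = np.repeat(["low", "middle", "high"], 30)
        X = pd.DataFrame({"sep": np.repeat([0.0, 1.0, 2.0], 30),
                          "noise": rng.normal(size=n)})
        with pytest.raises(ValueError, match="separation"):
            fit_propensity_weights(t, X)

    def test_small_tertile_rejected(self):
        t = np.array(["low"] * 10 + ["middle"] * 10 + ["high"] * 2)
        X = pd.DataFrame(np.random.default_rng(2).normal(size=(22, 2)))
        with pytest.raises(ValueError, match="3 patients"):
            fit_propensity_weights(t, X)


class TestEffectEstimators:
    def test_unit_weights_reproduce_ols(self):
        rng = np.random.default_rng(3)
        n = 200
        dr = rng.normal(0, 500, n)
        y = 70 - 0.4 * dr / 100 + rng.normal(0, 5, n)
        a = iptw_effect(y, dr, np.ones(n))
        b = ols_effect(y, dr)
        assert a.beta_per100 == pytest.approx(b.beta_per100, abs=1e-10)

    def test_zero_noise_linear_truth_exact(self):
        rng = np.random.default_rng(4)
        dr = rng.normal(0, 400, 100)
        y = 80 - 0.33 * dr / 100
        est = ols_effect(y, dr)
        assert est.beta_per100 == pytest.approx(-0.33, abs=1e-9)

    def test_per100_scaling_identity(self):
        """Slope on mg/kg equals the per-100 slope / 100 with identical p."""
        rng = np.random.default_rng(5)
        n = 150
        dr = rng.normal(0, 300, n)
        y = 75 - 0.5 * dr / 100 + rng.normal(0, 8, n)
        import statsmodels.api as sm

        raw = sm.OLS(y, sm.add_constant(dr)).fit()
        est = ols_effect(y, dr)
        assert est.beta_per100 == pytest.approx(raw.params[1] * 100)
        assert est.p_value == pytest.approx(raw.pvalues[1])

    def test_orthogonal_covariates_leave_slope_unchanged(self):
        rng = np.random.default_rng(6)
        n = 4000
        dr = rng.normal(0, 300, n)
        C = rng.normal(size=(n, 2))  # independent of dr
        y = 70 - 0.4 * dr / 100 + C @ [2.0, -1.0] + rng.normal(0, 3, n)
        simple = ols_effect(y, dr)
        multi = ols_effect(y, dr, covariates=C)
        assert multi.beta_per100 == pytest.approx(simple.beta_per100, abs=0.03)

    def test_collinear_design_rejected(self):
        dr = np.arange(50.0)
        C = np.column_stack([dr / 100.0])  # duplicates the exposure column
        with pytest.raises(ValueError, match="collinear"):
            ols_effect(np.ones(50), dr, covariates=C)

    def test_ci_brackets_estimate(self, default_chain):
        e = default_chain.effect
        assert e.ci_low <= e.beta_per100 <= e.ci_high


class TestInstrumentalVariable:
    def _simulate_iv(self, n=8000, beta=-0.4, exclusion_violation=0.0, seed=0):
        rng = np.random.default_rng(seed)
        year = rng.integers(2014, 2023, n).astype(float)
        u = rng.normal(size=n)  # unobserved confounder
        dr = 80.0 * (year - 2018) + 300.0 * u + rng.normal(0, 300, n)
        y = 70 + beta * dr / 100 - 4.0 * u + rng.normal(0, 5, n)
        y = y + exclusion_violation * (year - 2018)
        return y, dr, year

    def test_recovers_truth_when_ols_is_confounded(self):
        y, dr, year = self._simulate_iv()
        iv = iv_2sls_effect(y, dr, year)
        ols = ols_effect(y, dr)
        assert iv.beta_per100 == pytest.approx(-0.4, abs=0.08)
        assert abs(ols.beta_per100 - (-0.4)) > abs(iv.beta_per100 - (-0.4))

    def test_matches_statsmodels_reference(self):
        from statsmodels.sandbox.regression.gmm import IV2SLS

        y, dr, year = self._simulate_iv(n=500, seed=1)
        iv = iv_2sls_effect(y, dr, year)
        n = len(y)
        ref = IV2SLS(
            y,
            np.column_stack([np.ones(n), dr / 100.0]),
            instrument=np.column_stack([np.ones(n), year]),
        ).fit()
        assert iv.beta_per100 == pytest.approx(ref.params[1], abs=1e-8)

    def test_constant_instrument_rejected(self):
        y, dr, _ = self._simulate_iv(n=100)
        with pytest.raises(ValueError, match="constant"):
            iv_2sls_effect(y, dr, np.full(100, 2018.0))

    def test_weak_instrument_warning(self):
        c = generate_cohort(get_preset("default_paper", seed=2, n_patients=120,
                                       instrument_strength=0.0))
        ch = primary_chain(c.patients, c.infusion_days, c.outcomes, seed=0)
        m = ch.patients
        with pytest.warns(WeakInstrumentWarning):
            iv_2sls_effect(
                m["fsiq"].to_numpy(),
                ch.dr_records["dr"].to_numpy(),
                m["year"].to_numpy(),
            )

    def test_broken_exclusion_detected_against_oracle(self):
        """Instrument leaking directly into the outcome biases 2SLS."""
        y, dr, year = self._simulate_iv(exclusion_violation=2.0)
        iv = iv_2sls_effect(y, dr, year)
        assert abs(iv.beta_per100 - (-0.4)) > 0.5


class TestAgeInteraction:
    def _fixture(self, interaction, seed=0, n=2000):
        rng = np.random.default_rng(seed)
        dr = rng.normal(0, 600, n)
        age = rng.uniform(1, 14, n)
        y = 72 - 0.41 * dr / 100 + interaction * (dr / 100) * age + rng.normal(0, 6, n)
        return y, dr, age

    def test_null_interaction_ci_covers_zero(self):
        y, dr, age = self._fixture(0.0)
        est = age_interaction_effect(y, dr, age)
        assert est.ci_low <= 0.0 <= est.ci_high

    def test_recovery_of_configured_modification(self):
        y, dr, age = self._fixture(-0.08)
        est = age_interaction_effect(y, dr, age)
        assert est.beta_per100 == pytest.approx(-0.08, abs=0.04)

    def test_centering_age_leaves_interaction_unchanged(self):
        y, dr, age = self._fixture(-0.08, seed=1)
        a = age_interaction_effect(y, dr, age)
        b = age_interaction_effect(y, dr, age - age.mean())
        assert a.beta_per100 == pytest.approx(b.beta_per100, abs=1e-8)


@pytest.mark.parametrize(
    "beta, expected",
    [(-0.41, 8.2), (-0.35, 7.0), (-0.27, 5.4), (0.0, 0.0)],
)
def test_effect_to_iq_span(beta, expected):
    assert effect_to_iq_span(beta) == pytest.approx(expected)


def test_effect_to_iq_span_rejects_nonfinite():
    with pytest.raises(ValueError):
        effect_to_iq_span(np.nan)


def test_iptw_no_less_than_ols_under_confounding():
    """Seed-averaged attenuation ordering: the unweighted multivariable
    model absorbs part of the dose-residual signal into covariates, so its
    slope magnitude does not exceed the IPTW slope on average."""
    bi, bo = [], []
    for seed in range(12):
        c = generate_cohort(get_preset("strong_confounding", seed=400 + seed, n_patients=300))
        ch = primary_chain(c.patients, c.infusion_days, c.outcomes, seed=seed)
        m = ch.patients
        inf = c.infusion_days[c.infusion_days["patient_id"].isin(m["patient_id"])]
        X = causal.design_matrix(m, inf)[list(causal.PROPENSITY_COVARIATES)]
        bo.append(ols_effect(m["fsiq"].to_numpy(), ch.dr_records["dr"].to_numpy(), X).beta_per100)
        bi.append(ch.effect.beta_per100)
    assert abs(np.mean(bo)) <= abs(np.mean(bi))
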