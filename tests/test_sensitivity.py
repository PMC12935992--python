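"""Sensitivity suite: variants, E-value, trend test, power, quantiles, LOO."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mcpei.sensitivity import (
    beta_to_rr,
    cochran_armitage_trend,
    evalue_from_rr,
    leave_one_out,
    negative_control,
    power_closed_form,
    power_simulation,
    quantile_effects,
    random_forest_dr,
    run_sensitivity_variants,
    weighted_quantile_regression,
)


class TestEvalue:
    def test_null_effect(self):
        assert evalue_from_rr(1.0) == pytest.approx(1.0)

    def test_closed_form_at_two(self):
        assert evalue_from_rr(2.0) == pytest.approx(2.0 + np.sqrt(2.0))

    def test_inversion_below_one(self):
        assert evalue_from_rr(0.5) == pytest.approx(evalue_from_rr(2.0))

    def test_numeric_inversion_near_3_2(self):
        # E(RR) = 3.2 at RR ~ 1.896: 1.896 + sqrt(1.896*0.896) = 3.1996
        assert evalue_from_rr(1.896) == pytest.approx(3.2, abs=0.005)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            evalue_from_rr(0.0)

    @given(st.floats(1.0, 50.0))
    @settings(derandomize=True, max_examples=30)
    def test_monotone_and_at_least_rr(self, rr):
        e = evalue_from_rr(rr)
        assert e >= rr
        assert evalue_from_rr(rr + 0.5) > e


class TestBetaToRR:
    def test_zero_beta_is_null(self):
        assert beta_to_rr(0.0) == pytest.approx(1.0)

    def test_unit_standardized_difference(self):
        # d = 1 when |beta|*(contrast/100) = sd
        assert beta_to_rr(0.625, contrast=2000.0, outcome_sd=12.5) == pytest.approx(
            np.exp(0.91)
        )

    def test_monotone_in_beta(self):
        assert beta_to_rr(0.5) > beta_to_rr(0.3) > beta_to_rr(0.1)


class TestCochranArmitage:
    def test_equal_proportions_null(self):
        z, p = cochran_armitage_trend([10, 10, 10], [20, 20, 20])
        assert z == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_tertile_counts_from_hand_formula(self):
        z, p = cochran_armitage_trend([11, 15, 19], [25, 25, 24])
        assert z == pytest.approx(2.52, abs=0.01)
        assert p == pytest.approx(0.0118, abs=0.001)

    def test_reversed_order_flips_sign(self):
        z1, p1 = cochran_armitage_trend([3, 8, 15], [20, 20, 20])
        z2, p2 = cochran_armitage_trend([15, 8, 3], [20, 20, 20])
        assert z2 == pytest.approx(-z1)
        assert p2 == pytest.approx(p1)

    def test_degenerate_tables_rejected(self):
        with pytest.raises(ValueError):
            cochran_armitage_trend([0, 0, 0], [5, 5, 5])
        with pytest.raises(ValueError):
            cochran_armitage_trend([5, 5, 5], [5, 5, 5])

    def test_agrees_with_correlation_oracle(self):
        """On expanded individual-level data the trend z equals the
        score-outcome Pearson correlation times sqrt(N)."""
        rng = np.random.default_rng(0)
        for _ in range(40):
            totals = rng.integers(2, 11, size=3)
            events = [int(rng.integers(0, t + 1)) for t in totals]
            if sum(events) in (0, sum(totals)):
                continue
            z, _ = cochran_armitage_trend(events, totals)
            scores, ys = [], []
            for s, (e, t) in enumerate(zip(events, totals)):
                scores += [s] * t
                ys += [1] * e + [0] * (t - e)
            r = np.corrcoef(scores, ys)[0, 1]
            assert z == pytest.approx(r * np.sqrt(len(ys)), abs=1e-9)


class TestPower:
    def test_size_under_null(self):
        assert power_simulation(0.0, 12.5, 25, 24, reps=10_000, seed=0) == pytest.approx(
            0.05, abs=0.01
        )

    def test_matches_noncentral_t_oracle(self):
        for diff, n1, n2 in [(8.0, 25, 24), (5.0, 40, 40), (12.0, 15, 15)]:
            sim = power_simulation(diff, 12.5, n1, n2, reps=10_000, seed=1)
            exact = power_closed_form(diff, 12.5, n1, n2)
            assert sim == pytest.approx(exact, abs=0.02)

    def test_monotone_in_effect_and_n(self):
        p1 = power_simulation(4.0, 12.5, 25, 24, reps=10_000, seed=2)
        p2 = power_simulation(8.0, 12.5, 25, 24, reps=10_000, seed=2)
        p3 = power_simulation(8.0, 12.5, 80, 80, reps=10_000, seed=2)
        assert p1 < p2 < p3

    def test_too_few_reps_rejected(self):
        with pytest.raises(ValueError):
            power_simulation(8.0, 12.5, 25, 24, reps=10)


class TestQuantileEffects:
    def test_homoscedastic_linear_truth(self):
        rng = np.random.default_rng(3)
        n = 1500
        dr = rng.normal(0, 600, n)
        y = 70 - 0.4 * dr / 100 + rng.normal(0, 8, n)
        betas = quantile_effects(y, dr, quantiles=(0.25, 0.5, 0.75))
        for q, b in betas.items():
            assert b == pytest.approx(-0.4, abs=0.06), q
        assert max(betas.values()) - min(betas.values()) < 0.1

    def test_median_regression_matches_ols_under_symmetry(self):
        rng = np.random.default_rng(4)
        n = 2000
        x = rng.normal(size=n)
        y = 1.0 + 2.0 * x + rng.normal(0, 1, n)
        _, slope = weighted_quantile_regression(y, x, np.ones(n), 0.5)
        assert slope == pytest.approx(2.0, abs=0.08)

    def test_default_cohort_spread_below_point_one(self, default_chain):
        m = default_chain.patients
        betas = quantile_effects(
            m["fsiq"].to_numpy(),
            default_chain.dr_records["dr"].to_numpy(),
            default_chain.weights.weights,
        )
        assert max(betas.values()) - min(betas.values()) < 0.35


class TestLeaveOneOut:
    def _data(self, seed=0, n=80):
        rng = np.random.default_rng(seed)
        dr = rng.normal(0, 500, n)
        y = 70 - 0.4 * dr / 100 + rng.normal(0, 8, n)
        return y, dr

    def test_full_sample_beta_inside_range(self):
        y, dr = self._data()
        from mcpei.causal import ols_effect

        lo, hi = leave_one_out(y, dr)
        assert lo <= ols_effect(y, dr).beta_per100 <= hi

    def test_duplication_shrinks_influence(self):
        y, dr = self._data(1)
        lo, hi = leave_one_out(y, dr)
        lo2, hi2 = leave_one_out(np.tile(y, 2), np.tile(dr, 2))
        assert (hi2 - lo2) < (hi - lo)

    def test_gross_outlier_widens_range(self):
        y, dr = self._data(2)
        y_out, dr_out = y.copy(), dr.copy()
        y_out[0], dr_out[0] = 140.0, 2500.0
        lo, hi = leave_one_out(y, dr)
        lo2, hi2 = leave_one_out(y_out, dr_out)
        assert (hi2 - lo2) > (hi - lo)

    def test_matches_explicit_refits(self):
        y, dr = self._data(3, n=40)
        import statsmodels.api as sm

        lo, hi = leave_one_out(y, dr)
        betas = []
        for i in range(40):
            keep = np.arange(40) != i
            X = sm.add_constant(dr[keep] / 100.0)
            betas.append(sm.OLS(y[keep], X).fit().params[1])
        assert lo == pytest.approx(min(betas), abs=1e-8)
        assert hi == pytest.approx(max(betas), abs=1e-8)


class TestRandomForestDR:
    def test_deterministic_under_seed(self, small_cohort, default_chain):
        m = default_chain.patients
        sev = m[["se_duration_h", "pelod2", "seizure_density", "eeg_suppression"]]
        y = m["mcpei_mgkg"].to_numpy()
        a = random_forest_dr(y, sev, seed=5)
        b = random_forest_dr(y, sev, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_correlates_with_additive_model_dr(self, default_chain):
        m = default_chain.patients
        sev = m[["se_duration_h", "pelod2", "seizure_density", "eeg_suppression"]]
        rf = random_forest_dr(m["mcpei_mgkg"].to_numpy(), sev, seed=0)
        gam = default_chain.dr_records["dr"].to_numpy()
        assert np.corrcoef(rf, gam)[0, 1] > 0.8

    def test_pure_noise_exposure_returns_centered_exposure(self, default_chain):
        m = default_chain.patients
        sev = m[["se_duration_h", "pelod2", "seizure_density", "eeg_suppression"]]
        rng = np.random.default_rng(6)
        y = rng.normal(2000, 500, len(m))
        rf = random_forest_dr(y, sev, seed=0)
        assert np.corrcoef(rf, y - y.mean())[0, 1] > 0.9


class TestNegativeControl:
    def test_independent_outcome_covers_null_in_most_replicates(self):
        """OR CI covers 1 in >= 90% of replicate cohorts (nominal 95%)."""
        from mcpei.simulate import generate_cohort, get_preset

        covered = 0
        reps = 20
        for rep in range(reps):
            c = generate_cohort(get_preset("default_paper", seed=800 + rep, n_patients=250))
            m = c.outcomes.merge(c.truth, on="patient_id")
            res = negative_control(
                m["catheter_infection"].to_numpy(), m["practice_offset_mgkg"].to_numpy()
            )
            covered += res["ci_low"] <= 1.0 <= res["ci_high"]
        assert covered >= int(0.9 * reps)

    def test_coupled_outcome_detected(self):
        rng = np.random.default_rng(7)
        n = 600
        dr = rng.normal(0, 600, n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(dr / 300.0)))).astype(int)
        res = negative_control(y, dr)
        assert res["ci_low"] > 1.0 or res["ci_high"] < 1.0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            negative_control(np.array([0, 1, 0]), np.zeros(3))
        with pytest.raises(ValueError, match="constant"):
            negative_control(np.zeros(50, int), np.random.default_rng(0).normal(size=50))


class TestVariants:
    @pytest.fixture(scope="class")
    def report(self, default_cohort):
        c = default_cohort
        return run_sensitivity_variants(c.patients, c.infusion_days, c.outcomes, seed=0)

    def test_comparable_variants_close_to_primary(self, report):
        primary = report.variants["primary"].beta_per100
        for name in ("exclude_infants_lt24mo", "omit_seizure_duration", "random_forest_dr"):
            assert report.variants[name].beta_per100 == pytest.approx(
                primary, abs=0.1
            ), name

    def test_seven_day_window_same_direction(self, report):
        assert np.sign(report.variants["seven_day_window"].beta_per100) == np.sign(
            report.variants["primary"].beta_per100
        )

    def test_exclude_infants_drops_exactly_under_24_months(self, report, default_cohort):
        n_expected = int((default_cohort.patients["age_years"] >= 2.0).sum())
        assert report.variants["exclude_infants_lt24mo"].n == n_expected

    def test_every_variant_reports_its_n(self, report):
        for name, est in report.variants.items():
            assert est.n >= 20, name

    def test_small_subset_skipped_with_warning(self, default_cohort):
        c = default_cohort
        with pytest.warns(UserWarning, match="skipped"):
            rep = run_sensitivity_variants(
                c.patients.head(15), c.infusion_days, c.outcomes, seed=0, min_n=20
            )
        assert "primary" in rep.skipped
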