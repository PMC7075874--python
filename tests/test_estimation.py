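import numpy as np
import pytest
import statsmodels.api as sm

from nlari import (
    NLARIEstimator,
    detrend,
    estimate,
    fit_nlari,
    simulate_y_batch,
    to_log_hr,
)
from nlari.estimation import _design, fit_batch


class TestToLogHR:
    def test_unit_rr_is_ln_60(self):
        h = to_log_hr([1.0], kind="rr_seconds")
        assert h.x[0] == pytest.approx(np.log(60.0), rel=1e-12)

    def test_rr_and_hr_paths_agree(self):
        assert to_log_hr([1.0], "rr_seconds").x[0] == to_log_hr([60.0], "hr_bpm").x[0]

    def test_nonpositive_value_names_index(self):
        with pytest.raises(ValueError, match="index 2"):
            to_log_hr([0.8, 0.9, 0.0, 1.0], "rr_seconds")


class TestDetrend:
    def test_exact_line_gives_zero_residuals(self):
        t = np.arange(1, 101)
        tf = detrend(2.0 + 0.01 * t)
        assert tf.a_hat == pytest.approx(2.0, abs=1e-10)
        assert tf.b_hat == pytest.approx(0.01, abs=1e-12)
        assert np.allclose(tf.y, 0.0, atol=1e-10)

    def test_constant_series(self):
        tf = detrend(np.full(50, 3.3))
        assert tf.b_hat == pytest.approx(0.0, abs=1e-14)
        assert np.allclose(tf.y, 0.0, atol=1e-12)

    def test_residuals_sum_to_zero(self, stable_sim):
        tf = detrend(stable_sim.x)
        assert abs(tf.y.sum()) < 1e-8

    def test_slope_recovery_monte_carlo(self, stable_params):
        rng = np.random.default_rng(3)
        y = simulate_y_batch(0.2214, 0.3, 0.0275, 20000, rng, reps=5)
        x = y + 0.001 * np.arange(1, 20001)
        slopes = [detrend(row).b_hat for row in x]
        assert np.mean(slopes) == pytest.approx(0.001, abs=1e-4)


class TestFitNlari:
    def test_statsmodels_ols_oracle(self, stable_sim):
        """The hand-rolled normal-equations fit must agree with an
        independently computed OLS (statsmodels) on the same design."""
        y = detrend(stable_sim.x).y
        f = fit_nlari(y)
        resp, Z = _design(y, 1)
        res = sm.OLS(resp, Z).fit()
        assert f.theta1_hat == pytest.approx(res.params[0], rel=1e-9)
        assert f.theta2_hat == pytest.approx(res.params[1], rel=1e-9)
        assert f.s1 == pytest.approx(res.bse[0], rel=1e-9)
        assert f.s2 == pytest.approx(res.bse[1], rel=1e-9)
        # sigma_hat uses denominator rows-2, exactly statsmodels' df_resid
        assert f.sigma_hat == pytest.approx(np.sqrt(res.mse_resid), rel=1e-9)
        assert f.rows_used == resp.size

    def test_brute_force_grid_oracle(self):
        """On a tiny series the normal-equations solution beats every point
        of a fine (theta1, theta2) grid in residual sum of squares."""
        rng = np.random.default_rng(8)
        y = simulate_y_batch(0.2, 0.5, 0.3, 25, rng, reps=1)[0]
        f = fit_nlari(y)
        resp, Z = _design(y, 1)
        g1 = np.linspace(f.theta1_hat - 0.05, f.theta1_hat + 0.05, 41)
        g2 = np.linspace(f.theta2_hat - 0.05, f.theta2_hat + 0.05, 41)
        rss_grid = np.array(
            [[np.sum((resp - a * Z[:, 0] - b * Z[:, 1]) ** 2) for b in g2] for a in g1]
        )
        assert f.rss <= rss_grid.min() + 1e-12
        i, j = np.unravel_index(rss_grid.argmin(), rss_grid.shape)
        assert abs(g1[i] - f.theta1_hat) <= (g1[1] - g1[0])
        assert abs(g2[j] - f.theta2_hat) <= (g2[1] - g2[0])

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError):
            fit_nlari(np.zeros(100))

    def test_gamma_two_routes_agree(self, stable_sim):
        f = fit_nlari(detrend(stable_sim.x).y)
        alpha_hat = 1.0 - f.theta1_hat
        assert f.gamma_hat == pytest.approx(
            f.theta2_hat / (4.0 - 2.0 * alpha_hat), rel=1e-12
        )

    def test_parameter_recovery_long_series(self):
        """(theta1, theta2) recovered within 3 standard errors at n=5000 for
        the reference stable parameter set."""
        rng = np.random.default_rng(4)
        y = simulate_y_batch(0.2214, 0.3, 0.0275, 5000, rng, reps=1)[0]
        f = fit_nlari(y)
        assert abs(f.theta1_hat - 0.2214) < 3 * f.s1
        assert abs(f.theta2_hat - 0.3) < 3 * f.s2

    def test_white_noise_limit(self):
        """Pure white noise drives theta1 -> 0 and theta2 -> 1; this is the
        mechanism behind the aggregation limit."""
        rng = np.random.default_rng(5)
        t1, t2, _, _ = fit_batch(rng.normal(0.0, 0.05, (1, 100000)))
        assert abs(t1[0]) < 0.02
        assert abs(t2[0] - 1.0) < 0.03


class TestEstimatePipeline:
    def test_round_trip_recovery_at_900(self, stable_params):
        """Mean estimates over replicates recover the generating parameters
        at the study's window length."""
        rng = np.random.default_rng(6)
        y = simulate_y_batch(
            stable_params.theta1, stable_params.theta2, stable_params.sigma, 900, rng, reps=60
        )
        x = y + 4.1 + (stable_params.omega / stable_params.alpha) * np.arange(1, 901)
        ests = [estimate(np.exp(row), kind="hr_bpm") for row in x]
        alpha_bar = np.mean([e.alpha_hat for e in ests])
        beta_bar = np.mean([e.beta_hat for e in ests])
        sigma_bar = np.mean([e.sigma_hat for e in ests])
        omega_bar = np.mean([e.omega_hat for e in ests])
        assert alpha_bar == pytest.approx(stable_params.alpha, abs=0.05)
        assert beta_bar == pytest.approx(stable_params.beta, abs=0.05)
        assert sigma_bar == pytest.approx(stable_params.sigma, rel=0.05)
        assert omega_bar == pytest.approx(stable_params.omega, abs=2e-4)

    def test_eta2_tracks_sample_sd(self):
        """Across a beta grid, estimated eta2 and the sample sd of the
        series are positively rank-correlated."""
        from scipy.stats import spearmanr

        rng = np.random.default_rng(7)
        eta2s, sds = [], []
        for beta in np.linspace(0.1, 1.2, 12):
            y = simulate_y_batch(0.2214, beta, 0.0275, 900, rng, reps=5)
            for row in y:
                f = fit_nlari(detrend(row).y)
                eta2s.append(f.sigma_hat / f.theta2_hat)
                sds.append(row.std())
        rho = spearmanr(eta2s, sds).statistic
        assert rho > 0.7

    def test_unit_root_data_gives_near_zero_beta(self, unit_root_params):
        rng = np.random.default_rng(9)
        y = simulate_y_batch(0.2214, 0.0, 0.0275, 900, rng, reps=30)
        ests = [fit_nlari(detrend(row).y) for row in y]
        assert abs(np.mean([e.theta2_hat for e in ests])) < 0.05
        assert abs(np.mean([e.gamma_hat for e in ests])) < 0.05

    def test_mapping_identities_exact(self, stable_hr):
        e = estimate(stable_hr, kind="hr_bpm")
        f, tr = e.fit, e.trend
        assert e.alpha_hat == 1.0 - f.theta1_hat
        assert e.beta_hat == f.theta2_hat
        assert e.eta1_hat == tr.b_hat
        assert e.omega_hat == tr.b_hat * (1.0 - f.theta1_hat)
        assert e.eta2_hat == f.sigma_hat / f.theta2_hat
        assert e.gamma_hat == f.theta2_hat / (2.0 * (1.0 + f.theta1_hat))


class TestSklearnInterface:
    def test_get_set_params_and_clone(self):
        from sklearn.base import clone

        est = NLARIEstimator(kind="hr_bpm", kappa2=3)
        assert est.get_params() == {"kind": "hr_bpm", "kappa2": 3}
        est2 = clone(est).set_params(kappa2=1)
        assert est2.kappa2 == 1

    def test_fitted_attributes(self, stable_hr):
        est = NLARIEstimator(kind="hr_bpm").fit(stable_hr)
        for attr in ("theta1_", "theta2_", "alpha_", "beta_", "gamma_", "sigma_", "rows_used_"):
            assert hasattr(est, attr)
        assert est.rows_used_ == 898

    def test_column_vector_accepted(self, stable_hr):
        est = NLARIEstimator(kind="hr_bpm").fit(stable_hr.reshape(-1, 1))
        assert est.rows_used_ == 898

    def test_simulate_from_fit(self, stable_hr):
        est = NLARIEstimator(kind="hr_bpm").fit(stable_hr)
        sim = est.simulate(200, seed=1)
        assert len(sim) == 200
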