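import numpy as np
import pytest

from nlari import (
    ModelParams,
    NLARIEstimator,
    NoiseDrivenResponder,
    StimulusDrivenResponder,
    acf_curve,
    compare_acf,
    fit_noise_driven,
    fit_stimulus_driven,
    predict_out_of_sample,
    simulate_nlari,
)
from nlari.estimation import FitResult


def _fit(theta1=0.1, theta2=0.3, s1=0.02, s2=0.02, sigma=0.03, rows=400, kappa2=1):
    return FitResult(
        theta1_hat=theta1, theta2_hat=theta2, s1=s1, s2=s2, sigma_hat=sigma,
        sigma_gamma_hat=0.01, rows_used=rows, kappa2=kappa2, rss=sigma**2 * (rows - 2),
    )


class TestNoiseDriven:
    def test_zero_noise_zero_target_perfect_score(self):
        # sigma_hat -> 0 with Y == 0: every candidate reproduces zero exactly
        (th1, th2), trace, score = fit_noise_driven(np.zeros(100), _fit(sigma=0.0), seed=0)
        assert score == 0.0
        assert np.all(trace == 0.0)

    def test_score_non_increasing_under_grid_refinement(self, stable_hr):
        est = NLARIEstimator(kind="hr_bpm").fit(stable_hr)
        _, _, s_coarse = fit_noise_driven(est.y_, est.fit_result_, seed=0, grid_size=3,
                                          realizations=8)
        _, _, s_fine = fit_noise_driven(est.y_, est.fit_result_, seed=0, grid_size=21,
                                        realizations=8)
        assert s_fine <= s_coarse + 1e-12

    def test_chosen_params_inside_ci_box(self, stable_hr):
        r = NoiseDrivenResponder(kind="hr_bpm", grid_size=7, realizations=5).fit(stable_hr)
        f = r.estimator_.fit_result_
        from scipy import stats

        q = stats.t.ppf(0.975, f.rows_used - 2)
        assert f.theta1_hat - q * f.s1 <= r.theta1_ <= f.theta1_hat + q * f.s1
        assert f.theta2_hat - q * f.s2 <= r.theta2_ <= f.theta2_hat + q * f.s2

    def test_bit_identical_reproducibility(self, stable_hr):
        a = NoiseDrivenResponder(kind="hr_bpm", grid_size=5, realizations=5,
                                 random_state=3).fit(stable_hr)
        b = NoiseDrivenResponder(kind="hr_bpm", grid_size=5, realizations=5,
                                 random_state=3).fit(stable_hr)
        assert np.array_equal(a.fitted_trace_, b.fitted_trace_)
        assert a.score_ == b.score_

    def test_smaller_eta2_gives_smaller_amplitude(self):
        """A candidate with smaller eta2 (here: same beta, smaller sigma)
        produces a smaller fitted-trace amplitude."""
        y = np.zeros(300)
        f = _fit(sigma=0.05)
        _, trace_big, _ = fit_noise_driven(y, f, seed=1, grid_size=3, realizations=3)
        f2 = _fit(sigma=0.01)
        _, trace_small, _ = fit_noise_driven(y, f2, seed=1, grid_size=3, realizations=3)
        assert trace_small.std() < trace_big.std()


class TestOutOfSample:
    def test_prediction_runs_and_split_is_half(self, stable_hr):
        res = predict_out_of_sample(stable_hr, kind="hr_bpm", grid_size=5, realizations=5)
        assert res.actual.size == stable_hr.size - stable_hr.size // 2
        assert np.isfinite(res.score)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            predict_out_of_sample(np.full(10, 60.0), kind="hr_bpm")

    def test_long_even_delay_prediction_preserves_acf_shape(self):
        """kappa2=10 series: the predicted trace's ACF oscillates slowly,
        like the actual one."""
        p = ModelParams(omega=0.0, sigma=0.0275, alpha=0.7786, beta=0.3, kappa2=10)
        sim = simulate_nlari(p, 1800, x0=4.1, seed=5)
        res = predict_out_of_sample(
            np.exp(sim.x), kind="hr_bpm", kappa2=10, grid_size=5, realizations=5, seed=0
        )
        actual = acf_curve(res.actual, 80)
        predicted = acf_curve(res.predicted, 80)
        report = compare_acf(actual, predicted)
        assert actual.long_memory
        assert predicted.long_memory
        assert report["correlation"] > 0.3


class TestStimulusDriven:
    def test_clip_inactive_for_large_threshold(self):
        y = np.sin(np.arange(60) / 3.0) * 0.1
        res = fit_stimulus_driven(y, _fit(), c_grid=[10.0])
        assert np.array_equal(res.innovations, y)

    def test_clip_branches(self):
        y = np.array([0.0, 0.0, 0.2, -0.2, 0.05] * 20)
        res = fit_stimulus_driven(y, _fit(), c_grid=[0.1])
        assert res.innovations.max() == pytest.approx(0.1)
        assert res.innovations.min() == pytest.approx(-0.1)
        assert np.all(np.abs(res.innovations) <= 0.1)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            fit_stimulus_driven(np.ones(50) * 0.1, _fit(), c_grid=[])

    def test_beats_noise_driven_near_unit_root(self, near_boundary_params):
        """At the edge of stability the noise-driven responder cannot track
        the actual HRV, while the clipped-stimulus drive can."""
        sim = simulate_nlari(near_boundary_params, 900, x0=4.1, seed=3)
        hr = np.exp(sim.x)
        est = NLARIEstimator(kind="hr_bpm").fit(hr)
        _, _, noise_score = fit_noise_driven(
            est.y_, est.fit_result_, seed=0, grid_size=11, realizations=10
        )
        stim = StimulusDrivenResponder(kind="hr_bpm").fit(hr)
        assert stim.score_ < noise_score

    def test_sklearn_attributes(self, stable_hr):
        r = StimulusDrivenResponder(kind="hr_bpm").fit(stable_hr)
        assert r.c_ > 0
        assert r.fitted_trace_.shape == r.actual_.shape
        assert r.get_params()["kind"] == "hr_bpm"


class TestACF:
    def test_lag_zero_is_one(self, rng):
        curve = acf_curve(rng.normal(size=500), 50)
        assert curve.values[0] == 1.0

    def test_white_noise_within_band(self, rng):
        curve = acf_curve(rng.normal(size=2000), 100)
        assert not curve.long_memory
        assert np.mean(np.abs(curve.values[1:]) < curve.band) > 0.9

    def test_max_lag_bound(self, rng):
        with pytest.raises(ValueError):
            acf_curve(rng.normal(size=100), 60)

    def test_long_even_delay_flags_long_memory(self):
        p = ModelParams(omega=0.0, sigma=0.0275, alpha=0.7786, beta=0.3, kappa2=10)
        sim = simulate_nlari(p, 1800, x0=4.1, seed=5)
        curve = acf_curve(sim.y, 100)
        assert curve.long_memory
        # oscillation: the ACF keeps changing sign well into the tail
        signs = np.sign(curve.values[1:])
        assert np.sum(signs[1:] != signs[:-1]) >= 3
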