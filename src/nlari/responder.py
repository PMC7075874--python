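"""Noise- and stimulus-driven homeostatic HRV responders.

The *noise-driven* responder replays the fitted HRV recursion with Gaussian
innovations N(0, sigma_hat^2), tuning (theta1, theta2) inside the confidence
box theta_i_hat +/- t * s_i to bring the output as close as possible (minimum
RMSE, median over seeded realizations) to the actual HRV.  The
*stimulus-driven* responder instead feeds the observed deviations, clipped at
a threshold c, back into the recursion as innovations — the form that tracks
series at the edge of stability where Gaussian noise fails.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.tsa.stattools import acf as _sm_acf

from .estimation import FitResult, NLARIEstimator, detrend, fit_nlari, to_log_hr

__all__ = [
    "PredictionResult",
    "StimulusFit",
    "ACFCurve",
    "NoiseDrivenResponder",
    "StimulusDrivenResponder",
    "predict_out_of_sample",
    "fit_noise_driven",
    "fit_stimulus_driven",
    "acf_curve",
    "compare_acf",
]

_DIVERGED = 1e6


@dataclass(frozen=True)
class PredictionResult:
    in_sample: FitResult
    chosen_theta1: float
    chosen_theta2: float
    predicted: np.ndarray
    actual: np.ndarray
    score: float
    seed: int | None
    grid_size: int
    realizations: int


@dataclass(frozen=True)
class StimulusFit:
    c: float
    fitted: np.ndarray
    score: float
    innovations: np.ndarray


@dataclass(frozen=True)
class ACFCurve:
    lags: np.ndarray
    values: np.ndarray
    long_memory: bool
    band: float


def _ci_grid(fit: FitResult, grid_size: int, level: float = 0.95):
    q = stats.t.ppf(0.5 + level / 2.0, fit.rows_used - 2)
    th1 = np.linspace(fit.theta1_hat - q * fit.s1, fit.theta1_hat + q * fit.s1, grid_size)
    th2 = np.linspace(fit.theta2_hat - q * fit.s2, fit.theta2_hat + q * fit.s2, grid_size)
    g1, g2 = np.meshgrid(th1, th2, indexing="ij")
    return g1.ravel(), g2.ravel()


def _simulate_candidates(th1, th2, sigma, horizon, history, eps, kappa2):
    """Simulate every (theta1, theta2) candidate against a shared noise matrix
    ``eps`` of shape (realizations, horizon); common random numbers keep the
    grid-search objective comparable across candidates and grid refinements.

    Returns traces of shape (ncand, realizations, horizon)."""
    ncand = th1.size
    reals = eps.shape[0]
    B = ncand * reals
    T1 = np.repeat(th1, reals)
    T2 = np.repeat(th2, reals)
    hist = max(2, kappa2)
    y = np.empty((B, hist + horizon))
    y[:, :hist] = np.asarray(history, dtype=float)[None, :]
    e = np.tile(eps * sigma, (ncand, 1))
    with np.errstate(over="ignore", invalid="ignore"):
        for t in range(hist, hist + horizon):
            yk = y[:, t - kappa2]
            y[:, t] = (
                (1.0 + T1) * y[:, t - 1]
                - T1 * y[:, t - 2]
                - T2 * yk * np.exp(-yk * yk)
                + e[:, t - hist]
            )
    return y[:, hist:].reshape(ncand, reals, horizon)


def _grid_search(fit, actual, history, sigma, seed, grid_size, realizations, kappa2):
    rng = np.random.default_rng(seed)
    horizon = actual.size
    eps = rng.standard_normal((realizations, horizon))
    th1, th2 = _ci_grid(fit, grid_size)
    traces = _simulate_candidates(th1, th2, sigma, horizon, history, eps, kappa2)
    with np.errstate(invalid="ignore", over="ignore"):
        err = traces - actual[None, None, :]
        rmse = np.sqrt(np.mean(err * err, axis=2))
    bad = ~np.isfinite(rmse) | (np.abs(traces).max(axis=2) > _DIVERGED)
    rmse = np.where(bad, np.inf, rmse)
    scores = np.median(rmse, axis=1)
    best = int(np.argmin(scores))
    # representative trace: the realization closest to the median score
    k = int(np.argmin(np.abs(rmse[best] - scores[best])))
    return th1[best], th2[best], traces[best, k], float(scores[best])


class NoiseDrivenResponder(BaseEstimator):
    """Noise-driven homeostatic HRV responder fit on the full sample.

    Grid-searches (theta1, theta2) over the confidence box of the in-sample
    fit; each candidate is scored by the median RMSE of ``realizations``
    seeded noise runs against the actual HRV.

    Attributes after fit: ``theta1_``, ``theta2_`` (chosen parameters),
    ``fitted_trace_``, ``score_``, ``estimator_`` (the underlying
    :class:`NLARIEstimator`).
    """

    def __init__(
        self,
        kind: str = "rr_seconds",
        kappa2: int = 1,
        grid_size: int = 21,
        realizations: int = 20,
        random_state: int | None = 0,
    ):
        self.kind = kind
        self.kappa2 = kappa2
        self.grid_size = grid_size
        self.realizations = realizations
        self.random_state = random_state

    def fit(self, X, y=None):
        est = NLARIEstimator(kind=self.kind, kappa2=self.kappa2).fit(X)
        self.estimator_ = est
        actual = est.y_
        hist = max(2, self.kappa2)
        history = actual[:hist]
        th1, th2, trace, score = _grid_search(
            est.fit_result_,
            actual[hist:],
            history,
            est.sigma_,
            self.random_state,
            self.grid_size,
            self.realizations,
            self.kappa2,
        )
        self.theta1_ = float(th1)
        self.theta2_ = float(th2)
        self.fitted_trace_ = np.concatenate([history, trace])
        self.score_ = score
        self.actual_ = actual
        return self


class StimulusDrivenResponder(BaseEstimator):
    """Stimulus-driven homeostatic HRV responder.

    Parameters are fixed at the OLS estimates; the innovation at each step is
    the observed HRV value clipped to [-c, c], and the threshold c is chosen
    from ``c_grid`` by minimum RMSE.  The recursion feeds back its own fitted
    values, with the first observations as starting history.
    """

    def __init__(self, kind: str = "rr_seconds", kappa2: int = 1, c_grid=None):
        self.kind = kind
        self.kappa2 = kappa2
        self.c_grid = c_grid

    def fit(self, X, y=None):
        est = NLARIEstimator(kind=self.kind, kappa2=self.kappa2).fit(X)
        self.estimator_ = est
        res = fit_stimulus_driven(est.y_, est.fit_result_, self.c_grid)
        self.c_ = res.c
        self.fitted_trace_ = res.fitted
        self.score_ = res.score
        self.result_ = res
        self.actual_ = est.y_
        return self


def predict_out_of_sample(
    series,
    kind: str = "rr_seconds",
    kappa2: int = 1,
    seed: int | None = 0,
    grid_size: int = 21,
    realizations: int = 20,
) -> PredictionResult:
    """Out-of-sample prediction: fit on the first half, tune (theta1, theta2)
    inside the confidence box, and score seeded responder runs against the
    out-sample HRV.

    The out-sample HRV is formed with the in-sample trend line extrapolated
    (using out-sample information to detrend would leak), and the prediction
    starts from the last in-sample HRV values.
    """
    x = to_log_hr(series, kind).x
    n = x.size
    if n < 20:
        raise ValueError(f"need at least 20 points to split, got {n}")
    h = n // 2
    trend = detrend(x[:h])
    fit = fit_nlari(trend.y, kappa2)
    t_out = np.arange(h + 1, n + 1, dtype=float)
    y_out = x[h:] - (trend.a_hat + trend.b_hat * t_out)
    hist = max(2, kappa2)
    history = trend.y[-hist:]
    th1, th2, trace, score = _grid_search(
        fit, y_out, history, fit.sigma_hat, seed, grid_size, realizations, kappa2
    )
    return PredictionResult(
        in_sample=fit,
        chosen_theta1=float(th1),
        chosen_theta2=float(th2),
        predicted=trace,
        actual=y_out,
        score=score,
        seed=seed,
        grid_size=grid_size,
        realizations=realizations,
    )


def fit_noise_driven(
    y,
    fit: FitResult,
    seed: int | None = 0,
    grid_size: int = 21,
    realizations: int = 20,
):
    """Full-sample noise-driven fit on an already-detrended HRV series.
    Returns (chosen (theta1, theta2), fitted trace, score)."""
    y = np.asarray(y, dtype=float).ravel()
    hist = max(2, fit.kappa2)
    th1, th2, trace, score = _grid_search(
        fit, y[hist:], y[:hist], fit.sigma_hat, seed, grid_size, realizations, fit.kappa2
    )
    return (float(th1), float(th2)), np.concatenate([y[:hist], trace]), score


def fit_stimulus_driven(y, fit: FitResult, c_grid=None) -> StimulusFit:
    """Stimulus-driven fit: innovations are the observed HRV clipped at +/- c.

    For each threshold c in ``c_grid`` the responder recursion runs with
    (theta1, theta2) fixed at the OLS estimates and innovation
    ``eps_t = clip(Y_t, -c, c)``; returns the fit at the RMSE-minimising c.
    """
    y = np.asarray(y, dtype=float).ravel()
    if c_grid is None:
        top = float(np.max(np.abs(y)))
        if top <= 0:
            raise ValueError("cannot build a threshold grid for an all-zero series")
        # the useful regime is often c << max|Y| (the clipped series then acts
        # like a delta-modulation drive), so the grid is logarithmic
        c_grid = np.geomspace(top / 1000.0, top, 40)
    c_grid = np.asarray(c_grid, dtype=float).ravel()
    if c_grid.size == 0:
        raise ValueError("empty threshold grid")
    if np.any(c_grid <= 0):
        raise ValueError("thresholds must be positive")
    th1, th2, k2 = fit.theta1_hat, fit.theta2_hat, fit.kappa2
    hist = max(2, k2)
    n = y.size
    best = None
    for c in c_grid:
        eps = np.clip(y, -c, c)
        yh = np.empty(n)
        yh[:hist] = y[:hist]
        with np.errstate(over="ignore", invalid="ignore"):
            for t in range(hist, n):
                yk = yh[t - k2]
                yh[t] = (
                    (1.0 + th1) * yh[t - 1]
                    - th1 * yh[t - 2]
                    - th2 * yk * np.exp(-yk * yk)
                    + eps[t]
                )
        if not np.all(np.isfinite(yh)) or np.max(np.abs(yh)) > _DIVERGED:
            continue
        score = float(np.sqrt(np.mean((yh - y) ** 2)))
        if best is None or score < best.score:
            best = StimulusFit(c=float(c), fitted=yh, score=score, innovations=eps)
    if best is None:
        raise ValueError("responder diverged for every threshold in the grid")
    return best


def acf_curve(series, max_lag: int) -> ACFCurve:
    """Sample autocorrelation with a long-memory flag.

    The flag is set when the tail of the ACF decays more slowly than its
    best-fit exponential envelope or keeps oscillating outside the 2/sqrt(n)
    band — the signature of a long even restoration delay.
    """
    y = np.asarray(series, dtype=float).ravel()
    n = y.size
    if not max_lag < n / 2:
        raise ValueError(f"max_lag must be < n/2 = {n/2}")
    vals = _sm_acf(y, nlags=max_lag, fft=True)
    lags = np.arange(max_lag + 1)
    band = 2.0 / np.sqrt(n)
    tail = vals[max_lag // 2 :]
    frac_sig_tail = float(np.mean(np.abs(tail) > band))
    # exponential envelope fitted to the early significant lags
    early = vals[1 : max(2, max_lag // 2)]
    mask = np.abs(early) > 1e-3
    underfits = False
    if mask.sum() >= 3:
        ll = np.arange(1, early.size + 1)[mask]
        la = np.log(np.abs(early[mask]))
        slope, intercept = np.polyfit(ll, la, 1)
        if slope < 0:
            pred_tail = np.exp(intercept + slope * lags[max_lag // 2 :])
            underfits = float(np.mean(np.abs(tail))) > 2.0 * float(np.mean(pred_tail)) and (
                frac_sig_tail > 0.1
            )
    long_memory = bool(underfits or frac_sig_tail > 0.25)
    return ACFCurve(lags=lags, values=vals, long_memory=long_memory, band=band)


def compare_acf(actual: ACFCurve, predicted: ACFCurve) -> dict:
    """Summarise how closely a predicted ACF tracks the actual one."""
    m = min(actual.values.size, predicted.values.size)
    a, p = actual.values[:m], predicted.values[:m]
    return {
        "rmse": float(np.sqrt(np.mean((a - p) ** 2))),
        "correlation": float(np.corrcoef(a, p)[0, 1]) if m > 2 else float("nan"),
        "actual_long_memory": actual.long_memory,
        "predicted_long_memory": predicted.long_memory,
    }
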