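"""OLS estimation of the NLARI heart-rate parameters.

Pipeline: beats -> log heart rate ``X_t = ln(HR)`` -> OLS detrending
``Y_t = X_t - a_hat - b_hat t`` -> OLS on the first-difference form

    dY_t = theta1 dY_{t-1} + theta2 (-Y_{t-k2} exp(-Y_{t-k2}^2)) + eps_t

followed by the parameter mapping ``alpha = 1 - theta1``, ``beta = theta2``,
``gamma = theta2 / (2 (1 + theta1))``, ``omega = b_hat (1 - theta1)``,
``eta1 = b_hat``, ``eta2 = sigma / theta2``.

The estimator is exposed both as the scikit-learn style
:class:`NLARIEstimator` and as thin module-level functions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

__all__ = [
    "HRSeries",
    "TrendFit",
    "FitResult",
    "HRParamEstimates",
    "to_log_hr",
    "detrend",
    "fit_nlari",
    "estimate",
    "NLARIEstimator",
]

VALID_KINDS = ("rr_seconds", "hr_bpm", "log_hr")


@dataclass(frozen=True)
class HRSeries:
    """A beat series and its log-heart-rate transform ``x``."""

    raw: np.ndarray
    kind: str
    x: np.ndarray

    @property
    def n(self) -> int:
        return self.x.size


@dataclass(frozen=True)
class TrendFit:
    """OLS line ``X_t = a + b t`` and the detrended residual series ``y``."""

    a_hat: float
    b_hat: float
    y: np.ndarray


@dataclass(frozen=True)
class FitResult:
    """OLS estimates of (theta1, theta2) with classical standard errors."""

    theta1_hat: float
    theta2_hat: float
    s1: float
    s2: float
    sigma_hat: float
    sigma_gamma_hat: float
    rows_used: int
    kappa2: int
    rss: float

    @property
    def gamma_hat(self) -> float:
        return self.theta2_hat / (2.0 * (1.0 + self.theta1_hat))


@dataclass(frozen=True)
class HRParamEstimates:
    """Mapped heart-rate parameter estimates with their trend and fit."""

    omega_hat: float
    alpha_hat: float
    beta_hat: float
    gamma_hat: float
    eta1_hat: float
    eta2_hat: float
    sigma_hat: float
    trend: TrendFit
    fit: FitResult

    def as_dict(self) -> dict[str, float]:
        return {
            "omega": self.omega_hat,
            "alpha": self.alpha_hat,
            "beta": self.beta_hat,
            "gamma": self.gamma_hat,
            "eta1": self.eta1_hat,
            "eta2": self.eta2_hat,
            "sigma": self.sigma_hat,
        }


def to_log_hr(series, kind: str = "rr_seconds") -> HRSeries:
    """Transform a beat series to log heart rate.

    ``kind='rr_seconds'`` converts RR intervals to HR = 60/RR first;
    ``kind='hr_bpm'`` takes the values as beats per minute; ``kind='log_hr'``
    passes already-transformed values through unchanged.
    """
    raw = np.asarray(series, dtype=float).ravel()
    if kind not in VALID_KINDS:
        raise ValueError(f"kind must be one of {VALID_KINDS}, got {kind!r}")
    if kind == "log_hr":
        return HRSeries(raw=raw, kind=kind, x=raw.copy())
    bad = np.flatnonzero(~(raw > 0))
    if bad.size:
        raise ValueError(
            f"nonpositive beat value {raw[bad[0]]!r} at index {bad[0]} (kind={kind})"
        )
    hr = 60.0 / raw if kind == "rr_seconds" else raw
    return HRSeries(raw=raw, kind=kind, x=np.log(hr))


def detrend(h: HRSeries | np.ndarray) -> TrendFit:
    """Remove the OLS regression line ``X_t = a + b t`` (t = 1..n)."""
    x = h.x if isinstance(h, HRSeries) else np.asarray(h, dtype=float).ravel()
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 points to detrend, got {n}")
    t = np.arange(1, n + 1, dtype=float)
    design = np.column_stack([np.ones(n), t])
    coef, *_ = np.linalg.lstsq(design, x, rcond=None)
    y = x - design @ coef
    return TrendFit(a_hat=float(coef[0]), b_hat=float(coef[1]), y=y)


def _design(y: np.ndarray, kappa2: int):
    """Regression rows for the first-difference form.

    The recursion needs dY_{t-1} and Y_{t-kappa2}; rows start at
    t = max(3, kappa2 + 2) of the detrended series and the presample prefix
    is lost.  Returns (response dY_t, regressor matrix Z)."""
    n = y.size
    start = max(3, kappa2 + 2)  # 1-based t of the first usable row
    if n < start + 2:
        raise ValueError(f"series too short for kappa2={kappa2}: n={n}")
    dy = np.diff(y)
    resp = dy[start - 2 :]
    reg1 = dy[start - 3 : -1]
    ylag = y[start - 1 - kappa2 : n - kappa2]
    reg2 = -ylag * np.exp(-(ylag * ylag))
    return resp, np.column_stack([reg1, reg2])


def fit_nlari(y: np.ndarray, kappa2: int = 1) -> FitResult:
    """OLS fit of the first-difference HRV regression.

    Solves the normal equations ``theta = (Z'Z)^{-1} Z'r`` for regressors
    ``(dY_{t-1}, -Y_{t-k2} exp(-Y_{t-k2}^2))`` and response ``dY_t``;
    ``sigma_hat = sqrt(RSS / (rows - 2))`` and the classical standard errors

        s_i = sigma_hat * sqrt(e_i' (Z'Z)^{-1} e_i)
        sigma_gamma_hat = (sigma_hat / (2 (1 + theta1)))
                          * sqrt(v' (Z'Z)^{-1} v),  v = (-2 gamma_hat, 1)

    Raises
    ------
    ValueError
        On a rank-deficient design (e.g. ``y`` identically zero) or too few rows.
    """
    y = np.asarray(y, dtype=float).ravel()
    resp, Z = _design(y, kappa2)
    rows = resp.size
    if rows <= 2:
        raise ValueError(f"only {rows} regression rows; need more than 2")
    gram = Z.T @ Z
    if np.linalg.matrix_rank(gram) < 2 or np.linalg.cond(gram) > 1e14:
        raise ValueError("degenerate design matrix (is the series constant?)")
    gram_inv = np.linalg.inv(gram)
    theta = gram_inv @ (Z.T @ resp)
    resid = resp - Z @ theta
    rss = float(resid @ resid)
    sigma_hat = float(np.sqrt(rss / (rows - 2)))
    s1 = sigma_hat * float(np.sqrt(gram_inv[0, 0]))
    s2 = sigma_hat * float(np.sqrt(gram_inv[1, 1]))
    th1, th2 = float(theta[0]), float(theta[1])
    gamma_hat = th2 / (2.0 * (1.0 + th1))
    v = np.array([-2.0 * gamma_hat, 1.0])
    sigma_gamma_hat = (
        0.5 * sigma_hat / (1.0 + th1) * float(np.sqrt(v @ gram_inv @ v))
    )
    return FitResult(
        theta1_hat=th1,
        theta2_hat=th2,
        s1=s1,
        s2=s2,
        sigma_hat=sigma_hat,
        sigma_gamma_hat=sigma_gamma_hat,
        rows_used=rows,
        kappa2=kappa2,
        rss=rss,
    )


def estimate(series, kind: str = "rr_seconds", kappa2: int = 1) -> HRParamEstimates:
    """Full pipeline: log transform, detrend, OLS fit, parameter mapping."""
    est = NLARIEstimator(kind=kind, kappa2=kappa2).fit(series)
    return est.results_


class NLARIEstimator(BaseEstimator):
    """Scikit-learn style estimator for the NLARI heart-rate parameters.

    Parameters
    ----------
    kind : {'rr_seconds', 'hr_bpm', 'log_hr'}
        Interpretation of the input beat series.
    kappa2 : int
        Restoration lag used in the fitted recursion.

    Attributes (after :meth:`fit`)
    ------------------------------
    trend_intercept_, trend_slope_ : float
        OLS line of log HR on time.
    theta1_, theta2_, s1_, s2_, sigma_, sigma_gamma_ : float
        Regression estimates and classical standard errors.
    alpha_, beta_, gamma_, omega_, eta1_, eta2_ : float
        Mapped heart-rate parameters.
    y_ : ndarray
        Detrended log-HR (HRV) series.
    rows_used_ : int
        Effective regression length after presample loss.
    results_ : HRParamEstimates
        Bundled results object.
    """

    def __init__(self, kind: str = "rr_seconds", kappa2: int = 1):
        self.kind = kind
        self.kappa2 = kappa2

    def fit(self, X, y=None):
        series = np.asarray(X, dtype=float)
        if series.ndim == 2 and series.shape[1] == 1:
            series = series.ravel()
        if series.ndim != 1:
            raise ValueError("expected a one-dimensional beat series")
        h = to_log_hr(series, self.kind)
        trend = detrend(h)
        fit = fit_nlari(trend.y, self.kappa2)
        self.trend_intercept_ = trend.a_hat
        self.trend_slope_ = trend.b_hat
        self.y_ = trend.y
        self.x_ = h.x
        self.theta1_ = fit.theta1_hat
        self.theta2_ = fit.theta2_hat
        self.s1_ = fit.s1
        self.s2_ = fit.s2
        self.sigma_ = fit.sigma_hat
        self.sigma_gamma_ = fit.sigma_gamma_hat
        self.rows_used_ = fit.rows_used
        self.alpha_ = 1.0 - fit.theta1_hat
        self.beta_ = fit.theta2_hat
        self.gamma_ = fit.gamma_hat
        self.omega_ = trend.b_hat * (1.0 - fit.theta1_hat)
        self.eta1_ = trend.b_hat
        self.eta2_ = fit.sigma_hat / fit.theta2_hat if fit.theta2_hat != 0 else np.inf
        self.fit_result_ = fit
        self.trend_ = trend
        self.results_ = HRParamEstimates(
            omega_hat=self.omega_,
            alpha_hat=self.alpha_,
            beta_hat=self.beta_,
            gamma_hat=self.gamma_,
            eta1_hat=self.eta1_,
            eta2_hat=self.eta2_,
            sigma_hat=self.sigma_,
            trend=trend,
            fit=fit,
        )
        return self

    def simulate(self, n: int, seed: int | None = None, x0: float | None = None):
        """Simulate a new trajectory from the fitted parameters."""
        from .params import ModelParams
        from .simulate import simulate_nlari

        p = ModelParams(
            omega=self.omega_,
            sigma=self.sigma_,
            alpha=self.alpha_,
            beta=max(self.beta_, 0.0),
            kappa2=self.kappa2,
        )
        return simulate_nlari(p, n, x0=self.trend_intercept_ if x0 is None else x0, seed=seed)


# ---------------------------------------------------------------------------
# vectorised helpers shared by the Monte-Carlo modules


def detrend_batch(X: np.ndarray) -> np.ndarray:
    """Detrend each row of ``X`` by its own OLS line on t = 1..N."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[1]
    t = np.arange(1, n + 1, dtype=float)
    design = np.column_stack([np.ones(n), t])
    coef, *_ = np.linalg.lstsq(design, X.T, rcond=None)
    return X - (design @ coef).T, coef


def fit_batch(Y: np.ndarray, kappa2: int = 1):
    """Row-wise OLS fit of the first-difference regression.

    Returns arrays (theta1, theta2, sigma_hat) of shape (B,) plus rows_used."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    B, n = Y.shape
    start = max(3, kappa2 + 2)
    dY = np.diff(Y, axis=1)
    resp = dY[:, start - 2 :]
    reg1 = dY[:, start - 3 : -1]
    ylag = Y[:, start - 1 - kappa2 : n - kappa2]
    reg2 = -ylag * np.exp(-(ylag * ylag))
    Z = np.stack([reg1, reg2], axis=2)
    gram = np.einsum("bri,brj->bij", Z, Z)
    rhs = np.einsum("bri,br->bi", Z, resp)
    theta = np.linalg.solve(gram, rhs[..., None])[..., 0]
    resid = resp - np.einsum("bri,bi->br", Z, theta)
    rows = resp.shape[1]
    sigma = np.sqrt(np.einsum("br,br->b", resid, resid) / (rows - 2))
    return theta[:, 0], theta[:, 1], sigma, rows
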