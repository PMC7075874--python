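"""Sensitivity of the heart-rate parameters to input perturbations, and
time-scale (aggregation) analysis.

An extra white-noise input with mean ``omega_i`` and sd ``sigma_i`` shifts the
disturbance mean to ``omega + omega_i`` and the innovation sd to
``sqrt(sigma^2 + sigma_i^2)`` (the trend slope becomes
``(omega + omega_i)/alpha``).  Sensitivity of a parameter ``phi`` is the
absolute ratio of its relative change to the relative input change:

    S(omega_i, phi) = | (phi_i - phi) omega / (omega_i phi) |
    S(sigma_i, phi) = | (phi_i - phi) sigma / ((sqrt(sigma^2+sigma_i^2)-sigma) phi) |

where ``phi_i`` is the disturbed estimate averaged over replicates.  Values
classify as perfectly insensitive (0), insensitive (<1), unit sensitive (=1)
and sensitive (>1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimation import detrend_batch, fit_batch
from .params import ModelParams, derived_params
from .simulate import SimSeries, simulate_nlari, simulate_y_batch

__all__ = [
    "SensitivityTable",
    "ScaleSweep",
    "simulate_disturbed",
    "sensitivity_table",
    "aggregate",
    "scale_sweep",
]

MEAN_SHIFT_PARAMS = ("alpha", "beta", "gamma", "sigma", "eta2")
SD_SHIFT_PARAMS = ("omega", "alpha", "beta", "gamma", "eta1")


@dataclass(frozen=True)
class SensitivityTable:
    kind: str
    grid: np.ndarray
    table: pd.DataFrame = field(repr=False)
    reps: int
    seed: int | None
    base: ModelParams

    def max_sensitivity(self) -> float:
        return float(self.table["S"].max())


@dataclass(frozen=True)
class ScaleSweep:
    scales: list[int]
    table: pd.DataFrame = field(repr=False)
    reps: int
    seed: int | None
    base: ModelParams


def classify_sensitivity(s: float) -> str:
    if s == 0.0:
        return "perfectly_insensitive"
    if s < 1.0:
        return "insensitive"
    if s == 1.0:
        return "unit_sensitive"
    return "sensitive"


def simulate_disturbed(
    p: ModelParams,
    omega_i: float = 0.0,
    sigma_i: float = 0.0,
    n: int = 900,
    x0: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    burn_in: int = 500,
) -> SimSeries:
    """Simulate the process under an extra disturbance input.

    With ``omega_i = sigma_i = 0`` this is distributionally identical to the
    undisturbed simulation (identical under a shared seed)."""
    if sigma_i < 0:
        raise ValueError("sigma_i must be >= 0")
    disturbed = ModelParams(
        omega=p.omega + omega_i,
        sigma=float(np.sqrt(p.sigma**2 + sigma_i**2)),
        alpha=p.alpha,
        beta=p.beta,
        kappa2=p.kappa2,
    )
    return simulate_nlari(disturbed, n, x0=x0, seed=seed, rng=rng, burn_in=burn_in)


def _mean_estimates(
    p: ModelParams, omega_i: float, sigma_i: float, n: int, reps: int,
    rng: np.random.Generator,
) -> dict[str, float]:
    """Average parameter estimates over replicates of the disturbed process."""
    slope = (p.omega + omega_i) / p.alpha
    sd = float(np.sqrt(p.sigma**2 + sigma_i**2))
    y = simulate_y_batch(p.theta1, p.theta2, sd, n, rng, reps=reps, kappa2=p.kappa2)
    x = y + slope * np.arange(1, n + 1)
    xd, coef = detrend_batch(x)
    t1, t2, sig, _ = fit_batch(xd, kappa2=p.kappa2)
    b = coef[1]
    return {
        "omega": float(np.mean(b * (1.0 - t1))),
        "alpha": float(np.mean(1.0 - t1)),
        "beta": float(np.mean(t2)),
        "gamma": float(np.mean(t2 / (2.0 * (1.0 + t1)))),
        "sigma": float(np.mean(sig)),
        "eta1": float(np.mean(b)),
        "eta2": float(np.mean(sig / t2)),
    }


def sensitivity_table(
    p: ModelParams,
    kind: str = "mean_shift",
    grid=None,
    n: int = 900,
    reps: int = 300,
    seed: int | None = 0,
) -> SensitivityTable:
    """Sensitivity S of the heart-rate parameters over a perturbation grid.

    ``kind='mean_shift'`` perturbs the disturbance mean (grid of omega_i;
    default 0.00004 i for i = 1..20) and reports phi in (alpha, beta, gamma,
    sigma, eta2); ``kind='sd_shift'`` perturbs the disturbance sd (default
    0.007 i) and reports phi in (omega, alpha, beta, gamma, eta1).
    A base parameter of zero makes that S undefined (NaN, flagged).
    """
    if kind not in ("mean_shift", "sd_shift"):
        raise ValueError(f"kind must be 'mean_shift' or 'sd_shift', got {kind!r}")
    if grid is None:
        grid = (
            0.00004 * np.arange(1, 21) if kind == "mean_shift" else 0.007 * np.arange(1, 21)
        )
    grid = np.asarray(grid, dtype=float)
    if np.any(grid == 0):
        raise ValueError("grid entries must be nonzero")
    if kind == "mean_shift" and p.omega == 0:
        raise ValueError("mean_shift sensitivity needs a nonzero base omega")
    d = derived_params(p)
    base_vals = {
        "omega": p.omega,
        "alpha": p.alpha,
        "beta": p.beta,
        "gamma": d.gamma,
        "sigma": p.sigma,
        "eta1": d.eta1,
        "eta2": d.eta2 if d.eta2 is not None else np.nan,
    }
    names = MEAN_SHIFT_PARAMS if kind == "mean_shift" else SD_SHIFT_PARAMS
    rng = np.random.default_rng(seed)
    rows = []
    for g in grid:
        om_i, sg_i = (g, 0.0) if kind == "mean_shift" else (0.0, g)
        est = _mean_estimates(p, om_i, sg_i, n, reps, rng)
        if kind == "mean_shift":
            rel_input = om_i / p.omega
        else:
            rel_input = (np.sqrt(p.sigma**2 + sg_i**2) - p.sigma) / p.sigma
        for name in names:
            phi = base_vals[name]
            if phi == 0 or not np.isfinite(phi):
                s = np.nan
                label = "undefined"
            else:
                s = abs((est[name] - phi) / phi) / rel_input
                label = classify_sensitivity(s)
            rows.append(
                {
                    "input": g,
                    "parameter": name,
                    "estimate": est[name],
                    "base": phi,
                    "S": s,
                    "classification": label,
                }
            )
    return SensitivityTable(
        kind=kind, grid=grid, table=pd.DataFrame(rows), reps=reps, seed=seed, base=p
    )


def aggregate(y, m: int) -> np.ndarray:
    """Block means over consecutive non-overlapping windows of length ``m``;
    the trailing remainder is dropped (output length floor(T/m))."""
    y = np.asarray(y, dtype=float)
    if m < 1 or int(m) != m:
        raise ValueError(f"m must be a positive integer, got {m}")
    T = y.shape[-1]
    if m > T:
        raise ValueError(f"aggregation scale m={m} exceeds series length {T}")
    k = T // m
    if y.ndim == 1:
        return y[: k * m].reshape(k, m).mean(axis=1)
    return y[..., : k * m].reshape(*y.shape[:-1], k, m).mean(axis=-1)


def scale_sweep(
    p: ModelParams,
    m_list=(1, 2, 5, 10, 30, 60),
    n_base: int = 60000,
    reps: int = 100,
    seed: int | None = 0,
) -> ScaleSweep:
    """Average (alpha, beta, omega, sigma) estimates after block-mean
    aggregation at each scale m.

    Block means of a short-memory series approach white noise, for which the
    regression limit is theta1 -> 0, theta2 -> 1; hence alpha_hat and
    beta_hat both converge to 1 at minute scales.
    """
    m_list = [int(m) for m in m_list]
    if n_base // max(m_list) < 100:
        raise ValueError("n_base too short: need >= 100 aggregated points at max(m)")
    rng = np.random.default_rng(seed)
    slope = derived_params(p).eta1
    y = simulate_y_batch(p.theta1, p.theta2, p.sigma, n_base, rng, reps=reps, kappa2=p.kappa2)
    x = y + slope * np.arange(1, n_base + 1)
    rows = []
    for m in m_list:
        xa = aggregate(x, m)
        xd, coef = detrend_batch(xa)
        t1, t2, sig, _ = fit_batch(xd, kappa2=p.kappa2)
        b = coef[1]
        rows.append(
            {
                "m": m,
                "alpha": float(np.mean(1.0 - t1)),
                "beta": float(np.mean(t2)),
                "omega": float(np.mean(b * (1.0 - t1))),
                "sigma": float(np.mean(sig)),
            }
        )
    return ScaleSweep(
        scales=m_list, table=pd.DataFrame(rows), reps=reps, seed=seed, base=p
    )
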