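"""Stochastic simulation of the NLARI heart-rate process.

Simulation runs on the detrended component ``Y_t`` (the HRV equation) and the
trended level is reconstructed as ``X_t = X_0 + eta1 * t + Y_t``; for Gaussian
disturbances the two routes are equivalent and the detrended recursion is
numerically simpler.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ModelParams, derived_params

__all__ = ["SimSeries", "simulate_nlari", "simulate_y_batch"]

DEFAULT_BURN_IN = 500
DIVERGENCE_BOUND = 1e6


@dataclass(frozen=True)
class SimSeries:
    """A simulated trajectory: detrended HRV ``y``, trended level ``x``,
    and the innovations actually used (for exact replay)."""

    y: np.ndarray
    x: np.ndarray
    x0: float
    seed: int | None
    burn_in: int
    innovations: np.ndarray
    params: ModelParams

    def __len__(self) -> int:
        return self.y.size


def simulate_y_batch(
    theta1,
    theta2,
    sigma,
    n: int,
    rng: np.random.Generator,
    reps: int = 1,
    kappa2: int = 1,
    burn_in: int = DEFAULT_BURN_IN,
    innovations: np.ndarray | None = None,
    return_innovations: bool = False,
):
    """Vectorised simulation of the HRV recursion across replicates.

    ``theta1``, ``theta2``, ``sigma`` may be scalars or arrays of shape
    ``(reps,)`` (one parameter set per replicate/column).  Initial history is
    zero; ``burn_in`` leading steps are discarded.  Pass ``innovations`` of
    shape ``(reps, burn_in + n + presample)`` to replay exact draws.

    Returns ``Y`` of shape ``(reps, n)`` (and the innovations if requested).
    """
    theta1 = np.broadcast_to(np.asarray(theta1, dtype=float), (reps,))
    theta2 = np.broadcast_to(np.asarray(theta2, dtype=float), (reps,))
    sigma = np.broadcast_to(np.asarray(sigma, dtype=float), (reps,))
    hist = max(2, kappa2)
    total = hist + burn_in + n
    if innovations is None:
        eps = rng.standard_normal((reps, total)) * sigma[:, None]
        eps[:, :hist] = 0.0
    else:
        eps = np.asarray(innovations, dtype=float)
        if eps.shape != (reps, total):
            raise ValueError(f"innovations must have shape {(reps, total)}")
    y = np.zeros((reps, total))
    one_plus = 1.0 + theta1
    for t in range(hist, total):
        yk = y[:, t - kappa2]
        y[:, t] = (
            one_plus * y[:, t - 1]
            - theta1 * y[:, t - 2]
            - theta2 * yk * np.exp(-yk * yk)
            + eps[:, t]
        )
        if not np.all(np.abs(y[:, t]) <= DIVERGENCE_BOUND):
            raise OverflowError(
                f"simulation diverged at step {t - hist - burn_in + 1} "
                f"(|Y| > {DIVERGENCE_BOUND:g}); the fixed point is not globally stable"
            )
    out = y[:, hist + burn_in :]
    if return_innovations:
        return out, eps
    return out


def simulate_nlari(
    p: ModelParams,
    n: int,
    x0: float = 0.0,
    seed: int | None = None,
    burn_in: int = DEFAULT_BURN_IN,
    rng: np.random.Generator | None = None,
) -> SimSeries:
    """Simulate one NLARI trajectory of length ``n``.

    The detrended component ``Y`` follows the HRV recursion with Gaussian
    innovations ``N(0, sigma^2)`` from zero initial history; the level is
    ``X_t = x0 + (omega/alpha) t + Y_t`` for ``t = 1..n``.

    Parameters
    ----------
    p : ModelParams
    n : int
        Output length, ``>= 3``.
    x0 : float
        Initial level of the trend line.
    seed : int, optional
        Seed for the per-call generator.  Required unless ``rng`` is given:
        silent nondeterminism is not allowed.
    burn_in : int
        Discarded prefix length.
    rng : numpy.random.Generator, optional
        Externally managed generator (takes precedence over ``seed``).
    """
    if n < 3:
        raise ValueError(f"n must be >= 3, got {n}")
    if rng is None:
        if seed is None:
            raise ValueError("simulate_nlari requires a seed (or an explicit rng)")
        rng = np.random.default_rng(seed)
    y, eps = simulate_y_batch(
        p.theta1,
        p.theta2,
        p.sigma,
        n,
        rng,
        reps=1,
        kappa2=p.kappa2,
        burn_in=burn_in,
        return_innovations=True,
    )
    y = y[0]
    eta1 = derived_params(p).eta1
    t = np.arange(1, n + 1, dtype=float)
    x = x0 + eta1 * t + y
    return SimSeries(
        y=y, x=x, x0=x0, seed=seed, burn_in=burn_in, innovations=eps[0], params=p
    )
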