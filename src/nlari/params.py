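"""Model parameters of the stochastic self-restoring (NLARI) heart-rate process.

The process for the log heart-rate level ``X_t`` is a second-order nonlinear
autoregression driven by disturbances ``eps_t`` with mean ``omega`` and
standard deviation ``sigma``::

    X_t = omega + (1 + theta1) X_{t-1} - theta1 X_{t-2}
          + theta2 * (-(X_{t-k2} - mu_{t-k2}) * exp(-(X_{t-k2} - mu_{t-k2})^2))
          + eps_t,          theta1 = 1 - alpha,  theta2 = beta  (kappa1 = 1)

``alpha`` is the resistance coefficient (myocardial electrical resistance),
``beta`` the restoration coefficient (relative PNS-vs-SNS activity), and
``kappa1``/``kappa2`` the resistance/restoration lags.  The relative stability
coefficient ``gamma = beta / (4 - 2 alpha)`` controls the dynamic regime of
the noise-free skeleton:

* ``beta = 0``        -- unit-root process (no restoring force);
* ``0 < gamma < 1``   -- exponentially asymptotically stable fixed point;
* ``1 < gamma < e^.5``-- stable period-two cycle of amplitude ``sqrt(ln gamma)``;
* ``gamma > sqrt(e)`` -- unstable.

The wave indicators are ``eta1 = omega / alpha`` (slope of the mean heart-rate
line) and ``eta2 = sigma / beta`` (amplitude of fluctuations).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "ModelParams",
    "DerivedParams",
    "RegimeLabel",
    "SQRT_E",
    "derived_params",
    "classify_regime",
    "two_cycle_amplitude",
]

#: Upper stability boundary of the period-two cycle.
SQRT_E = math.sqrt(math.e)

#: Relative tolerance used to flag gamma sitting exactly on a regime boundary.
_BOUNDARY_RTOL = 1e-12


@dataclass(frozen=True)
class ModelParams:
    """Ground-truth parameters of the NLARI heart-rate process.

    Parameters
    ----------
    omega : float
        Mean of the disturbances (log-HR units per step).
    sigma : float
        Standard deviation of the disturbances, ``>= 0``.
    alpha : float
        Resistance coefficient, ``> 0``.
    beta : float
        Restoration coefficient, ``>= 0``.
    kappa1 : int
        Resistance lag; the model equations are stated for ``kappa1 = 1``
        and no other value is supported.
    kappa2 : int
        Restoration lag, ``>= 1``.
    """

    omega: float = 0.0
    sigma: float = 0.0
    alpha: float = 1.0
    beta: float = 0.0
    kappa1: int = 1
    kappa2: int = 1

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if self.kappa1 != 1:
            raise ValueError("kappa1 is fixed to 1 in this model")
        if self.kappa2 < 1 or int(self.kappa2) != self.kappa2:
            raise ValueError(f"kappa2 must be a positive integer, got {self.kappa2}")

    @property
    def theta1(self) -> float:
        return 1.0 - self.alpha

    @property
    def theta2(self) -> float:
        return self.beta

    def derived(self) -> "DerivedParams":
        return derived_params(self)


@dataclass(frozen=True)
class DerivedParams:
    """Derived quantities of a parameter set: theta0..2, gamma, eta1, eta2.

    ``eta2`` is ``None`` (undefined, not infinite) when ``beta = 0``.
    """

    theta0: float
    theta1: float
    theta2: float
    gamma: float
    eta1: float
    eta2: float | None


@dataclass(frozen=True)
class RegimeLabel:
    """Dynamic regime of the noise-free skeleton, classified by gamma.

    ``boundary`` is set when gamma sits exactly on one of the open-interval
    endpoints {1, sqrt(e)}; the paper's stability intervals are open, so a
    boundary value belongs to neither side.
    """

    label: str
    gamma: float
    boundary: bool = field(default=False)


def derived_params(p: ModelParams) -> DerivedParams:
    """Compute (theta0, theta1, theta2, gamma, eta1, eta2) from model parameters.

    Raises
    ------
    ValueError
        If ``alpha == 2``, where ``gamma = beta / (4 - 2 alpha)`` is undefined.
    """
    if p.alpha == 2.0:
        raise ValueError("gamma = beta/(4 - 2*alpha) is undefined at alpha = 2")
    gamma = p.beta / (4.0 - 2.0 * p.alpha)
    eta1 = p.omega / p.alpha
    eta2 = p.sigma / p.beta if p.beta > 0 else None
    return DerivedParams(
        theta0=p.omega,
        theta1=1.0 - p.alpha,
        theta2=p.beta,
        gamma=gamma,
        eta1=eta1,
        eta2=eta2,
    )


def classify_regime(p: ModelParams) -> RegimeLabel:
    """Classify the dynamic regime of the deterministic skeleton.

    ``unit_root`` iff ``beta == 0``; otherwise by gamma: stable fixed point on
    (0, 1), stable two-cycle on (1, sqrt(e)), unstable above sqrt(e).
    """
    if p.beta == 0.0:
        return RegimeLabel(label="unit_root", gamma=0.0)
    gamma = derived_params(p).gamma
    if _on_boundary(gamma, 1.0):
        return RegimeLabel(label="stable_fixed_point", gamma=gamma, boundary=True)
    if _on_boundary(gamma, SQRT_E):
        return RegimeLabel(label="stable_two_cycle", gamma=gamma, boundary=True)
    if 0.0 < gamma < 1.0:
        return RegimeLabel(label="stable_fixed_point", gamma=gamma)
    if 1.0 < gamma < SQRT_E:
        return RegimeLabel(label="stable_two_cycle", gamma=gamma)
    return RegimeLabel(label="unstable", gamma=gamma)


def two_cycle_amplitude(gamma: float) -> float:
    """Amplitude ``sqrt(ln gamma)`` of the period-two cycle ``(-1)^t sqrt(ln gamma)``.

    Defined for ``gamma > 1``; returns 0 exactly at the ``gamma = 1`` boundary.
    """
    if gamma < 1.0:
        raise ValueError(f"two-cycle amplitude undefined for gamma <= 1, got {gamma}")
    if gamma == 1.0:
        return 0.0
    return math.sqrt(math.log(gamma))


def _on_boundary(gamma: float, edge: float) -> bool:
    return math.isclose(gamma, edge, rel_tol=_BOUNDARY_RTOL, abs_tol=0.0)
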