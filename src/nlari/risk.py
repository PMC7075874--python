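"""Group-level parameter summaries and the sudden-cardiac-death risk predictor.

The risk predictor combines three multiplicative factors against control
standards (alpha_c, sigma_c, gamma_c), typically the healthy-young group
means: elevated myocardial electrical resistance (alpha/alpha_c), elevated
metabolic variability (sigma/sigma_c), and deviation of the stability
coefficient below or above control::

    rho = (alpha/alpha_c) (sigma/sigma_c) (gamma_c/gamma)   if gamma <= gamma_c
        = (alpha/alpha_c) (sigma/sigma_c) (gamma/gamma_c)   if gamma >  gamma_c

so a stability deviation in either direction raises the score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["GroupAssessment", "RiskScore", "group_assessment", "scd_risk", "compare_to_control"]


@dataclass(frozen=True)
class GroupAssessment:
    """Per-parameter mean and sd over p sample periods x q subjects."""

    group: str
    means: dict[str, float]
    sds: dict[str, float]
    p: int
    q: int


@dataclass(frozen=True)
class RiskScore:
    rho: float
    branch: str
    inputs: tuple[float, float, float]
    controls: tuple[float, float, float]


def group_assessment(estimates, group: str = "") -> GroupAssessment:
    """Group-average mean and sd of parameter estimates.

    ``estimates`` is a DataFrame (or dict of 2-D arrays) with one column per
    parameter; rows are the p*q period-by-subject estimates.  The sd uses
    denominator pq - 1.
    """
    if isinstance(estimates, dict):
        frames = {}
        for k, v in estimates.items():
            arr = np.asarray(v, dtype=float)
            frames[k] = arr.ravel()
        estimates = pd.DataFrame(frames)
    df = pd.DataFrame(estimates)
    if df.size == 0:
        raise ValueError("empty estimate table")
    if len(df) < 2:
        raise ValueError("need pq >= 2 estimates for a group summary")
    means = {c: float(df[c].mean()) for c in df.columns}
    sds = {c: float(df[c].std(ddof=1)) for c in df.columns}
    return GroupAssessment(group=group, means=means, sds=sds, p=1, q=len(df))


def scd_risk(inputs, controls) -> RiskScore:
    """Sudden-cardiac-death risk predictor rho.

    Parameters are triples (alpha, sigma, gamma) for the subject/group under
    assessment and for the control standard; all six must be positive.
    rho is continuous across the branch point gamma = gamma_c, and deviation
    of gamma in either direction increases it.
    """
    alpha, sigma, gamma = map(float, inputs)
    alpha_c, sigma_c, gamma_c = map(float, controls)
    for name, v in [
        ("alpha", alpha), ("sigma", sigma), ("gamma", gamma),
        ("alpha_c", alpha_c), ("sigma_c", sigma_c), ("gamma_c", gamma_c),
    ]:
        if not v > 0:
            raise ValueError(f"{name} must be positive, got {v}")
    base = (alpha / alpha_c) * (sigma / sigma_c)
    if gamma <= gamma_c:
        rho = base * (gamma_c / gamma)
        branch = "low"
    else:
        rho = base * (gamma / gamma_c)
        branch = "high"
    return RiskScore(
        rho=float(rho),
        branch=branch,
        inputs=(alpha, sigma, gamma),
        controls=(alpha_c, sigma_c, gamma_c),
    )


def compare_to_control(
    group: GroupAssessment,
    control: GroupAssessment,
    increase: float = 1.25,
    ultra: float = 2.0,
) -> pd.DataFrame:
    """Per-parameter ratios to the control group with direction labels.

    Ratios above ``increase``/``ultra`` are labelled ``increase``/
    ``ultraincrease`` (and symmetrically below their reciprocals for
    decreases); thresholds are configurable as the banding is qualitative.
    """
    common = [k for k in group.means if k in control.means]
    if not common:
        raise ValueError("no common parameters between the two groups")
    rows = []
    for k in common:
        g, c = group.means[k], control.means[k]
        ratio = g / c if c != 0 else np.inf
        if ratio >= ultra:
            label = "ultraincrease"
        elif ratio >= increase:
            label = "increase"
        elif ratio <= 1.0 / ultra:
            label = "ultradecrease"
        elif ratio <= 1.0 / increase:
            label = "decrease"
        else:
            label = "unchanged"
        rows.append({"parameter": k, "group": g, "control": c, "ratio": ratio, "label": label})
    return pd.DataFrame(rows)
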