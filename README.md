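# nlari

A Python package for modelling heart-rate dynamics as a **stochastic
self-restoring system**: a nonlinear autoregressive integrated (NLARI)
process in which every beat reflects the balance between cardiac
disturbances, a parasympathetic-vs-sympathetic (PNS−SNS) restoring force,
and myocardial electrical resistance.

It is aimed at HRV researchers and biostatisticians who want physiologically
interpretable parameters out of ordinary RR-interval (or instantaneous heart
rate) recordings — and a formal test of whether a recording is compatible
with *stable homeostasis* — rather than descriptive frequency-band indices
alone.

## The model

Let `X_t = log HR_t` (HR in bpm, HR = 60/RR). The level follows

```
X_t = ω + (1+θ₁) X_{t−1} − θ₁ X_{t−2} + θ₂ · ( −(X_{t−κ₂}−μ_{t−κ₂}) · exp(−(X_{t−κ₂}−μ_{t−κ₂})²) ) + ε_t
θ₁ = 1 − α,   θ₂ = β,   μ_t = X₀ + (ω/α) t,   ε_t ~ N(0, σ²)
```

Writing `Y_t = X_t − X₀ − (ω/α)t` for the detrended HRV component gives the
HRV recursion `Y_t = (1+θ₁)Y_{t−1} − θ₁Y_{t−2} − θ₂ Y_{t−κ₂} e^{−Y²_{t−κ₂}} + ε_t`.

Parameters and their physiological reading:

| symbol | meaning |
|---|---|
| ω, σ | mean / sd of cardiac disturbances (metabolic load and its variability) |
| α | myocardial electrical resistance coefficient |
| β | PNS−SNS (restoration) activity coefficient |
| γ = β/(4−2α) | stability coefficient of the dynamics |
| η₁ = ω/α | heart-rate slope indicator |
| η₂ = σ/β | heart-rate amplitude indicator |

The noise-free skeleton has a fixed point that is exponentially
asymptotically stable for γ ∈ (0,1) ("stable homeostasis"), a stable
period-two cycle of amplitude √(ln γ) for γ ∈ (1, √e), instability beyond
√e, and degenerates to a unit-root (random-walk-like) process when β = 0.

All parameters are estimated by OLS: a linear trend is removed from log HR,
then `ΔY_t` is regressed on `(ΔY_{t−1}, −Y_{t−1}e^{−Y²_{t−1}})`. The
homeostasis test battery checks the 95% confidence intervals of θ₁ and θ₂
against the theoretical stable intervals (−1,1) and (0,4), an F test of
γ = 1, and the nonstandard γₙ statistic for γ = 0 (no restoring force),
whose null distribution is related to a Brownian endpoint over the square
root of its local time at zero.

Also included: noise-driven and clipped-stimulus-driven HRV responders for
prediction/simulation, parameter-sensitivity analysis under disturbance
perturbations, block-mean time-scale analysis, AR(16) power-spectral
(VLF/LF/HF) comparison, and a multiplicative sudden-cardiac-death risk score.

## Worked example

Simulate a 900-beat RR series in the stable regime (α=0.7786, β=0.3,
σ=0.0275, ω=1e−4) and recover its physiology:

```python
import numpy as np
from nlari import ModelParams, simulate_nlari, estimate, homeostasis_test

p = ModelParams(omega=1e-4, sigma=0.0275, alpha=0.7786, beta=0.3)
sim = simulate_nlari(p, 900, x0=4.1, seed=42)
rr = 60.0 / np.exp(sim.x)          # RR intervals in seconds

est = estimate(rr, kind="rr_seconds")
print(est.as_dict())

report = homeostasis_test(rr, kind="rr_seconds")
print(report.as_dict())
```

This prints (exact numbers for seed 42):

```
 omega:  0.00010
 alpha:  0.73264
  beta:  0.28699
 gamma:  0.11323
  eta1:  0.00014
  eta2:  0.09725
 sigma:  0.02791
theta1 95% CI: [0.2043, 0.3305]  in (-1,1): True
theta2 95% CI: [0.2444, 0.3296]  in (0,4):  True
F (gamma=1): 1376.8  > 6.66: reject = True
gamma_n (gamma=0): 161.4  outside (-3.50, 11.9): reject = True
homeostatic: True
```

Reading: the resistance (α̂=0.73) and restoration (β̂=0.29) coefficients and
the disturbance moments are recovered close to the generating values; the
stability coefficient γ̂=0.11 sits deep inside (0,1); all four sub-tests
pass, so the series is accepted as output of the stable homeostatic HRV
responder. The amplitude indicator η̂₂ ≈ 0.097 matches σ/β ≈ 0.092.

The same pipeline is exposed as a scikit-learn style estimator
(`NLARIEstimator(kind="rr_seconds").fit(rr)`, fitted attributes `alpha_`,
`beta_`, `gamma_`, ...) and as a CLI:

```bash
nlari synth --regime stable_fixed_point -n 900 --seed 7 --out-dir fixtures
nlari test fixtures/synthetic_stable_fixed_point_w0.txt --json
nlari psd fixtures/synthetic_stable_fixed_point_w0.txt --out psd.csv
```

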