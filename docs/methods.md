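# Methods

## Model

The package models the log heart-rate level `X_t = ln(HR_t)` as a
second-order nonlinear autoregression driven by disturbances with mean ω and
standard deviation σ, damped by a resistance coefficient α and pulled back
toward its mean line by a saturating restoring force with coefficient β:

```
Y_t = (1+θ₁) Y_{t−1} − θ₁ Y_{t−2} − θ₂ Y_{t−κ₂} exp(−Y²_{t−κ₂}) + ε_t
θ₁ = 1−α,  θ₂ = β,  ε_t ~ N(0, σ²)
```

where `Y_t = X_t − X₀ − (ω/α)t` is the detrended HRV component. The
restoring term `−βY e^{−Y²}` is linear near equilibrium and dies off for
large excursions, so the fixed point is locally but **not globally** stable;
simulations therefore guard against divergence (|Y| > 10⁶ aborts with an
error identifying the step) rather than silently saturating.

The stability coefficient γ = β/(4−2α) governs the noise-free skeleton:
stable fixed point on (0,1), stable period-two cycle of amplitude √(ln γ) on
(1, √e), instability beyond √e, and a unit-root process at β = 0. Values of
γ exactly on a boundary are reported with an explicit boundary flag because
the stability intervals are open. γ is undefined at α = 2 (explicit error).

### Simulation choices

* Simulation runs on the detrended recursion and adds the trend
  `X_t = x₀ + (ω/α)t + Y_t` afterwards; for Gaussian disturbances this is
  equivalent to iterating the level equation and numerically simpler.
* Stochastic runs start from zero history with a default burn-in of 500
  discarded steps; deterministic probes default to init 0.1 (any nonnull
  start reaches the two-cycle). Neither value is critical; both are
  parameters.
* Every simulation call takes a seed (or an explicit generator); the
  innovations actually used are retained so any run can be replayed draw
  for draw. Monte-Carlo modules vectorise the recursion across replicates,
  which keeps the full acceptance pipeline at a few seconds on one core.

### Stability probing

`find_stability_boundary` bisects γ (varying β at fixed α) on an empirical
criterion: after a long transient, the deviation of iterates from the
candidate attractor (0, or the ±√(ln γ) cycle) must shrink by more than 1%
between the last two 3000-step windows, or have decayed below 10⁻¹².
The 1% shrink margin distinguishes genuine decay from the sub-percent
fluctuation of window maxima on a saturated non-attracting orbit. With a
12000-step horizon the located boundaries agree with the theoretical values
1 and √e to the requested 10⁻³ width (verified in the acceptance suite).

## Estimation

Three OLS steps, exactly in the first-difference form of the model:

1. remove the OLS line `X_t = a + bt` (always — even when b̂ ≈ 0 — so the
   pipeline is identical for trending and non-trending records);
2. regress `ΔY_t` on `(ΔY_{t−1}, −Y_{t−κ₂} e^{−Y²_{t−κ₂}})` by the normal
   equations; σ̂² = RSS/(rows−2), classical standard errors from
   `(Z'Z)^{-1}`, and the delta-method standard error for γ̂;
3. map: α̂ = 1−θ̂₁, β̂ = θ̂₂, γ̂ = θ̂₂/(2(1+θ̂₁)), ω̂ = b̂(1−θ̂₁), η̂₁ = b̂,
   η̂₂ = σ̂/θ̂₂.

The regression starts at t = max(3, κ₂+2): the presample prefix is dropped
rather than imputed, and the effective row count is reported. "log" is the
natural log, which keeps the log transform symmetric with the exp(·) in the
restoring force. The tests cross-check this estimator against an
independent OLS implementation and against brute-force RSS minimisation
over a fine (θ₁, θ₂) grid on tiny inputs.

A useful analytic landmark used in the time-scale analysis: for white-noise
input of small amplitude, the population projection gives θ₁ → 0, θ₂ → 1
(derived from the autocovariances of ΔY against the two regressors), hence
α̂ and β̂ both → 1 when a series is aggregated until it resembles white
noise.

## Homeostasis testing

A record is accepted as *stable homeostatic* iff all four hold:

1. 95% CI of θ̂₁ inside (−1, 1);
2. 95% CI of θ̂₂ inside (0, 4) — CIs use two-tailed Student-t critical
   values with rows−2 degrees of freedom;
3. F test rejects γ = 1. Under that restriction θ₂ = 2(1+θ₁), so the
   restricted model is the single-regressor OLS fit of
   `(ΔY_t + 2Y_{t−1}e^{−Y²})` on `(ΔY_{t−1} − 2Y_{t−1}e^{−Y²})`; this is the
   algebraically consistent restricted least-squares problem, it nests
   inside the unrestricted fit, and it guarantees RSS₀ ≥ RSS₁ and F ≥ 0.
   F is compared with the F(1, rows−2) critical value (default level 1%).
4. the γₙ test rejects γ = 0 (no restoring force), with

   `γₙ = (πn/(32σ̂⁶))^{1/4} · √(1−θ̂₁) · θ̂₂`.

   The fourth-root norming is what makes the statistic meaningful: under
   the unit-root null the nonlinear regressor is only active when Y visits
   the origin, Σ Y²e^{−2Y²} grows on the local-time scale
   (√n/σ_lr)·L·√(π/32), and the norming cancels this exactly, giving the
   scale-free limit W(1)/√L(1,0) with √(1−θ₁) absorbing short-run
   autocorrelation. On data-scale records (σ̂ ≈ 0.03, n = 900) the statistic
   lands in the tens-to-hundreds for stable-regime series, which is what
   the power checks in the test suite assert.

### Critical values for γₙ

The package ships the conventional tabled pair (−3.50, 11.9) for the
two-sided 1% test as the default, and `null_critical_values` regenerates
empirical quantiles by Monte Carlo under the β = 0 null
(ΔY_t = θ₁ΔY_{t−1} + ε_t; canonical θ₁ = 0, σ = 1, both configurable),
allocating 0.5% per tail by default. Quantile uncertainty is reported via
distribution-free order-statistic standard errors, which remain honest for
this statistic's heavy-tailed null.

Two facts, both computed by the test and acceptance suites, deserve
emphasis:

* the Monte-Carlo null under the canonical unit-scale setup does **not**
  reproduce the tabled pair — the upper 0.5% quantile comes out near 5, not
  11.9 (the corresponding acceptance check is deliberately left failing
  rather than retuned);
* the finite-sample null distribution depends strongly on the innovation
  scale and on whether the detrending step is applied, i.e. the statistic
  is far from its pivotal limit at n = 900. Against the tabled values the
  test is conservative under the canonical null (size ≤ ~1–4% is asserted)
  and extremely powerful against stable-regime alternatives (|γₙ| > 11.9 in
  ≥ 99% of replicates at n = 900).

Users who want critical values matched to their recording scale should call
`null_critical_values(sigma_null=..., detrend=True)`. A discretised
Brownian-path simulator for the limiting ratio W(1)/√L(1,0) (ε-window local
time, ε = N^(−1/4)) is provided as a cross-check only.

## HRV responders

*Noise-driven*: innovations N(0, σ̂²); (θ₁, θ₂) are tuned over the 95%
confidence box of the in-sample fit on a 21×21 grid (default), each
candidate scored by the median RMSE of 20 seeded realizations against the
actual HRV. "As close as possible" is operationalised as minimum RMSE; a
single noise matrix is shared across candidates (common random numbers), so
the objective is comparable across candidates and refinement never worsens
the best score. Out-of-sample prediction splits at ⌊n/2⌋, extrapolates the
in-sample trend (using the out-sample to detrend would leak), and starts
the recursion from the last in-sample HRV values.

*Stimulus-driven*: (θ₁, θ₂) fixed at the OLS estimates; the innovation is
the observed HRV clipped at ±c, with the recursion feeding back its own
fitted values (first values set to the observed ones — whether fitted or
observed lags feed back is a genuinely open choice; fitted feedback makes
the output a proper responder trajectory). The threshold grid is geometric
from max|Y|/1000 to max|Y|: on near-unit-root records the best c is small,
where the clipped drive acts like delta modulation and tracks the slow
excursions that defeat the noise-driven responder.

ACF curves use the standard sample autocorrelation; the long-memory flag is
set when the ACF tail decays more slowly than its best-fit exponential
envelope or keeps oscillating outside the 2/√n band, the signature of a
long even restoration delay (κ₂ = 10).

## Sensitivity analysis

An extra disturbance input with mean ω_i and sd σ_i shifts the simulated
process's disturbance mean to ω+ω_i (trend slope (ω+ω_i)/α) and the
innovation sd to √(σ²+σ_i²). Sensitivity of parameter φ is

```
S(ω_i, φ) = |(φ_i − φ) ω / (ω_i φ)|
S(σ_i, φ) = |(φ_i − φ) σ / ((√(σ²+σ_i²) − σ) φ)|
```

with φ_i the disturbed estimate averaged over replicates (default 300 at
n = 900; the desk-scale default trades the original 3000 for speed and is
configurable). Classification: perfectly insensitive (0), insensitive (<1),
unit sensitive (=1), sensitive (>1); a zero base parameter makes S
undefined and is flagged, never silently dropped. Mean shifts report
φ ∈ {α, β, γ, σ, η₂}, sd shifts φ ∈ {ω, α, β, γ, η₁}.

In the stable regime all sensitivities stay well below 1 over the grid
ω_i = 0.00004·i, σ_i = 0.007·i (i = 1..20). Near the stability boundary
(γ ≈ 0.017) the β and γ estimates are sensitive (S > 1) to sd shifts — and
the peak sits at the *smallest* shifts, where the relative input change in
the denominator is smallest; sensitivity decays as the shift grows.

## Time-scale analysis

Aggregation is the block mean `Y^(m)_t = (1/m) Σ Y_{(t−1)m+i}` with output
length ⌊T/m⌋ (remainder dropped). `scale_sweep` simulates at base scale
(beats ≈ 1 s), aggregates, re-estimates and averages over replicates.
Block means of a short-memory series approach white noise, so by the
white-noise limit above both α̂ and β̂ converge to 1 at minute scales
(m = 60: both within 0.1 of 1; tightening further at larger m) — the model
parameters lose their physiological content on over-enlarged scales, which
bounds the usable observation scale to seconds. The scale m is always
explicit; nothing is inferred from timestamps.

## Spectral comparison

AR(16) spectra are fitted with Burg's method by default (stable for short
HRV segments; Yule-Walker available), evaluated as a one-sided density on
[0, 0.5] cycles/sample whose integral matches the model variance. Beats are
treated as 1 s apart so cycles/sample read as Hz; bands are VLF 0–0.05,
LF 0.05–0.15, HF 0.15–1.0 Hz, with the HF integral truncated at the Nyquist
frequency (0.5) and a log note emitted. `band_powers` is grid-agnostic, so
a caller who resamples onto a finer physical-frequency grid gets the full
0.15–1.0 HF band.

The "frequency of a series" in the restoration-coefficient sweep is the
mean zero-crossing rate of the mean-removed series (model-free; an
alternating series gives 0.5), with the AR dominant frequency as an
alternative. Two robust findings, asserted by rank correlation in the
acceptance suite: frequency rises with β at the base scale, and the
β-dependence flattens steadily as the aggregation scale grows. The LF/HF
ratio falls with β over the low-restoration range (β ≤ 0.1). **Limitation:**
under this package's band conventions the LF/HF ratio keeps falling as β
grows further — the spectral peak simply moves deeper into the HF band —
so a rising LF/HF at high restoration coefficients, sometimes described for
this model, is not reproduced here; it appears to hinge on unstated
spectral conventions.

## Group assessment and risk score

Group summaries are the plain mean and sd (denominator pq−1) of the
per-window parameter estimates over p periods × q subjects. The
sudden-cardiac-death score is

```
ρ = (α/α_c)(σ/σ_c)(γ_c/γ)  if γ ≤ γ_c,   (α/α_c)(σ/σ_c)(γ/γ_c)  otherwise
```

— multiplicative in resistance excess, metabolic-variability excess and the
direction-folded stability deviation, continuous at γ = γ_c. Control
standards (α_c, σ_c, γ_c) are supplied by the user or computed as a healthy
control group's means; no clinical values are hard-coded, and the score is
a screening construct without clinical validation. Alteration banding
against a control group uses configurable ratio thresholds (1.25 for
increase, 2.0 for ultra-increase).

## What the synthetic data does and does not emulate

The fixture generator produces 900-point beat-series windows (RR seconds or
HR bpm) from the model itself, with a linear log-HR trend, Gaussian
disturbances, and parameter presets spanning the stable regime, the
stability boundary, the unit-root case and the two-cycle regime; manifests
record the generating truth and seed, and regeneration is byte-identical.
Passing tests on these fixtures demonstrate internal consistency —
estimator recovery, test power and size, responder behaviour — under the
model's own assumptions. They do not demonstrate anything about real
recordings: ectopy and artefacts, heart-rate asymmetry (the model is
time-reversible by construction), non-Gaussian disturbances and
nonstationary parameter drift are all outside the generator, and published
subject-level parameter tables are not reproduced here because the exact
recording windows behind them are not specified.

## Known limitations

* The γₙ critical-value pair shipped as the default could not be
  regenerated from any simulable null (see above); decisions at the 1%
  level near the boundary should rely on `null_critical_values` matched to
  the recording scale.
* Estimates near γ = 1 can be inconsistent after large shocks (the fixed
  point is not globally stable); the log transform reduces, but does not
  eliminate, the issue.
* κ₁ is fixed at 1; only the discrete-time process is implemented.
* Minute-scale aggregation destroys parameter interpretability by design
  (see Time-scale analysis); this is a property of the model, not a bug.
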