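# Methods

This note documents the statistical model behind `nbdecide`, the numerical
choices in its implementation, what the synthetic-data generators do and do
not emulate, and the package's known limitations.

## Model

Both pipeline stages are linear Gaussian autoregressions with exogenous
covariates (ARX):

* **Employment (benefit side).** Weekly percent employed, 0–100 scale:
  `E_t = α₀ + α₁ c_t + α₂ d_t + Σᵢ φᵢ E_{t−i} + ε_t`, ε ~ N(0, σ²).
  `c_t` is test positivity as a fraction in [0, 1] (zero before pandemic
  onset); `d_t ∈ {0,1}` marks recession/pandemic regime windows. Keeping
  employment on the percent scale and positivity as a fraction puts the
  infection coefficient at an interpretable magnitude (percentage points
  of employment per unit of positivity).
* **Fatality rate (cost side).** Daily
  `w_t = γ₀ + γ₁ c_t + Σᵢ φᵢ w_{t−i} + ε_t`, where
  `w_t = cum_deaths_t / cum_positives_{t−7}`. Deaths follow infections
  with delay, hence the 7-day-lagged denominator (configurable). The
  numerator is **cumulative** deaths on day *t*, consistent with how
  health agencies report case-fatality ratios and with the magnitude of
  the shipped Florida baseline (w₀ = 3.48%); incident deaths are
  recoverable by differencing if a user wants a different construction.
* Daily positivity is reduced to a weekly covariate by taking the rate on
  the **last observed day of each Monday-start week** — the most recent
  information available within the week. Weeks ending before onset are
  zero by definition.

Priors are deliberately diffuse: N(0, 100) on the intercept and exogenous
coefficients, Uniform[−1, 1] on each AR coefficient, and
InverseGamma(0.01, 0.01) on σ². The uniform box is applied per
coefficient; joint stationarity of higher-order AR polynomials is *not*
enforced. The likelihood conditions on the first p observations
(conditional likelihood) — no stationary-initial-value treatment.

## Sampling

The posterior is simulated by a two-block Gibbs sampler with exact
full-conditional draws:

1. **All regression coefficients jointly, given σ².** The conditional is
   multivariate normal truncated to the AR box `[−1, 1]^p`. We draw from
   the untruncated normal (prior precision 1/100 on non-AR coordinates,
   zero on AR coordinates) and reject draws outside the box; away from the
   boundary the acceptance rate is essentially 1. If 50 proposals are
   rejected, the iteration falls back to one sweep of coordinate-wise
   truncated-normal full conditionals (inverse-CDF sampling), which is
   exact as well. The joint block update avoids the slow mixing that a
   coordinate-wise scheme exhibits when the intercept and a persistent lag
   are strongly correlated.
2. **σ² given the coefficients:** conjugate inverse-gamma.

All per-iteration quantities are formed from precomputed Gram matrices, so
iteration cost is independent of the series length. Defaults are 20,000
iterations with a 10,000 burn-in in each of two chains; draws are
bit-reproducible given a seed (chains use `SeedSequence.spawn`).
Initial values are ridge-regularised least squares with AR components
clipped inside the prior support.

Convergence is monitored with split-R̂ (rank-normalised) and bulk
effective sample size via `arviz`; fits attach a warning when any R̂
exceeds 1.05. Credible intervals are highest-posterior-density intervals
computed as the shortest contiguous window over the sorted pooled draws.

## Lag-order selection

Candidate orders p = 1..p_max (default 7) are compared by posterior model
probability under a uniform model prior. Every candidate is scored on the
common window obtained by dropping the first p_max observations, so
evidences are comparable. The evidence is estimated by Laplace–Metropolis:
posterior mean and covariance of the retained draws plug into the Laplace
approximation, with σ² mapped to the log scale (Jacobian included in the
prior density) so the Gaussian approximation acts on an unconstrained
coordinate. The estimator is deterministic given the draws and was
validated against a closed-form conjugate evidence (fixed σ²: within 0.1
nats) and dense 2-D grid integration (within 0.2 nats) in the test suite.

## From predictive draws to money

One-step-ahead predictive simulation draws, per retained posterior draw,
the linear predictor plus N(0, σ²-draw) noise, conditioning on the p most
recent observed outcome values and a covariate scenario. For
pandemic-period scenarios the regime dummy defaults to 1 (overridable).

* **Benefit**: income draw = `E/100 × annual per-capita income` (the
  shipped Florida figures are $52,426, or $58,371 with federal relief
  transfers included). Negative employment draws — possible in the far
  normal tail — are clipped to zero with a warning. No household-size
  scaling is applied.
* **Cost**: relative to a baseline day with rates (w₀, c₀), the four
  components are `Δλ_Si = (w₀c₀ − wc)·C_Si` (i = 1, 2, 3) and
  `Δλ_D = (wc − w₀c₀)·C_D`, which collapse to
  `(wc − w₀c₀)(C_D − C_S1 − C_S2 − C_S3)`; with the default assumptions
  the multiplier is exactly $6,968,000. Treatment cost for a patient who
  dies is taken equal to that for one who recovers (C_S3 = C_S2 =
  $15,000), since there is no reliable basis for distinguishing them.
  Costs may be negative when the scenario product wc falls below the
  baseline product.

**dNB simulation.** Benefit and cost predictive distributions are
approximately normal, so dNB draws are formed by resampling each as an
independent normal with its Monte-Carlo mean and SD and subtracting
(default 5,000 draws). Reported summaries: mean, SD, 2.5/97.5 percentiles,
and P(dNB > 0). Dollar tables are rounded to the nearest dollar,
probabilities to four decimals.

**Scenario tables.** A policy j carries a probability row π_jk over
incremental infection rates k. Expected benefit is E(B_j) = Σ_k π_jk
E(B_jk). For the probability of a positive outcome, P_j, two readings of
"prob(B_j > 0)" exist:

* the **π-weighted sum** of independent per-rate draws,
  `P_j = P(Σ_k π_jk B_jk > 0)`, with closed form
  `Φ(Σπμ / √(Σπ²σ²))` — the default, because it reproduces the published
  Florida look-up table to within 0.006 in every cell;
* the **mixture** `Σ_k π_jk P(B_jk > 0)` — exposed via
  `method="mixture"`, but it yields materially lower probabilities
  (e.g. 0.874 instead of 0.9988 for the Minor policy under scenario 1)
  and does not match the published table.

The risk-neutral choice is argmax E(B_j); the risk-averse choice is
argmax E(B_j) among policies with P_j > T. Ties break toward the policy
listed earlier in the matrix (least disruptive first) — a conservative
convention under equal expected benefit.

One published look-up cell (Minor policy, scenario 3) equals 21,475.6 when
recomputed from the *printed* dNB means, one dollar above the published
21,475; the published cell was evidently rounded from unrounded means. The
golden tests allow that single dollar.

## Synthetic data

The generators realise exactly the statistical structure the two models
assume, with ground truth attached, so every stage is testable without the
original employment and epidemic series:

* **Employment panels** follow the ARX recursion over Monday-start weeks
  (default window 2007–2020: 696 weeks, a 2007-12→2009-06 recession
  window, pandemic onset 2020-03-02, positivity ramping logistically to
  12% after onset — the order of magnitude observed in Florida). Default
  truth (α₀ = 3, α₁ = −5.67, α₂ = −0.05, φ = (0.35, 0.95, −0.05, −0.30),
  σ = 0.155) gives a persistent series with a long-run level near 60% and
  week-to-week noise of ~0.15 percentage points, matching the magnitudes
  of the published Florida posterior. Explosive configurations warn;
  values leaving [0, 100] are clipped with a warning.
* **Epidemic panels** are back-constructed from a simulated fatality-rate
  process rather than from a mechanistic epidemic: cumulative tests grow
  by a fixed daily volume (default 200,000 — large enough that count
  rounding is negligible), positives are `round(c_t × cum_tests)`, and
  deaths are `round(w_t × cum_positives_{t−7})`. Because cumulative
  deaths cannot fall, a rate draw below the level already implied by
  accumulated deaths is raised to that feasibility floor (counted and
  warned); draws are also clipped to [0, 1]. With this construction,
  `compute_death_rate` recovers the stored truth path within one count of
  rounding on every day, and cumulative monotonicity holds by
  construction. The default noise (σ = 0.003/day) keeps the generated
  rate within the realistic few-percent band; much larger values would
  make daily swings that a cumulative ratio cannot express, engaging the
  floor on most days.

What the generators deliberately do **not** emulate: reporting artifacts
(weekend dips, backfills, revisions), mechanistic transmission dynamics,
seasonality in employment, or cross-state heterogeneity. Passing tests
therefore demonstrate correctness of the pipeline under its own model
assumptions, not robustness to real-data violations of them.

## Verification strategy and problem sizes

The published state-level posterior tables cannot be reproduced without
the original (undeposited) series, so the model-fitting stages are
validated property-wise on synthetic data:

* posterior moments for lag-free models agree with dense-grid integration
  of the exact posterior within 3 Monte-Carlo standard errors;
* 95% HPDs cover generating parameters on 20 synthetic panels (n = 300,
  ARX(1)) at a rate not statistically below nominal (binomial test,
  α = 0.01);
* lag selection puts the modal posterior probability on the generating
  order for ≥ 90% of 20 strong-signal AR(2) datasets (n = 600);
* one-step out-of-sample RMSE approaches the innovation SD within 20% on
  a well-specified AR(1) at n = 1000.

Tests and the verification scripts run the sampler at 1,500–6,000
iterations per chain — enough for the ~1,000-fold effective sample sizes
these checks need — while the package defaults remain 20,000/10,000.
Published-table checks (expected benefits, P_j cells, dNB probabilities)
use 100,000 Monte-Carlo draws or the closed-form normal expressions, which
puts simulation error well below the tables' printed precision.

## Limitations

* Single-equation models: no feedback from employment to infection, no
  supply-side channel, no panel pooling across regions.
* Out-of-sample evaluation fits once on the training window and predicts
  each holdout step from observed lags (`refit=True` re-estimates each
  step at proportional cost).
* Benefit and cost draws are treated as independent when forming dNB;
  any correlation induced by the shared infection-rate scenario is
  ignored, consistent with how the published distributions combine.
* The threshold rule is a hard cut; no continuous utility-based risk
  aversion.
* VSL is a single constant (no age schedule), costs are undiscounted, and
  healthcare-capacity constraints are out of scope.
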