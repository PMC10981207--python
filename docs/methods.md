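# Methods

This note records the statistical conventions implemented by `bayesadapt`:
what is estimated, how posterior draws are produced, and how the adaptive
design and its operating characteristics are defined. Section references are
to modules in `src/bayesadapt/`.

## 1. Estimands (`estimands.py`)

All trial decisions concern a **marginal** (population-averaged) contrast of
arm-specific outcome parameters, γ = f(μ₁, μ₀), where μₐ is the mean outcome
that would be observed if the whole covariate population were assigned arm
A = a:

| endpoint      | arm parameter μₐ                   | contrast γ                  | null |
|---------------|------------------------------------|-----------------------------|------|
| continuous    | mean outcome                       | μ₁ − μ₀ (difference)        | 0    |
| binary        | event risk                         | μ₁ / μ₀ (relative risk)     | 1    |
| binary        | event risk                         | odds(μ₁)/odds(μ₀) (OR)      | 1    |
| time-to-event | survival probability at horizon t* | log μ₁ / log μ₀ (HR)        | 1    |

The hazard-ratio convention uses the identity HR = log S₁(t)/log S₀(t), exact
under proportional hazards, evaluated at the analysis horizon (the interim
calendar time for interim looks, the administrative horizon t* = 50 for the
final analysis). Benefit is a *smaller* outcome in every family, so the
alternative region is γ < null value.

The difference in means with an identity link and no treatment-covariate
interactions is collapsible: the marginal and conditional effects coincide
draw by draw (this identity is enforced by a machine-precision test). Odds
and hazard ratios are **non-collapsible**: the marginal ratio is generally
closer to the null than the conditional ratio even in a randomized trial, so
the adjusted conditional coefficient cannot be used directly as the decision
quantity.

## 2. Data-generating mechanisms (`dgm.py`, `scenarios.py`)

Each simulated trial draws participants with jointly independent baseline
covariates, assigns treatment A ~ Bernoulli(0.5) independently of covariates,
and forms the linear predictor

η = β₀ + ϕA + Σⱼ βⱼ termⱼ(x),

where terms may include a squared covariate (e.g. X3²). Outcomes:

- **continuous**: Y ~ Normal(η, σ²), σ = 1, observed at enrollment;
- **binary**: Y ~ Bernoulli(expit(η)), observed at enrollment; β₀ is solved
  by deterministic Monte-Carlo root finding (common random numbers, 10⁶
  covariate draws) so the *marginal* control-arm risk hits a target (0.30 for
  the grid scenarios, 0.07 for the registry emulation);
- **time-to-event**: latent times are Exponential with rate λ·exp(η − β₀)
  (the intercept is absorbed into the baseline rate λ = 0.02), enrollment is
  uniform over [0, 25] calendar units, and follow-up is administratively
  censored at calendar time 50.

The benchmark grid uses covariates {X1, X2 ~ Bern(0.5); X3, X5 ~ N(0,1)} in
the outcome model plus pure-noise {X6 ~ Bern(0.5); X7, X8 ~ N(0,1)}. The
registry-based COVID-19 emulation (CCEDRRN scenarios) uses truncated-normal
age and respiratory rate — parameterized by *post-truncation* support, mean
and SD, with the underlying normal solved by 2-D root finding; the published
quartiles over-determine the law and serve only as validation data — plus
Bernoulli sex, chest pain, and arrival mode, a maximum of 3000 participants,
and event-driven interims after every 75 new events.

Scenario effect sizes (ϕ, with the implied marginal γ) are tabulated per
endpoint and maximum sample size in `scenarios.py`; the true marginal γ for
any DGM can also be recomputed by Monte-Carlo standardization
(`true_marginal_estimand`).

## 3. Outcome models and priors (`models.py`)

Six analysis models per scenario share one naming scheme: `correct` (the DGM's
own signal terms), `no_quad` (omits the quadratic), `correct_noise` (adds the
noise covariates), `correct_prior` / `correct_strong_prior` (priors centered
on the true coefficients, weakly / strongly concentrated), and `unadjusted`
(treatment only).

Priors are weakly informative and **autoscaled** to the analysis snapshot
after internally centering the predictors, in the style of common applied
Bayesian GLM defaults:

- intercept ~ N(ȳ, 2.5·s_y);
- slope for term j ~ N(0, 2.5·s_y / s_{x_j});
- residual scale (normal family) σ ~ Exponential(1/s_y);
- binary and PH families use the conventions ȳ = 0, s_y = 1;
- `centered` mode moves the slope prior location to the supplied coefficient
  (same scale); `strong` mode also shrinks the scale to s_y / s_{x_j};
- the treatment prior is always the weak zero-centered one, so informative
  priors never touch the effect under test;
- the baseline-hazard simplex gets ψ ~ Dirichlet(1, …, 1).

The proportional-hazards baseline is an **M-spline mixture**: h₀(t) =
Σ ψ_l M_l(t) with cumulative hazard Σ ψ_l I_l(t), cubic basis with boundary
knots at 0 and the current analysis horizon and interior knots at terciles of
the observed event times (`splines.py`; both bases are evaluated through
B-spline identities and verified against quadrature oracles).

## 4. Posterior computation

All decision quantities need only an exchangeable sample
θ₁,…,θ_S from the posterior (default S = 3000):

- **Normal family — exact sampling.** With Gaussian priors, the coefficient
  block is integrated out analytically (via an SVD of the prior-scaled,
  centered design), σ is drawn from its exact 1-D marginal posterior by
  inverse-CDF on a 600-point log grid, and coefficients follow from the
  conjugate Gaussian conditional. Draws are i.i.d.; no convergence issue can
  arise.
- **Logistic and PH families — Laplace + SIR.** The posterior mode is found
  by quasi-Newton optimization with analytic gradients, the Hessian is formed
  (analytically for the logistic family, by central differences of the
  analytic gradient for the PH family, whose simplex is parameterized by a
  softmax with the last category as reference and a Dirichlet-plus-Jacobian
  prior term). A multivariate-t proposal (df = 7, scale inflated 1.2×) around
  the Laplace approximation is then corrected by sampling-importance-
  resampling with a 4× oversampled pool.

Every fit returns a convergence report: split-R̂ over pseudo-chains for each
parameter (threshold 1.05) and, for SIR fits, the normalized importance
effective sample fraction. A failed check is surfaced as a warning and the
analysis is flagged; a failed *fit* is recorded on the trial result without
silently dropping the replicate. The samplers are validated in the test suite
against closed-form conjugate posteriors, quadrature oracles, parameter
recovery at n = 5000, and an independent MCMC sampler.

## 5. Standardization and the decision rule (`gcomp.py`)

Each posterior draw θₛ of conditional parameters is converted into a draw of
the marginal arm parameter by averaging conditional predictions over the
covariate patterns of the participants enrolled at the analysis:

μ(θₛ; A = a) ≈ Σᵢ wᵢₛ · g⁻¹(η(θₛ; a, xᵢ)),

with one Bayesian-bootstrap weight vector wₛ ~ Dirichlet(1,…,1) per draw,
shared between the two arms within a draw. The weights propagate uncertainty
about the covariate distribution itself; with the weights fixed at 1/n the
procedure reduces to plug-in standardization. For the PH family the
conditional prediction is the survival probability at the analysis horizon.
Unadjusted models shortcut to a direct transform of the (intercept,
treatment) draws.

The decision statistic is T = (1/S) Σₛ 1{γₛ < null}, and superiority is
declared when **strictly** T > u (u = 0.99 throughout), so T = 0.99 does not
stop the trial.

## 6. Sequential design (`sequential.py`)

- **Continuous endpoint**: analyses after every 25 / 50 / 125 / 250
  enrollments for maximum sample sizes 100 / 200 / 500 / 1000, the last being
  the final analysis.
- **Binary endpoint**: the enrollment stream is monitored participant by
  participant; an interim fires when at least 10 / 20 / 50 / 100 new events
  have accumulated since the last analysis, and the final analysis always runs
  at full enrollment.
- **Time-to-event**: interims fire at the calendar times where cumulative new
  events since the previous analysis reach 20 / 40 / 100 / 200, strictly
  before the horizon; the final analysis is at calendar time 50 with
  administrative censoring (T = min(latent time, 50 − enrollment time)).
  Snapshots include only participants enrolled by the analysis time.

Stopping at an interim ends enrollment (time-to-event trials stop enrolling
and the stop-time snapshot defines the final data).

## 7. Operating characteristics (`oc.py`, `config.py`)

For each scenario × model cell, replicate trials with seeds derived
independently per replicate (SeedSequence spawning, each reduced below 2³¹ so
results are order-independent and resumable) are aggregated into: rejection
rate (type-1 error under the null, power otherwise), probability of stopping
early and of stopping at the first interim, expected sample size, bias of the
posterior median (plus log-scale bias for ratio estimands), and per-replicate
posterior RMSE, √(meanₛ (γₛ − γ*)²), summarized by its mean and quartiles.
Every rate carries its Monte-Carlo standard error so scaled-down runs remain
interpretable.

Runs are driven by validated YAML/JSON configs (or built-in scenario names)
and write per-model OC tables (CSV), per-analysis trial logs (JSONL), and a
manifest with the config hash and all replicate seeds, making any cell
reproducible in isolation.
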