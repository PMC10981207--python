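# bayesadapt

Simulation and estimation framework for **Bayesian adaptive randomized trials
with early stopping for superiority**, where interim decisions are driven by
posterior probabilities of **marginal** treatment effects obtained from
covariate-adjusted Bayesian outcome models via G-computation.

## The scientific problem

Adjusting for prognostic baseline covariates makes randomized-trial analyses
more efficient, but for non-linear models it changes the question being
answered: the conditional odds ratio or hazard ratio from an adjusted logistic
or proportional-hazards model is *not* the population-averaged (marginal)
effect, and the two do not coincide even without confounding
(non-collapsibility). In an adaptive trial that stops early when the posterior
probability of benefit exceeds a threshold, mixing the two estimands distorts
the design's operating characteristics.

`bayesadapt` keeps the efficiency of covariate adjustment while always making
decisions about the marginal estimand:

1. At each interim analysis a Bayesian outcome model is fit to the enrolled
   snapshot — normal linear (continuous outcomes), logistic (binary), or an
   M-spline proportional-hazards model (time-to-event) — with weakly
   informative, data-autoscaled priors.
2. Each posterior draw of the conditional parameters θₛ is standardized to a
   draw of the marginal arm parameter by averaging conditional predictions
   over the enrolled covariate patterns with Bayesian-bootstrap weights
   (one Dirichlet(1,…,1) weight vector per draw, shared between arms):

   μ(θₛ; A=a) ≈ Σᵢ wᵢₛ · g⁻¹(η(θₛ; a, xᵢ))

3. The per-draw marginal contrast γₛ = f(μ₁ₛ, μ₀ₛ) — difference in means,
   relative risk, odds ratio, or hazard ratio (log-survival ratio at the
   horizon) — yields the decision statistic
   T = P(γ on the beneficial side of the null | data), and superiority is
   declared when T strictly exceeds a threshold u (default 0.99).
4. Frequentist operating characteristics of the whole design — type-1 error,
   power, probability of early stopping, expected sample size, bias, RMSE —
   are estimated by replicated simulation from configurable data-generating
   mechanisms, including a registry-based emergency-department COVID-19 trial
   emulation with 3000 maximum participants.

## Running the tests

```bash
python -m pytest -q tests/
```

The suite includes unit tests, hypothesis property tests, quadrature and
conjugate-posterior oracles, and acceptance tests that re-simulate scaled-down
operating-characteristics studies (the full run takes about 5–10 minutes on
one CPU; everything except `tests/test_acceptance.py::test_criterion_5_*`
finishes in about two minutes).

## Worked example: one adaptive trial

```python
from bayesadapt import builtin_scenarios, model_variants, run_trial
from bayesadapt.models import SamplerConfig

scenario = builtin_scenarios()["continuous_ss100_eff3"]   # max n = 100, true effect -0.73
model = model_variants(scenario)["correct"]               # adjusts for X1, X2, X3, X3^2, X5

result = run_trial(
    scenario.dgm, model, scenario.schedule, scenario.kind, scenario.u,
    seed=11, sampler=SamplerConfig(chains=3, draws=1000),
)
print(f"stopped early   : {result.stopped_early}")
print(f"superiority     : {result.declared}")
print(f"n enrolled      : {result.n_enrolled}")
print(f"posterior median: {result.gamma_median:.3f}")
for a in result.analyses:
    print(f"  analysis {a.index}: n={a.n_t:3d}  T={a.T:.4f}  superior={a.superior}")
```

Output:

```
stopped early   : True
superiority     : True
n enrolled      : 50
posterior median: -1.029
  analysis 1: n= 25  T=0.9577  superior=False
  analysis 2: n= 50  T=0.9997  superior=True
```

The trial analyzed after every 25 enrollments and stopped at the second
interim, enrolling 50 of a possible 100 participants.

## Command-line interface

```bash
# one synthetic dataset from a built-in scenario
bayesadapt simulate-data --scenario binary_ss100_eff2 --n 100 --seed 1 --out data.csv

# replicate study from a YAML config (CSV OC table + JSONL trial logs + manifest)
bayesadapt run-scenario --config configs/continuous_ss100_scaled.yaml --out runs/demo

# or directly from a built-in scenario name
bayesadapt run-scenario --builtin ccedrrn_eff3 --models correct --replicates 100 \
    --seed 1 --scaled --out runs/ccedrrn

# concatenate OC tables from one or more runs
bayesadapt summarize --indir runs --out oc_all.csv

# re-simulate a whole endpoint's OC table at reduced fidelity
bayesadapt reproduce-table 2 --scaled --max-ss 100 --models correct,unadjusted \
    --replicates 400 --seed 1 --out runs/table2
```

Built-in scenarios follow the naming scheme
`{continuous|binary|tte}_ss{100|200|500|1000}_{null|eff2|eff3}` plus
`ccedrrn_{null|eff2|eff3}` for the COVID-19 application; adjustment models are
`correct`, `no_quad`, `correct_noise`, `correct_prior`,
`correct_strong_prior`, and `unadjusted`.

## Repository layout

```
src/bayesadapt/
  dgm.py         data-generating mechanisms (continuous / binary / time-to-event)
  estimands.py   marginal estimand definitions and null values
  splines.py     M-/I-spline bases for the baseline hazard
  models.py      Bayesian outcome models, autoscaled priors, posterior samplers
  gcomp.py       Bayesian-bootstrap standardization and the decision statistic
  sequential.py  single-trial engine (accrual, interim analyses, stopping)
  oc.py          operating-characteristics aggregation with MC standard errors
  scenarios.py   built-in scenario grid and the CCEDRRN application
  config.py      YAML/JSON run configs, orchestration, reproducibility manifests
  cli.py         command-line interface
docs/methods.md  methods note (estimands, standardization, samplers, schedules)
scripts/acceptance.py  recompute all headline targets
tests/           unit, property, oracle, and acceptance tests
```

See `docs/methods.md` for the precise model, prior, and scheduling
conventions.
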