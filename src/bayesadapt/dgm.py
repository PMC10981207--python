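"""Synthetic trial populations and outcomes for three endpoint families.

The data-generating mechanisms (DGMs) emulate two-arm superiority trials with
simple 1:1 randomization, jointly independent baseline covariates, and a
generalized-linear latent structure

    eta = beta0 + phi * A + sum_j beta_j * term_j(x),

where terms may include a squared covariate. Endpoints:

* ``continuous``  Y ~ Normal(eta, residual_sd^2), observed at enrollment.
* ``binary``      Y ~ Bernoulli(expit(eta)), observed at enrollment; the
  intercept is calibrated so the *marginal* control-arm risk hits a target.
* ``tte``         latent event time ~ Exponential(lambda * exp(eta - beta0))
  under proportional hazards (the intercept is absorbed by the baseline rate),
  with administrative right-censoring at a calendar horizon.

Covariate laws supported: Bernoulli(p), standard normal, and a truncated
normal parameterized by *post-truncation* min/max/quartiles/mean/SD, as used
to emulate registry summary statistics (age, respiratory rate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from bayesadapt.estimands import EstimandKind

__all__ = [
    "TruncatedNormalSpec",
    "CovariateSpec",
    "DGMSpec",
    "solve_truncated_normal",
    "sample_truncated_normal",
    "calibrate_intercept",
    "sample_population",
    "latent_event_times",
    "simulate_outcomes",
    "true_marginal_estimand",
]


@dataclass(frozen=True)
class TruncatedNormalSpec:
    """Truncated normal law described by post-truncation summary statistics.

    ``lower``/``upper`` are the support bounds (observed min/max), ``mean`` and
    ``sd`` the post-truncation moments.  ``q1``/``q3`` are the quartiles; they
    over-determine the two free parameters of the underlying normal, so the
    solver matches mean/SD and the quartiles serve only as validation data.
    """

    lower: float
    upper: float
    q1: float
    q3: float
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not (self.lower < self.q1 < self.q3 < self.upper):
            raise ValueError(
                "require lower < q1 < q3 < upper, got "
                f"{self.lower}, {self.q1}, {self.q3}, {self.upper}"
            )
        if self.sd <= 0:
            raise ValueError(f"sd must be positive, got {self.sd}")
        if not (self.lower <= self.mean <= self.upper):
            raise ValueError("mean must lie within [lower, upper]")


@dataclass(frozen=True)
class CovariateSpec:
    """One baseline covariate: its name, law, and whether it drives the outcome.

    ``law`` is one of ``("bernoulli", p)``, ``("standard_normal",)`` or
    ``("truncated_normal", TruncatedNormalSpec)``.  ``role="noise"`` covariates
    are generated but never enter the DGM's linear predictor.
    """

    name: str
    law: tuple
    role: str = "signal"

    def __post_init__(self) -> None:
        kind = self.law[0]
        if kind == "bernoulli":
            p = self.law[1]
            if not 0 < p < 1:
                raise ValueError(f"bernoulli p must be in (0,1), got {p}")
        elif kind == "standard_normal":
            pass
        elif kind == "truncated_normal":
            if not isinstance(self.law[1], TruncatedNormalSpec):
                raise ValueError("truncated_normal law needs a TruncatedNormalSpec")
        else:
            raise ValueError(f"unknown covariate law {kind!r}")
        if self.role not in ("signal", "noise"):
            raise ValueError(f"role must be 'signal' or 'noise', got {self.role!r}")


@dataclass
class DGMSpec:
    """Complete generative description of one trial scenario.

    ``terms`` maps linear-predictor terms to their conditional coefficients.
    A term is a covariate name (``"X3"``) or a squared covariate (``"X3^2"``).
    ``phi`` is the conditional treatment effect on the linear-predictor scale.
    """

    endpoint: str  # "continuous" | "binary" | "tte"
    covariates: list[CovariateSpec]
    phi: float
    terms: dict[str, float] = field(default_factory=dict)
    beta0: float = 0.0
    residual_sd: float = 1.0  # continuous only
    baseline_rate: float | None = None  # tte only: exponential hazard rate
    target_control_risk: float | None = None  # binary only
    max_ss: int = 100

    def __post_init__(self) -> None:
        if self.endpoint not in ("continuous", "binary", "tte"):
            raise ValueError(f"unknown endpoint {self.endpoint!r}")
        if self.endpoint == "tte" and (self.baseline_rate is None or self.baseline_rate <= 0):
            raise ValueError("tte endpoint requires baseline_rate > 0")
        if self.endpoint == "continuous" and self.residual_sd <= 0:
            raise ValueError("continuous endpoint requires residual_sd > 0")
        if self.target_control_risk is not None and not 0 < self.target_control_risk < 1:
            raise ValueError("target_control_risk must be in (0,1)")
        if self.max_ss <= 0:
            raise ValueError("max_ss must be positive")
        names = {c.name for c in self.covariates}
        noise = {c.name for c in self.covariates if c.role == "noise"}
        for term in self.terms:
            base = term.split("^")[0]
            if base not in names:
                raise ValueError(f"term {term!r} references unknown covariate {base!r}")
            if base in noise:
                raise ValueError(f"noise covariate {base!r} cannot enter the linear predictor")

    @property
    def covariate_names(self) -> list[str]:
        return [c.name for c in self.covariates]


# ---------------------------------------------------------------------------
# Truncated normal with post-truncation moment constraints
# ---------------------------------------------------------------------------


def _truncnorm_frozen(mu: float, sigma: float, lower: float, upper: float):
    a = (lower - mu) / sigma
    b = (upper - mu) / sigma
    return stats.truncnorm(a, b, loc=mu, scale=sigma)


def solve_truncated_normal(spec: TruncatedNormalSpec) -> tuple[float, float]:
    """Find the pre-truncation (mu, sigma) whose truncation to [lower, upper]
    has the requested post-truncation mean and SD.

    The quartiles in ``spec`` are not used as constraints (four constraints
    would over-determine two parameters); callers may check them empirically.

    Raises ``ValueError`` when no underlying normal can achieve the moments —
    e.g. when the requested SD exceeds what any unimodal law on the interval
    supports (the uniform limit SD, (upper-lower)/sqrt(12)).
    """
    width = spec.upper - spec.lower
    sd_sup = width / math.sqrt(12.0)
    if spec.sd >= sd_sup:
        raise ValueError(
            f"infeasible spec: requested sd {spec.sd} >= uniform-limit sd "
            f"{sd_sup:.4g} on [{spec.lower}, {spec.upper}]"
        )

    def residual(params: np.ndarray) -> np.ndarray:
        mu, log_sigma = params
        sigma = math.exp(log_sigma)
        m, v = _truncnorm_frozen(mu, sigma, spec.lower, spec.upper).stats(moments="mv")
        return np.array([float(m) - spec.mean, math.sqrt(float(v)) - spec.sd])

    x0 = np.array([spec.mean, math.log(spec.sd)])
    sol = optimize.root(residual, x0, method="hybr", tol=1e-12)
    if not sol.success or np.max(np.abs(sol.fun)) > 1e-6:
        raise ValueError(
            "infeasible spec: root finder could not match post-truncation "
            f"mean/SD (residual {sol.fun}, last iterate {sol.x})"
        )
    return float(sol.x[0]), float(math.exp(sol.x[1]))


def sample_truncated_normal(
    spec: TruncatedNormalSpec, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw ``n`` values from the truncated normal matching ``spec``'s moments."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    mu, sigma = solve_truncated_normal(spec)
    frozen = _truncnorm_frozen(mu, sigma, spec.lower, spec.upper)
    return frozen.rvs(size=n, random_state=rng)


# ---------------------------------------------------------------------------
# Populations, linear predictors, outcomes
# ---------------------------------------------------------------------------


def _sample_covariate(cov: CovariateSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    kind = cov.law[0]
    if kind == "bernoulli":
        return rng.binomial(1, cov.law[1], size=n).astype(float)
    if kind == "standard_normal":
        return rng.standard_normal(n)
    return sample_truncated_normal(cov.law[1], n, rng)


def sample_covariates(
    dgm: DGMSpec, n: int, seed: int | np.random.Generator
) -> pd.DataFrame:
    """Draw ``n`` jointly independent baseline covariate rows."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame({c.name: _sample_covariate(c, n, rng) for c in dgm.covariates})


def eval_terms(terms: dict[str, float], x: pd.DataFrame) -> np.ndarray:
    """Evaluate sum_j beta_j * term_j(x) for term names like 'X3' or 'X3^2'."""
    out = np.zeros(len(x))
    for term, coef in terms.items():
        if term.endswith("^2"):
            out += coef * np.asarray(x[term[:-2]], dtype=float) ** 2
        else:
            out += coef * np.asarray(x[term], dtype=float)
    return out


def linear_predictor(dgm: DGMSpec, x: pd.DataFrame, a: np.ndarray | float) -> np.ndarray:
    """eta = beta0 + phi*A + covariate terms, on the linear-predictor scale."""
    return dgm.beta0 + dgm.phi * np.asarray(a, dtype=float) + eval_terms(dgm.terms, x)


def sample_population(
    dgm: DGMSpec,
    n: int,
    accrual: str | tuple = "instant",
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Generate a trial population: enrollment times, 1:1 randomization, covariates.

    ``accrual`` is ``"instant"`` (all enrollment times 0) or ``("uniform", t_acc)``
    for uniform accrual on [0, t_acc].  Treatment is assigned Bernoulli(0.5)
    independently of all covariates; rows are ordered by enrollment time.
    """
    if n > dgm.max_ss:
        raise ValueError(f"n={n} exceeds max_ss={dgm.max_ss}")
    rng = np.random.default_rng(seed)
    if accrual == "instant":
        enroll = np.zeros(n)
    else:
        mode, t_acc = accrual
        if mode != "uniform":
            raise ValueError(f"unknown accrual mode {accrual!r}")
        enroll = np.sort(rng.uniform(0.0, t_acc, size=n))
    a = rng.binomial(1, 0.5, size=n).astype(int)
    x = sample_covariates(dgm, n, rng)
    pop = pd.DataFrame({"id": np.arange(n), "enroll_time": enroll, "A": a})
    pop = pd.concat([pop, x], axis=1)
    pop["eta"] = linear_predictor(dgm, x, a)
    return pop


def latent_event_times(
    dgm: DGMSpec, pop: pd.DataFrame, seed: int | np.random.Generator
) -> np.ndarray:
    """Uncensored event times T ~ Exponential(rate = lambda * exp(eta - beta0)).

    The DGM intercept is excluded from the hazard: under proportional hazards
    it is absorbed by the baseline rate.  Drawn by inverse transform.
    """
    if dgm.endpoint != "tte":
        raise ValueError("latent event times are defined for the tte endpoint only")
    rng = np.random.default_rng(seed)
    rate = dgm.baseline_rate * np.exp(pop["eta"].to_numpy() - dgm.beta0)
    u = rng.uniform(size=len(pop))
    return -np.log1p(-u) / rate


def simulate_outcomes(
    dgm: DGMSpec,
    pop: pd.DataFrame,
    horizon: float | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate outcomes for a population.

    Continuous/binary: returns ``pop`` with a ``Y`` column (``horizon`` must be
    None; outcomes are observed at enrollment).  TTE: ``horizon`` (calendar
    time) is required; returns columns ``T`` (observed or censored time since
    enrollment), ``delta`` (1 = event observed) and ``event_time_latent``.
    """
    rng = np.random.default_rng(seed)
    eta = pop["eta"].to_numpy()
    out = pop.copy()
    if dgm.endpoint == "continuous":
        if horizon is not None:
            raise ValueError("horizon is only meaningful for the tte endpoint")
        out["Y"] = eta + dgm.residual_sd * rng.standard_normal(len(pop))
        return out
    if dgm.endpoint == "binary":
        if horizon is not None:
            raise ValueError("horizon is only meaningful for the tte endpoint")
        out["Y"] = rng.binomial(1, special.expit(eta)).astype(int)
        return out
    if horizon is None:
        raise ValueError("tte endpoint requires a censoring horizon")
    latent = latent_event_times(dgm, pop, rng)
    follow_up = horizon - pop["enroll_time"].to_numpy()
    if np.any(follow_up < 0):
        raise ValueError("horizon precedes some enrollment times")
    observed = latent <= follow_up
    out["event_time_latent"] = latent
    out["T"] = np.where(observed, latent, follow_up)
    out["delta"] = observed.astype(int)
    return out


# ---------------------------------------------------------------------------
# Intercept calibration and true marginal estimands
# ---------------------------------------------------------------------------


def calibrate_intercept(
    dgm: DGMSpec,
    target_risk: float | None = None,
    mc_n: int = 1_000_000,
    tol: float = 1e-3,
    seed: int | np.random.Generator = 0,
    bracket: tuple[float, float] = (-15.0, 5.0),
) -> float:
    """Solve for the logistic intercept giving a target *marginal* control risk.

    A single covariate sample of size ``mc_n`` is drawn once (common random
    numbers), making the Monte-Carlo objective
    ``mean(expit(beta0 + covariate terms)) - target`` deterministic in beta0;
    the root is then found by bisection-type solving on the bracket.
    """
    if dgm.endpoint != "binary":
        raise ValueError("intercept calibration applies to the binary endpoint")
    if target_risk is None:
        target_risk = dgm.target_control_risk
    if target_risk is None or not 0 < target_risk < 1:
        raise ValueError("target_risk must be in (0,1)")
    x = sample_covariates(dgm, mc_n, seed)
    lin = eval_terms(dgm.terms, x)

    def objective(beta0: float) -> float:
        return float(np.mean(special.expit(beta0 + lin))) - target_risk

    lo, hi = bracket
    f_lo, f_hi = objective(lo), objective(hi)
    if f_lo * f_hi > 0:
        raise ValueError(
            f"root finder bracket [{lo}, {hi}] does not straddle the target "
            f"(objective {f_lo:.4g} .. {f_hi:.4g})"
        )
    beta0 = optimize.brentq(objective, lo, hi, xtol=1e-8, maxiter=200)
    achieved = objective(beta0) + target_risk
    if abs(achieved - target_risk) > tol:
        raise ValueError(
            f"calibration did not converge: achieved risk {achieved:.5f} vs "
            f"target {target_risk} (last bracket [{lo}, {hi}])"
        )
    return float(beta0)


def true_marginal_estimand(
    dgm: DGMSpec,
    estimand: EstimandKind,
    mc_n: int = 1_000_000,
    seed: int | np.random.Generator = 0,
    eval_time: float = 50.0,
) -> float:
    """Monte-Carlo value of the marginal estimand implied by the DGM.

    Averages the conditional arm parameter over the covariate law at each arm
    and forms the contrast.  For the identity link without treatment-covariate
    interactions the difference in means is collapsible and equals ``phi``
    exactly, so no simulation is used.  The hazard ratio contrasts marginal
    survival probabilities at ``eval_time`` (default: the trial horizon).
    """
    if estimand is EstimandKind.DIFF_MEANS:
        # Collapsible: E[eta | A=1] - E[eta | A=0] = phi for any covariate law.
        return float(dgm.phi)
    x = sample_covariates(dgm, mc_n, seed)
    lin = dgm.beta0 + eval_terms(dgm.terms, x)
    if dgm.endpoint == "binary":
        mu1 = float(np.mean(special.expit(lin + dgm.phi)))
        mu0 = float(np.mean(special.expit(lin)))
        if estimand is EstimandKind.RELATIVE_RISK:
            return mu1 / mu0
        if estimand is EstimandKind.ODDS_RATIO:
            return (mu1 / (1 - mu1)) / (mu0 / (1 - mu0))
        raise ValueError(f"{estimand} is not defined for a binary endpoint")
    if dgm.endpoint == "tte":
        if estimand is not EstimandKind.HAZARD_RATIO:
            raise ValueError(f"{estimand} is not defined for a tte endpoint")
        cum_haz0 = dgm.baseline_rate * eval_time * np.exp(lin - dgm.beta0)
        s1 = float(np.mean(np.exp(-cum_haz0 * math.exp(dgm.phi))))
        s0 = float(np.mean(np.exp(-cum_haz0)))
        return math.log(s1) / math.log(s0)
    raise ValueError(f"no ratio estimand is defined for endpoint {dgm.endpoint!r}")
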