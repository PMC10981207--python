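"""Bayesian-bootstrap-weighted standardization of posterior draws.

Adjusted outcome models deliver posterior draws of *conditional* parameters.
Each draw is converted into a draw of the *marginal* arm parameter by
averaging conditional predictions over the enrolled participants' covariate
patterns with Dirichlet(1, ..., 1) weights (the Bayesian bootstrap), which
propagates uncertainty about the covariate law:

    mu(theta_s; A=a) ~= sum_i w_{i,s} * g^{-1}(eta(theta_s; a, x_i))

One independent weight vector is drawn per posterior draw and shared between
the two arms within a draw, since both arm averages integrate over the same
empirical covariate distribution.  The marginal estimand gamma_s = f(mu_1s,
mu_0s) then feeds the trial's decision statistic T = P(gamma on the
alternative side of the null | data), with superiority declared when T
strictly exceeds the threshold u.

Unadjusted models (treatment-only) are a special case: the marginal parameter
is a direct transform of (intercept, treatment) draws and no weighting is
involved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from bayesadapt.estimands import EstimandKind
from bayesadapt.models import PosteriorDraws, design_matrix
from bayesadapt.splines import ispline_basis

__all__ = [
    "EstimandKind",
    "MarginalSamples",
    "DecisionStatistic",
    "bootstrap_weights",
    "marginalize",
    "contrast",
    "decision_statistic",
]


@dataclass
class MarginalSamples:
    """Per-draw marginal arm parameters mu(theta_s; A=a).

    For the normal family these are arm means, for the logistic family arm
    risks, and for the PH family marginal survival probabilities at ``time``.
    """

    mu1: np.ndarray
    mu0: np.ndarray
    family: str
    time: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mu1": self.mu1, "mu0": self.mu0})


@dataclass
class DecisionStatistic:
    T: float
    u: float
    superior: bool


def bootstrap_weights(
    n_t: int, S: int, seed: int | np.random.Generator
) -> np.ndarray:
    """S independent Dirichlet(1_{n_t}) weight vectors, one per posterior draw.

    Returns an (S, n_t) matrix with unit row sums; each weight has marginal
    expectation 1/n_t.
    """
    if n_t < 1 or S < 1:
        raise ValueError("n_t and S must be >= 1")
    rng = np.random.default_rng(seed)
    g = rng.standard_gamma(1.0, size=(S, n_t))
    return g / g.sum(axis=1, keepdims=True)


def _arm_response(
    draws: PosteriorDraws, rows: pd.DataFrame, arm: float, time: float | None
) -> np.ndarray:
    """Conditional responses g^{-1}(eta) for every (participant, draw) pair.

    Shape (n_t, S).  For the PH family the response is the conditional
    survival probability at ``time``.
    """
    X = design_matrix(draws.terms, rows, a_override=arm)
    eta = draws.coefs[:, 0] + X @ draws.coefs[:, 1:].T  # n x S
    if draws.family == "normal":
        return eta
    if draws.family == "bernoulli_logit":
        return special.expit(eta)
    if time is None:
        raise ValueError("the PH family requires an evaluation time")
    i_vec = ispline_basis(np.array([time]), draws.spline)[0]  # (L,)
    cum0 = draws.psi @ i_vec  # (S,) baseline cumulative hazard shape at t
    return np.exp(-cum0 * np.exp(eta))


def marginalize(
    draws: PosteriorDraws,
    covariate_rows: pd.DataFrame | None,
    weights: np.ndarray | None = None,
    time: float | None = None,
    seed: int | np.random.Generator | None = None,
) -> MarginalSamples:
    """Standardize posterior draws to marginal arm parameters.

    ``covariate_rows`` are the enrolled participants' covariates at the
    analysis (the adjustment snapshot).  ``weights`` is an (S, n_t) Bayesian
    bootstrap matrix; if omitted it is drawn fresh using ``seed``.  For an
    unadjusted model the marginal parameter is transformed directly from the
    (intercept, treatment) draws and neither rows nor weights are needed.
    """
    if draws.family == "ph_mspline" and time is None:
        raise ValueError("marginal survival for the PH family needs a time point")
    if tuple(draws.terms) == ("A",):
        dummy = pd.DataFrame({"A": [0.0]})
        mu1 = _arm_response(draws, dummy, 1.0, time)[0]
        mu0 = _arm_response(draws, dummy, 0.0, time)[0]
        return MarginalSamples(mu1=mu1, mu0=mu0, family=draws.family, time=time)
    if covariate_rows is None:
        raise ValueError("adjusted models need the analysis covariate rows")
    n_t = len(covariate_rows)
    S = draws.n_draws
    if weights is None:
        if seed is None:
            raise ValueError("provide either a weight matrix or a seed to draw one")
        weights = bootstrap_weights(n_t, S, seed)
    if weights.shape != (S, n_t):
        raise ValueError(f"weights must have shape {(S, n_t)}, got {weights.shape}")
    resp1 = _arm_response(draws, covariate_rows, 1.0, time)
    resp0 = _arm_response(draws, covariate_rows, 0.0, time)
    mu1 = np.einsum("sn,ns->s", weights, resp1)
    mu0 = np.einsum("sn,ns->s", weights, resp0)
    return MarginalSamples(mu1=mu1, mu0=mu0, family=draws.family, time=time)


def contrast(marg: MarginalSamples, kind: EstimandKind) -> np.ndarray:
    """Per-draw marginal estimand gamma_s = f(mu_1s, mu_0s)."""
    mu1, mu0 = marg.mu1, marg.mu0
    if kind is EstimandKind.DIFF_MEANS:
        return mu1 - mu0
    if kind is EstimandKind.RELATIVE_RISK:
        if np.any(mu0 <= 0):
            bad = int(np.argmax(mu0 <= 0))
            raise ValueError(f"zero control risk in draw {bad}: relative risk undefined")
        return mu1 / mu0
    if kind is EstimandKind.ODDS_RATIO:
        if np.any((mu0 <= 0) | (mu0 >= 1) | (mu1 >= 1)):
            bad = int(np.argmax((mu0 <= 0) | (mu0 >= 1) | (mu1 >= 1)))
            raise ValueError(f"degenerate risk in draw {bad}: odds ratio undefined")
        return (mu1 / (1 - mu1)) / (mu0 / (1 - mu0))
    # hazard ratio: log-survival ratio at the evaluation time
    if np.any((mu0 >= 1) | (mu1 >= 1) | (mu0 <= 0) | (mu1 <= 0)):
        bad = int(np.argmax((mu0 >= 1) | (mu1 >= 1) | (mu0 <= 0) | (mu1 <= 0)))
        raise ValueError(f"survival probability outside (0,1) in draw {bad}")
    return np.log(mu1) / np.log(mu0)


def decision_statistic(
    gamma: np.ndarray, kind: EstimandKind, u: float
) -> DecisionStatistic:
    """T = posterior probability that gamma lies on the alternative side of
    its null value; superiority requires strictly T > u."""
    if len(gamma) < 2:
        raise ValueError("need at least two posterior draws")
    T = float(np.mean(gamma < kind.null_value))
    return DecisionStatistic(T=T, u=u, superior=T > u)
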