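"""Bayesian outcome models returning exchangeable posterior draws.

Three likelihood families are supported, matching the endpoint types:

* ``normal``           linear model with residual SD sigma,
* ``bernoulli_logit``  logistic regression,
* ``ph_mspline``       proportional hazards with an M-spline baseline hazard
                       (simplex-constrained basis coefficients and a log-scale
                       intercept absorbed into the baseline).

Priors follow the autoscaling convention of weakly informative GLM defaults:
after internal centering of all predictor columns, the intercept gets
Normal(ybar, 2.5*s_y), slopes Normal(0, 2.5*s_y/s_x), the treatment coefficient
Normal(0, 2.5*s_y/s_a), and sigma an Exponential(1/s_y) prior; binary and
time-to-event families use ybar=0, s_y=1.  ``centered`` mode relocates the
covariate (never the treatment) priors to supplied centers; ``strong`` mode
additionally tightens their scale to s_y/s_x.

Sampling backends (the posterior, not the sampler, drives the design's
operating characteristics, so any method delivering exchangeable draws is
valid):

* normal family — *exact i.i.d. draws*: the coefficient block is integrated
  out analytically, sigma is drawn from its marginal posterior on a fine grid
  by inverse-CDF, and coefficients are then drawn from their exact Gaussian
  conditional.
* logistic and PH families — Laplace approximation at the posterior mode with
  a multivariate-t proposal, corrected by sampling-importance-resampling (SIR)
  so the retained draws target the exact posterior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special

from bayesadapt.splines import SplineConfig, default_knots, ispline_basis, mspline_basis

__all__ = [
    "ModelSpec",
    "ResolvedPriors",
    "SamplerConfig",
    "PosteriorDraws",
    "ConvergenceReport",
    "design_matrix",
    "resolve_priors",
    "log_likelihood",
    "fit_posterior",
]

RHAT_THRESHOLD = 1.05


@dataclass(frozen=True)
class ModelSpec:
    """An analysis model: family, predictor terms, and prior scheme.

    ``terms`` always includes ``"A"``; covariate terms may be raw names,
    squares (``"X3^2"``) or treatment interactions (``"A:X1"``).
    ``prior_mode`` is ``weak``, ``centered`` or ``strong``; the latter two need
    ``prior_centers`` for every non-treatment term.
    """

    family: str  # "normal" | "bernoulli_logit" | "ph_mspline"
    terms: tuple[str, ...]
    prior_mode: str = "weak"
    prior_centers: dict[str, float] | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.family not in ("normal", "bernoulli_logit", "ph_mspline"):
            raise ValueError(f"unknown family {self.family!r}")
        if "A" not in self.terms:
            raise ValueError("the treatment indicator 'A' must be a model term")
        if self.prior_mode not in ("weak", "centered", "strong"):
            raise ValueError(f"unknown prior_mode {self.prior_mode!r}")
        if self.prior_mode != "weak":
            centers = self.prior_centers or {}
            missing = [t for t in self.terms if t != "A" and t not in centers]
            if missing:
                raise ValueError(f"prior_centers missing for terms {missing}")

    @property
    def is_unadjusted(self) -> bool:
        return tuple(self.terms) == ("A",)


@dataclass
class ResolvedPriors:
    """Data-dependent (autoscaled) normal priors, on the centered scale."""

    intercept_loc: float
    intercept_scale: float
    locs: np.ndarray  # per term, order of ModelSpec.terms
    scales: np.ndarray
    sigma_rate: float | None  # normal family only: Exponential rate 1/s_y
    s_y: float
    ybar: float
    s_x: dict[str, float]
    column_means: np.ndarray  # centering offsets per term


@dataclass
class SamplerConfig:
    """Monte Carlo settings: ``chains * draws`` retained posterior samples."""

    chains: int = 3
    draws: int = 1000
    oversample: int = 4  # SIR proposal pool = oversample * S
    prior_only: bool = False
    sigma_fixed: float | None = None  # normal family: hold sigma at this value
    proposal_df: float = 7.0

    @property
    def total_draws(self) -> int:
        return self.chains * self.draws


@dataclass
class ConvergenceReport:
    rhat: dict[str, float]
    passed: bool
    ess_fraction: float | None = None  # SIR importance effective sample fraction

    def max_rhat(self) -> float:
        return max(self.rhat.values()) if self.rhat else 1.0


@dataclass
class PosteriorDraws:
    """S exchangeable posterior draws of the model parameters.

    ``coefs`` has the intercept in column 0 followed by ``terms`` in order,
    on the original (uncentered) predictor scale.  ``sigma`` (normal) or
    ``psi`` + ``spline`` (ph_mspline) hold the nuisance block.
    """

    terms: tuple[str, ...]
    family: str
    coefs: np.ndarray  # S x (1 + len(terms))
    chain: np.ndarray  # S, chain index per draw
    sigma: np.ndarray | None = None  # S, normal family
    psi: np.ndarray | None = None  # S x L, ph_mspline family
    spline: SplineConfig | None = None

    @property
    def n_draws(self) -> int:
        return self.coefs.shape[0]

    @property
    def param_names(self) -> list[str]:
        names = ["intercept", *self.terms]
        if self.sigma is not None:
            names.append("sigma")
        if self.psi is not None:
            names += [f"psi[{l}]" for l in range(self.psi.shape[1])]
        return names

    def to_frame(self) -> pd.DataFrame:
        cols = {"chain": self.chain, "intercept": self.coefs[:, 0]}
        for j, t in enumerate(self.terms):
            cols[t] = self.coefs[:, j + 1]
        if self.sigma is not None:
            cols["sigma"] = self.sigma
        if self.psi is not None:
            for l in range(self.psi.shape[1]):
                cols[f"psi[{l}]"] = self.psi[:, l]
        return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# Design matrices and priors
# ---------------------------------------------------------------------------


def _term_column(term: str, data: pd.DataFrame, a_override: float | None = None) -> np.ndarray:
    def base(name: str) -> np.ndarray:
        if name == "A" and a_override is not None:
            return np.full(len(data), float(a_override))
        return np.asarray(data[name], dtype=float)

    if ":" in term:
        left, right = term.split(":")
        return _term_column(left, data, a_override) * _term_column(right, data, a_override)
    if term.endswith("^2"):
        return base(term[:-2]) ** 2
    return base(term)


def design_matrix(
    terms: tuple[str, ...] | list[str],
    data: pd.DataFrame,
    a_override: float | None = None,
) -> np.ndarray:
    """Columns for each model term (no intercept column).

    ``a_override`` replaces the treatment indicator by a constant, switching
    interaction terms with it — used when standardizing to a fixed arm.
    """
    return np.column_stack([_term_column(t, data, a_override) for t in terms])


def resolve_priors(spec: ModelSpec, data: pd.DataFrame) -> ResolvedPriors:
    """Autoscale the prior scheme to the analysis sample.

    Deterministic given the data.  Raises on zero-variance predictor columns
    (autoscaling would divide by zero).
    """
    if len(data) == 0:
        raise ValueError("cannot resolve priors on an empty dataset")
    X = design_matrix(spec.terms, data)
    if spec.family == "normal":
        y = np.asarray(data["Y"], dtype=float)
        ybar, s_y = float(np.mean(y)), float(np.std(y, ddof=1))
        if s_y == 0:
            raise ValueError("outcome Y has zero variance")
        sigma_rate = 1.0 / s_y
    else:
        ybar, s_y, sigma_rate = 0.0, 1.0, None
    s_x: dict[str, float] = {}
    locs = np.zeros(len(spec.terms))
    scales = np.zeros(len(spec.terms))
    centers = spec.prior_centers or {}
    for j, term in enumerate(spec.terms):
        sd = float(np.std(X[:, j], ddof=1))
        if sd == 0:
            raise ValueError(f"predictor column {term!r} has zero variance")
        s_x[term] = sd
        if term == "A" or spec.prior_mode == "weak":
            locs[j] = 0.0
            scales[j] = 2.5 * s_y / sd
        elif spec.prior_mode == "centered":
            locs[j] = centers[term]
            scales[j] = 2.5 * s_y / sd
        else:  # strong
            locs[j] = centers[term]
            scales[j] = s_y / sd
    return ResolvedPriors(
        intercept_loc=ybar,
        intercept_scale=2.5 * s_y,
        locs=locs,
        scales=scales,
        sigma_rate=sigma_rate,
        s_y=s_y,
        ybar=ybar,
        s_x=s_x,
        column_means=X.mean(axis=0),
    )


# ---------------------------------------------------------------------------
# Log likelihoods (uncentered scale)
# ---------------------------------------------------------------------------


def log_likelihood(
    spec: ModelSpec,
    theta: dict,
    data: pd.DataFrame,
    spline: SplineConfig | None = None,
) -> float:
    """Sum of per-participant log densities for parameter point ``theta``.

    ``theta["beta"]`` holds the intercept followed by the model terms; the
    normal family additionally needs ``theta["sigma"] > 0`` and the PH family
    ``theta["psi"]`` on the simplex together with a ``spline`` basis.
    """
    beta = np.asarray(theta["beta"], dtype=float)
    if beta.shape[0] != 1 + len(spec.terms):
        raise ValueError("theta dimension does not match the model terms")
    X = design_matrix(spec.terms, data)
    eta = beta[0] + X @ beta[1:]
    if spec.family == "normal":
        sigma = float(theta["sigma"])
        if sigma <= 0:
            raise ValueError("sigma must be positive")
        y = np.asarray(data["Y"], dtype=float)
        return float(
            -0.5 * len(y) * math.log(2 * math.pi)
            - len(y) * math.log(sigma)
            - 0.5 * np.sum((y - eta) ** 2) / sigma**2
        )
    if spec.family == "bernoulli_logit":
        y = np.asarray(data["Y"], dtype=float)
        # log p = y*eta - log(1 + exp(eta)), numerically stable via logaddexp
        return float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    psi = np.asarray(theta["psi"], dtype=float)
    if np.any(psi < 0) or abs(psi.sum() - 1.0) > 1e-8:
        raise ValueError("psi must lie on the simplex")
    if spline is None:
        raise ValueError("ph_mspline likelihood needs a spline basis")
    t = np.asarray(data["T"], dtype=float)
    delta = np.asarray(data["delta"], dtype=float)
    m_val = mspline_basis(t, spline) @ psi
    i_val = ispline_basis(t, spline) @ psi
    haz = np.exp(eta)
    with np.errstate(divide="ignore"):
        log_h = np.where(delta > 0, np.log(np.maximum(m_val, 1e-300)) + eta, 0.0)
    return float(np.sum(delta * log_h - i_val * haz))


# ---------------------------------------------------------------------------
# Exact sampler: normal family
# ---------------------------------------------------------------------------


def _sample_normal_exact(
    Xc: np.ndarray,
    y: np.ndarray,
    m0: np.ndarray,
    s0: np.ndarray,
    sigma_rate: float,
    S: int,
    rng: np.random.Generator,
    sigma_fixed: float | None,
) -> tuple[np.ndarray, np.ndarray]:
    """i.i.d. draws of (coefficients, sigma) from the exact posterior.

    The Gaussian coefficient block is integrated out to give the 1-D marginal
    posterior of sigma, which is sampled by inverse-CDF on a log-spaced grid;
    coefficients are then drawn from their conjugate Gaussian conditional.
    """
    n, P = Xc.shape
    if n <= P:
        raise ValueError(f"need more observations ({n}) than parameters ({P})")
    G = Xc * s0
    U, sv, Wt = np.linalg.svd(G, full_matrices=False)
    W = Wt.T
    r = y - Xc @ m0
    z = U.T @ r
    rr_extra = float(r @ r - z @ z)  # residual norm outside the column space

    if sigma_fixed is not None:
        sigmas = np.full(S, float(sigma_fixed))
    else:
        resid = r - U @ z
        base = math.sqrt(max(rr_extra, 1e-12) / max(n - P, 1))
        lo = min(base / 12.0, 1.0 / (sigma_rate * 50))
        hi = max(base * 12.0, 6.0 / sigma_rate)
        grid = np.exp(np.linspace(math.log(max(lo, 1e-8)), math.log(hi), 600))
        g2 = grid[:, None] ** 2
        logdet = (n - P) * 2 * np.log(grid) + np.sum(np.log(g2 + sv**2), axis=1)
        quad = rr_extra / grid**2 + np.sum(z**2 / (g2 + sv**2), axis=1)
        logp = -sigma_rate * grid - 0.5 * logdet - 0.5 * quad
        logp -= logp.max()
        w = np.exp(logp)
        cdf = np.cumsum((w[1:] + w[:-1]) * np.diff(grid))  # trapezoid
        cdf = np.concatenate([[0.0], cdf])
        cdf /= cdf[-1]
        sigmas = np.interp(rng.uniform(size=S), cdf, grid)

    s2 = sigmas[:, None] ** 2
    mean_coord = sv * z / (s2 + sv**2)  # S x P
    sd_coord = 1.0 / np.sqrt(1.0 + sv**2 / s2)
    u = (mean_coord + sd_coord * rng.standard_normal((S, P))) @ W.T
    betas = m0 + s0 * u
    return betas, sigmas


# ---------------------------------------------------------------------------
# Laplace + SIR sampler: logistic and PH families
# ---------------------------------------------------------------------------


def _newton_map(
    f_grad: callable, x0: np.ndarray, hess: callable | None = None, tol: float = 1e-9
) -> np.ndarray:
    """Maximize a log posterior given a (negative) value+gradient callable."""
    res = optimize.minimize(f_grad, x0, jac=True, method="BFGS", options={"maxiter": 500, "gtol": 1e-7})
    # Polish with a second run from the BFGS solution if the gradient is loose.
    if not res.success and np.max(np.abs(res.jac)) > 1e-4:
        res = optimize.minimize(f_grad, res.x, jac=True, method="BFGS", options={"maxiter": 500})
    return res.x


def _fd_hessian(grad: callable, x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Hessian by central differences of an analytic gradient."""
    p = len(x)
    H = np.zeros((p, p))
    for j in range(p):
        step = eps * max(1.0, abs(x[j]))
        xp, xm = x.copy(), x.copy()
        xp[j] += step
        xm[j] -= step
        H[:, j] = (grad(xp) - grad(xm)) / (2 * step)
    return 0.5 * (H + H.T)


def _mvt_draws(
    mean: np.ndarray,
    factor: np.ndarray,
    half_logdet: float,
    df: float,
    K: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Multivariate-t proposal draws and their log densities.

    ``factor`` is any square root of the scale matrix (cov = factor @ factor.T)
    with ``half_logdet = 0.5 * log det(cov)``.
    """
    p = len(mean)
    zn = rng.standard_normal((K, p))
    g = rng.chisquare(df, size=K) / df
    x = mean + (zn @ factor.T) / np.sqrt(g)[:, None]
    delta = np.linalg.solve(factor, (x - mean).T)
    q = np.sum(delta**2, axis=0)
    logpdf = (
        special.gammaln((df + p) / 2)
        - special.gammaln(df / 2)
        - 0.5 * p * math.log(df * math.pi)
        - half_logdet
        - 0.5 * (df + p) * np.log1p(q / df)
    )
    return x, logpdf


def _sir(
    log_target: callable,
    mode: np.ndarray,
    hess: np.ndarray,
    S: int,
    cfg: SamplerConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    """Sampling-importance-resampling around a Laplace approximation."""
    p = len(mode)
    # Robustify the proposal: inflate the Laplace covariance slightly.
    cov = np.linalg.inv(hess)
    cov = 0.5 * (cov + cov.T)
    # Guard small negative eigenvalues from finite differencing.
    evals, evecs = np.linalg.eigh(cov)
    evals = np.maximum(evals, 1e-12) * 1.2**2
    factor = evecs * np.sqrt(evals)
    half_logdet = 0.5 * float(np.sum(np.log(evals)))
    K = cfg.oversample * S
    x, logq = _mvt_draws(mode, factor, half_logdet, cfg.proposal_df, K, rng)
    logw = log_target(x) - logq
    logw -= logw.max()
    w = np.exp(logw)
    w /= w.sum()
    ess = 1.0 / float(np.sum(w**2))
    idx = rng.choice(K, size=S, replace=True, p=w)
    return x[idx], ess / K


def _split_rhat(draws_1d: np.ndarray, chains: int) -> float:
    """Split Gelman-Rubin statistic treating the draw stream as pseudo-chains."""
    S = len(draws_1d)
    n_split = 2 * chains
    m = S // n_split
    if m < 2:
        return 1.0
    x = draws_1d[: m * n_split].reshape(n_split, m)
    means = x.mean(axis=1)
    variances = x.var(axis=1, ddof=1)
    W = variances.mean()
    B = m * means.var(ddof=1)
    if W <= 0:
        return 1.0
    var_hat = (m - 1) / m * W + B / m
    return float(np.sqrt(var_hat / W))


def _report(draws: PosteriorDraws, chains: int, ess_fraction: float | None) -> ConvergenceReport:
    rhat = {}
    names = ["intercept", *draws.terms]
    for j, name in enumerate(names):
        rhat[name] = _split_rhat(draws.coefs[:, j], chains)
    if draws.sigma is not None:
        rhat["sigma"] = _split_rhat(draws.sigma, chains)
    passed = all(v < RHAT_THRESHOLD for v in rhat.values())
    return ConvergenceReport(rhat=rhat, passed=passed, ess_fraction=ess_fraction)


# ---------------------------------------------------------------------------
# fit_posterior
# ---------------------------------------------------------------------------


def fit_posterior(
    spec: ModelSpec,
    data: pd.DataFrame,
    sampler: SamplerConfig | None = None,
    seed: int | np.random.Generator = 0,
    time_upper: float | None = None,
) -> tuple[PosteriorDraws, ConvergenceReport]:
    """Fit the model and return S = chains x draws exchangeable posterior draws.

    ``time_upper`` sets the upper boundary knot of the baseline-hazard spline
    (PH family); it defaults to the largest observed follow-up time.
    """
    cfg = sampler or SamplerConfig()
    rng = np.random.default_rng(seed)
    S = cfg.total_draws
    chain_idx = np.repeat(np.arange(cfg.chains), cfg.draws)[:S]

    if not cfg.prior_only:
        a = np.asarray(data["A"])
        if (a == 1).sum() < 1 or (a == 0).sum() < 1:
            raise ValueError("need at least one participant per arm")

    priors = resolve_priors(spec, data)
    X = design_matrix(spec.terms, data)
    Xc = X - priors.column_means
    m0 = np.concatenate([[priors.intercept_loc], priors.locs])
    s0 = np.concatenate([[priors.intercept_scale], priors.scales])

    def uncenter(betas_c: np.ndarray) -> np.ndarray:
        out = betas_c.copy()
        out[:, 0] = betas_c[:, 0] - betas_c[:, 1:] @ priors.column_means
        return out

    if spec.family == "normal":
        if cfg.prior_only:
            betas_c = m0 + s0 * rng.standard_normal((S, len(m0)))
            sigmas = rng.exponential(1.0 / priors.sigma_rate, size=S)
        else:
            Xd = np.column_stack([np.ones(len(data)), Xc])
            betas_c, sigmas = _sample_normal_exact(
                Xd,
                np.asarray(data["Y"], dtype=float),
                m0,
                s0,
                priors.sigma_rate,
                S,
                rng,
                cfg.sigma_fixed,
            )
        draws = PosteriorDraws(
            terms=spec.terms,
            family=spec.family,
            coefs=uncenter(betas_c),
            chain=chain_idx,
            sigma=sigmas,
        )
        return draws, _report(draws, cfg.chains, None)

    if spec.family == "bernoulli_logit":
        if cfg.prior_only:
            betas_c = m0 + s0 * rng.standard_normal((S, len(m0)))
            draws = PosteriorDraws(spec.terms, spec.family, uncenter(betas_c), chain_idx)
            return draws, _report(draws, cfg.chains, None)
        y = np.asarray(data["Y"], dtype=float)
        Xd = np.column_stack([np.ones(len(data)), Xc])

        def negpost_grad(b: np.ndarray) -> tuple[float, np.ndarray]:
            eta = Xd @ b
            p = special.expit(eta)
            nll = -np.sum(y * eta - np.logaddexp(0.0, eta))
            npr = 0.5 * np.sum(((b - m0) / s0) ** 2)
            grad = Xd.T @ (p - y) + (b - m0) / s0**2
            return nll + npr, grad

        mode = _newton_map(negpost_grad, np.zeros(len(m0)))
        p_hat = special.expit(Xd @ mode)
        hess = Xd.T @ (Xd * (p_hat * (1 - p_hat))[:, None]) + np.diag(1.0 / s0**2)

        def log_target(B: np.ndarray) -> np.ndarray:
            eta = Xd @ B.T  # n x K
            ll = y @ eta - np.logaddexp(0.0, eta).sum(axis=0)
            lp = -0.5 * np.sum(((B - m0) / s0) ** 2, axis=1)
            return ll + lp

        samples, ess_frac = _sir(log_target, mode, hess, S, cfg, rng)
        draws = PosteriorDraws(spec.terms, spec.family, uncenter(samples), chain_idx)
        return draws, _report(draws, cfg.chains, ess_frac)

    # --- ph_mspline ---
    t_obs = np.asarray(data["T"], dtype=float)
    delta = np.asarray(data["delta"], dtype=float)
    if not cfg.prior_only and delta.sum() < 1:
        raise ValueError("PH model requires at least one observed event")
    upper = float(time_upper) if time_upper is not None else float(t_obs.max()) * (1 + 1e-9)
    events = t_obs[delta > 0] if delta.sum() >= 1 else t_obs
    spline = default_knots(events, upper)
    L = spline.size
    Mb = mspline_basis(t_obs, spline)  # n x L
    Ib = ispline_basis(t_obs, spline)

    def softmax_full(xi: np.ndarray) -> np.ndarray:
        z = np.concatenate([xi, [0.0]]) if xi.ndim == 1 else np.pad(xi, ((0, 0), (0, 1)))
        z = z - z.max(axis=-1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=-1, keepdims=True)

    P = len(m0)

    if cfg.prior_only:
        betas_c = m0 + s0 * rng.standard_normal((S, P))
        psi = rng.dirichlet(np.ones(L), size=S)
        draws = PosteriorDraws(
            spec.terms, spec.family, uncenter(betas_c), chain_idx, psi=psi, spline=spline
        )
        return draws, _report(draws, cfg.chains, None)

    Xd = np.column_stack([np.ones(len(data)), Xc])

    def unpack(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return v[:P], v[P:]

    def negpost_grad(v: np.ndarray) -> tuple[float, np.ndarray]:
        b, xi = unpack(v)
        psi = softmax_full(xi)
        eta = Xd @ b
        haz = np.exp(eta)
        m_val = Mb @ psi
        i_val = Ib @ psi
        ll = np.sum(delta * (np.log(np.maximum(m_val, 1e-300)) + eta) - i_val * haz)
        lp_b = -0.5 * np.sum(((b - m0) / s0) ** 2)
        lp_xi = np.sum(np.log(np.maximum(psi, 1e-300)))  # Dirichlet(1) + softmax Jacobian
        # gradient
        g_b = Xd.T @ (delta - i_val * haz) - (b - m0) / s0**2
        g_psi = Mb.T @ (delta / np.maximum(m_val, 1e-300)) - Ib.T @ haz
        g_psi_prior = 1.0 / np.maximum(psi, 1e-300)
        g_psi_tot = g_psi + g_psi_prior
        # chain rule through softmax (reference category last)
        inner = g_psi_tot - np.dot(psi, g_psi_tot)
        g_xi = (psi * inner)[:-1]
        val = -(ll + lp_b + lp_xi)
        return val, -np.concatenate([g_b, g_xi])

    x0 = np.zeros(P + L - 1)
    mode = _newton_map(negpost_grad, x0)
    grad_only = lambda v: negpost_grad(v)[1]
    hess = _fd_hessian(grad_only, mode)

    def log_target(V: np.ndarray) -> np.ndarray:
        B = V[:, :P]
        Xi = V[:, P:]
        psi = softmax_full(Xi)  # K x L
        eta = Xd @ B.T  # n x K
        haz = np.exp(eta)
        m_val = Mb @ psi.T  # n x K
        i_val = Ib @ psi.T
        ll = np.sum(delta[:, None] * (np.log(np.maximum(m_val, 1e-300)) + eta) - i_val * haz, axis=0)
        lp = -0.5 * np.sum(((B - m0) / s0) ** 2, axis=1) + np.sum(
            np.log(np.maximum(psi, 1e-300)), axis=1
        )
        return ll + lp

    samples, ess_frac = _sir(log_target, mode, hess, S, cfg, rng)
    betas_c = samples[:, :P]
    psi = softmax_full(samples[:, P:])
    draws = PosteriorDraws(
        spec.terms, spec.family, uncenter(betas_c), chain_idx, psi=psi, spline=spline
    )
    return draws, _report(draws, cfg.chains, ess_frac)
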