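"""Built-in simulation scenarios: the endpoint x max-ss x effect grid and the
emergency-department COVID-19 (CCEDRRN) application.

Each scenario bundles a data-generating mechanism, its interim schedule, the
marginal estimand and decision threshold, and the tabulated true marginal
effect.  The six named adjustment-model variants (correct, no_quad,
correct_noise, correct_prior, correct_strong_prior, unadjusted) are built per
scenario from the DGM's own coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from bayesadapt.dgm import CovariateSpec, DGMSpec, TruncatedNormalSpec, calibrate_intercept
from bayesadapt.estimands import EstimandKind
from bayesadapt.models import ModelSpec
from bayesadapt.sequential import InterimSchedule

__all__ = ["Scenario", "builtin_scenarios", "model_variants", "MODEL_NAMES"]

CALIBRATION_SEED = 20240901
U_THRESHOLD = 0.99
TTE_ACCRUAL_END = 25.0
TTE_HORIZON = 50.0

MODEL_NAMES = (
    "correct",
    "no_quad",
    "correct_noise",
    "correct_prior",
    "correct_strong_prior",
    "unadjusted",
)

# Interim triggers per max ss: enrollments (continuous) or new events (binary, tte).
ENROLL_TRIGGER = {100: 25, 200: 50, 500: 125, 1000: 250}
BINARY_EVENT_TRIGGER = {100: 10, 200: 20, 500: 50, 1000: 100}
TTE_EVENT_TRIGGER = {100: 20, 200: 40, 500: 100, 1000: 200}

# (gamma, phi) per endpoint and max ss; gamma is the tabulated marginal effect.
CONTINUOUS_EFFECTS = {
    100: [(0.0, 0.0), (-0.52, -0.52), (-0.73, -0.73)],
    200: [(0.0, 0.0), (-0.36, -0.36), (-0.52, -0.52)],
    500: [(0.0, 0.0), (-0.22, -0.22), (-0.32, -0.32)],
    1000: [(0.0, 0.0), (-0.16, -0.16), (-0.22, -0.22)],
}
BINARY_EFFECTS = {
    100: [(1.0, 0.0), (0.53, -0.99), (0.46, -1.21)],
    200: [(1.0, 0.0), (0.59, -0.86), (0.41, -1.36)],
    500: [(1.0, 0.0), (0.72, -0.56), (0.60, -0.82)],
    1000: [(1.0, 0.0), (0.80, -0.39), (0.72, -0.54)],
}
TTE_EFFECTS = {
    100: [(1.0, 0.0), (0.65, -0.68), (0.60, -0.79)],
    200: [(1.0, 0.0), (0.69, -0.59), (0.57, -0.86)],
    500: [(1.0, 0.0), (0.78, -0.39), (0.71, -0.54)],
    1000: [(1.0, 0.0), (0.85, -0.27), (0.78, -0.39)],
}
CCEDRRN_EFFECTS = [(1.0, 0.0), (0.73, -0.42), (0.63, -0.60)]

# Conditional covariate effects (beta1..beta5 on X1, X2, X3, X3^2, X5).
CONTINUOUS_BETA = {"X1": 0.5, "X2": -0.25, "X3": 0.5, "X3^2": -0.05, "X5": 0.25}
BINARY_BETA = {"X1": 1.0, "X2": -0.5, "X3": 1.0, "X3^2": -0.1, "X5": 0.5}
TTE_BETA = {"X1": 1.0, "X2": -0.5, "X3": 1.0, "X3^2": -0.1, "X5": 0.5}
CCEDRRN_BETA = {"X1": 0.092, "X2": 0.097, "X3": -0.61, "X4": -0.80, "X5": 0.63}

CCEDRRN_AGE = TruncatedNormalSpec(lower=18, upper=90, q1=39, q3=70, mean=54.7, sd=19.8)
CCEDRRN_RESP = TruncatedNormalSpec(lower=12, upper=40, q1=18, q3=22, mean=21.0, sd=6.2)


@dataclass(frozen=True)
class Scenario:
    """One simulation cell: DGM + schedule + estimand + decision rule."""

    name: str
    dgm: DGMSpec
    schedule: InterimSchedule
    kind: EstimandKind
    gamma_table: float  # tabulated true marginal effect
    u: float = U_THRESHOLD

    @property
    def adjustment_terms(self) -> tuple[str, ...]:
        return ("A", *self.dgm.terms.keys())


def _grid_covariates() -> list[CovariateSpec]:
    return [
        CovariateSpec("X1", ("bernoulli", 0.5)),
        CovariateSpec("X2", ("bernoulli", 0.5)),
        CovariateSpec("X3", ("standard_normal",)),
        CovariateSpec("X5", ("standard_normal",)),
        CovariateSpec("X6", ("bernoulli", 0.5), role="noise"),
        CovariateSpec("X7", ("standard_normal",), role="noise"),
        CovariateSpec("X8", ("standard_normal",), role="noise"),
    ]


def ccedrrn_covariates() -> list[CovariateSpec]:
    return [
        CovariateSpec("X1", ("truncated_normal", CCEDRRN_AGE)),  # age, years
        CovariateSpec("X2", ("truncated_normal", CCEDRRN_RESP)),  # resp. rate
        CovariateSpec("X3", ("bernoulli", 0.478)),  # female sex
        CovariateSpec("X4", ("bernoulli", 0.216)),  # chest pain
        CovariateSpec("X5", ("bernoulli", 0.403)),  # police/ambulance arrival
    ]


@lru_cache(maxsize=None)
def _calibrated_intercept(endpoint_tag: str) -> float:
    """Binary intercepts solved once per DGM family under the null effect."""
    if endpoint_tag == "binary_grid":
        dgm = DGMSpec(
            "binary", _grid_covariates(), phi=0.0, terms=dict(BINARY_BETA),
            target_control_risk=0.3,
        )
        return calibrate_intercept(dgm, 0.3, seed=CALIBRATION_SEED)
    dgm = DGMSpec(
        "binary", ccedrrn_covariates(), phi=0.0, terms=dict(CCEDRRN_BETA),
        target_control_risk=0.07, max_ss=3000,
    )
    return calibrate_intercept(dgm, 0.07, seed=CALIBRATION_SEED)


def _make_scenario(endpoint: str, max_ss: int, eff_index: int) -> Scenario:
    if endpoint == "continuous":
        gamma, phi = CONTINUOUS_EFFECTS[max_ss][eff_index]
        dgm = DGMSpec(
            "continuous", _grid_covariates(), phi=phi, terms=dict(CONTINUOUS_BETA),
            beta0=0.0, residual_sd=1.0, max_ss=max_ss,
        )
        schedule = InterimSchedule("enrollment_count", ENROLL_TRIGGER[max_ss])
        kind = EstimandKind.DIFF_MEANS
    elif endpoint == "binary":
        gamma, phi = BINARY_EFFECTS[max_ss][eff_index]
        dgm = DGMSpec(
            "binary", _grid_covariates(), phi=phi, terms=dict(BINARY_BETA),
            beta0=_calibrated_intercept("binary_grid"), target_control_risk=0.3,
            max_ss=max_ss,
        )
        schedule = InterimSchedule("event_count", BINARY_EVENT_TRIGGER[max_ss])
        kind = EstimandKind.RELATIVE_RISK
    else:
        gamma, phi = TTE_EFFECTS[max_ss][eff_index]
        dgm = DGMSpec(
            "tte", _grid_covariates(), phi=phi, terms=dict(TTE_BETA),
            beta0=0.0, baseline_rate=0.02, max_ss=max_ss,
        )
        schedule = InterimSchedule(
            "event_count", TTE_EVENT_TRIGGER[max_ss],
            accrual_end=TTE_ACCRUAL_END, horizon=TTE_HORIZON,
        )
        kind = EstimandKind.HAZARD_RATIO
    tag = "null" if eff_index == 0 else f"eff{eff_index + 1}"
    return Scenario(f"{endpoint}_ss{max_ss}_{tag}", dgm, schedule, kind, gamma)


def _make_ccedrrn(eff_index: int) -> Scenario:
    gamma, phi = CCEDRRN_EFFECTS[eff_index]
    dgm = DGMSpec(
        "binary", ccedrrn_covariates(), phi=phi, terms=dict(CCEDRRN_BETA),
        beta0=_calibrated_intercept("ccedrrn"), target_control_risk=0.07, max_ss=3000,
    )
    schedule = InterimSchedule("event_count", 75)
    tag = "null" if eff_index == 0 else f"eff{eff_index + 1}"
    return Scenario(f"ccedrrn_{tag}", dgm, schedule, EstimandKind.RELATIVE_RISK, gamma)


@lru_cache(maxsize=1)
def builtin_scenarios() -> dict[str, Scenario]:
    """Registry of every endpoint x max-ss x effect cell plus the CCEDRRN trial.

    Names follow ``{endpoint}_ss{max_ss}_{null|eff2|eff3}`` and
    ``ccedrrn_{null|eff2|eff3}`` (eff2/eff3 are the two non-null effects).
    """
    registry: dict[str, Scenario] = {}
    for endpoint in ("continuous", "binary", "tte"):
        for max_ss in (100, 200, 500, 1000):
            for eff in range(3):
                sc = _make_scenario(endpoint, max_ss, eff)
                registry[sc.name] = sc
    for eff in range(3):
        sc = _make_ccedrrn(eff)
        registry[sc.name] = sc
    return registry


def model_variants(scenario: Scenario) -> dict[str, ModelSpec]:
    """The named adjustment models for a scenario, built from its DGM.

    The CCEDRRN application omits the quadratic/noise variants (its DGM has
    neither a quadratic term nor noise covariates).
    """
    dgm = scenario.dgm
    family = {
        "continuous": "normal",
        "binary": "bernoulli_logit",
        "tte": "ph_mspline",
    }[dgm.endpoint]
    correct_terms = scenario.adjustment_terms
    centers = dict(dgm.terms)
    out = {
        "correct": ModelSpec(family, correct_terms, "weak", name="correct"),
        "correct_prior": ModelSpec(
            family, correct_terms, "centered", prior_centers=centers, name="correct_prior"
        ),
        "correct_strong_prior": ModelSpec(
            family, correct_terms, "strong", prior_centers=centers, name="correct_strong_prior"
        ),
        "unadjusted": ModelSpec(family, ("A",), "weak", name="unadjusted"),
    }
    if "X3^2" in dgm.terms:
        no_quad = tuple(t for t in correct_terms if t != "X3^2")
        out["no_quad"] = ModelSpec(family, no_quad, "weak", name="no_quad")
    noise = tuple(c.name for c in dgm.covariates if c.role == "noise")
    if noise:
        out["correct_noise"] = ModelSpec(
            family, (*correct_terms, *noise), "weak", name="correct_noise"
        )
    return out
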