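"""Monte-Carlo operating characteristics across replicate trials.

For a fixed scenario x adjustment model, replicate trials are summarized into
the design's frequentist operating characteristics: rejection rate (power away
from the null, type-1 error at it), probability of stopping early, expected
sample size, posterior-median bias against the true marginal estimand, and the
per-replicate posterior RMSE

    RMSE_r = sqrt( mean_s (gamma_s - gamma*)^2 )

over the S retained draws of replicate r.  Monte-Carlo standard errors are
reported alongside every rate so that scaled-down runs remain interpretable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from bayesadapt.estimands import EstimandKind
from bayesadapt.sequential import TrialResult

__all__ = ["ScenarioTruth", "OCTable", "rmse_replicate", "summarize", "run_replicates"]


@dataclass(frozen=True)
class ScenarioTruth:
    """The true marginal effect against which replicates are scored."""

    gamma_star: float
    kind: EstimandKind
    max_ss: int

    @property
    def is_null(self) -> bool:
        return math.isclose(self.gamma_star, self.kind.null_value, abs_tol=1e-12)


@dataclass
class OCTable:
    """Operating characteristics of one scenario x model cell."""

    n_replicates: int
    n_flagged: int
    reject_rate: float
    reject_rate_se: float
    p_stop_early: float
    p_stop_early_se: float
    p_stop_first_interim: float
    expected_n: float
    expected_n_se: float
    bias: float
    bias_log: float | None
    rmse_mean: float
    rmse_q: tuple[float, float, float]
    mean_analyses: float
    gamma_star: float

    def to_frame(self) -> pd.DataFrame:
        d = {k: v for k, v in self.__dict__.items() if k != "rmse_q"}
        d["rmse_q25"], d["rmse_q50"], d["rmse_q75"] = self.rmse_q
        return pd.DataFrame([d])


def rmse_replicate(gamma_draws: np.ndarray, gamma_star: float) -> float:
    """Root mean squared deviation of one replicate's posterior draws from truth."""
    gamma_draws = np.asarray(gamma_draws, dtype=float)
    if gamma_draws.size < 2:
        raise ValueError("need at least two posterior draws")
    return float(np.sqrt(np.mean((gamma_draws - gamma_star) ** 2)))


def _rate_se(p: float, n: int) -> float:
    return math.sqrt(max(p * (1 - p), 0.0) / n) if n > 0 else float("nan")


def summarize(results: list[TrialResult], truth: ScenarioTruth) -> OCTable:
    """Aggregate replicate trials into an operating-characteristics row.

    Replicates with flagged (failed) model fits at their stopping analysis are
    excluded from posterior-based summaries with a logged count; decision-based
    rates use every replicate whose stopping decision was computable.
    """
    if not results:
        raise ValueError("need at least one replicate")
    usable = [r for r in results if np.isfinite(r.T_stop)]
    n_flagged = sum(1 for r in results if r.flagged)
    n = len(usable)
    if n == 0:
        raise ValueError("all replicates failed their model fits")
    reject = np.array([r.declared for r in usable], dtype=float)
    early = np.array([r.stopped_early for r in usable], dtype=float)
    first = np.array(
        [r.stopped_early and r.stop_analysis_index == 1 for r in usable], dtype=float
    )
    n_end = np.array([r.n_enrolled for r in usable], dtype=float)
    medians = np.array([r.gamma_median for r in usable])
    rmses = np.array([rmse_replicate(r.gamma_draws, truth.gamma_star) for r in usable])
    bias = float(np.mean(medians) - truth.gamma_star)
    if truth.kind is EstimandKind.DIFF_MEANS:
        bias_log = None
    else:
        with np.errstate(invalid="ignore"):
            bias_log = float(np.mean(np.log(medians)) - math.log(truth.gamma_star))
    return OCTable(
        n_replicates=n,
        n_flagged=n_flagged,
        reject_rate=float(reject.mean()),
        reject_rate_se=_rate_se(float(reject.mean()), n),
        p_stop_early=float(early.mean()),
        p_stop_early_se=_rate_se(float(early.mean()), n),
        p_stop_first_interim=float(first.mean()),
        expected_n=float(n_end.mean()),
        expected_n_se=float(n_end.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan"),
        bias=bias,
        bias_log=bias_log,
        rmse_mean=float(rmses.mean()),
        rmse_q=tuple(np.quantile(rmses, [0.25, 0.5, 0.75])),
        mean_analyses=float(np.mean([len(r.analyses) for r in usable])),
        gamma_star=truth.gamma_star,
    )


def run_replicates(
    dgm,
    model,
    schedule,
    kind: EstimandKind,
    u: float,
    n_replicates: int,
    master_seed: int,
    sampler=None,
) -> list[TrialResult]:
    """Run independent replicate trials with per-replicate derived seeds.

    Replicate r's seed depends only on (master_seed, r), so results are
    invariant to execution order and reproducible one replicate at a time.
    """
    from bayesadapt.sequential import run_trial

    ss = np.random.SeedSequence(master_seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_replicates)]
    return [
        run_trial(dgm, model, schedule, kind, u, seeds[r], sampler)
        for r in range(n_replicates)
    ]
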