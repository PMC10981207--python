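"""Single-trial engine: accrual, interim analyses, early stopping.

A trial enrolls up to ``max_ss`` participants under 1:1 randomization and is
analyzed at a predefined schedule: after fixed enrollment increments
(continuous endpoint) or whenever at least ``trigger`` new events have
accumulated since the previous analysis (binary, time-to-event).  At each
analysis the outcome model is refit to the enrolled snapshot, posterior draws
are standardized to the marginal estimand, and superiority is declared when
the posterior probability of the alternative strictly exceeds the threshold u,
stopping the trial.  Otherwise a final analysis runs at full enrollment
(continuous/binary) or at the calendar horizon (time-to-event, with
administrative censoring of participants still at risk).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from bayesadapt.dgm import DGMSpec, latent_event_times, sample_population, simulate_outcomes
from bayesadapt.estimands import EstimandKind
from bayesadapt.gcomp import bootstrap_weights, contrast, decision_statistic, marginalize
from bayesadapt.models import ModelSpec, SamplerConfig, fit_posterior

__all__ = [
    "InterimSchedule",
    "AnalysisRecord",
    "TrialResult",
    "plan_analyses",
    "enrollment_analysis_points",
    "event_analysis_points",
    "snapshot_tte",
    "run_trial",
]


@dataclass(frozen=True)
class InterimSchedule:
    """When interim analyses fire.

    ``mode="enrollment_count"``: every ``trigger`` enrollments, final at max_ss.
    ``mode="event_count"``: whenever at least ``trigger`` new events have
    occurred since the last analysis.  Time-to-event trials additionally carry
    the accrual end and censoring horizon (calendar times).
    """

    mode: str
    trigger: int
    accrual_end: float | None = None
    horizon: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("enrollment_count", "event_count"):
            raise ValueError(f"unknown schedule mode {self.mode!r}")
        if self.trigger < 1:
            raise ValueError("trigger must be >= 1")


@dataclass
class AnalysisRecord:
    index: int  # 1-based analysis index
    calendar_time: float
    n_t: int
    events: int
    new_events: int
    T: float
    superior: bool
    is_final: bool
    flagged: str | None = None


@dataclass
class TrialResult:
    """One simulated trial's stopping history and posterior at stop."""

    stopped_early: bool
    declared: bool  # superiority at any analysis, interim or final
    stop_analysis_index: int
    n_enrolled: int
    n_events: int
    T_stop: float
    gamma_draws: np.ndarray
    gamma_median: float
    analyses: list[AnalysisRecord] = field(default_factory=list)
    flagged: list[str] = field(default_factory=list)


def enrollment_analysis_points(max_ss: int, trigger: int) -> list[int]:
    """Cumulative enrollments at which analyses run; the last is the final."""
    if trigger > max_ss:
        raise ValueError(f"trigger {trigger} exceeds max_ss {max_ss}")
    pts = list(range(trigger, max_ss + 1, trigger))
    if not pts or pts[-1] != max_ss:
        pts.append(max_ss)
    return pts


def plan_analyses(dgm: DGMSpec, schedule: InterimSchedule) -> list[int] | InterimSchedule:
    """Resolve the analysis trigger rule for a scenario.

    Enrollment-count mode returns the explicit cumulative enrollment points;
    event-count analyses depend on the realized outcome stream, so the
    (validated) schedule itself is returned as the rule.
    """
    if schedule.mode == "event_count" and dgm.endpoint == "tte" and (
        schedule.accrual_end is None or schedule.horizon is None
    ):
        raise ValueError("tte schedules need accrual_end and horizon")
    if schedule.trigger > dgm.max_ss:
        raise ValueError(f"trigger {schedule.trigger} exceeds max_ss {dgm.max_ss}")
    if schedule.mode == "enrollment_count":
        return enrollment_analysis_points(dgm.max_ss, schedule.trigger)
    return schedule


def event_analysis_points(y: np.ndarray, trigger: int) -> list[int]:
    """Enrollment counts at which event-driven interims fire (binary endpoint).

    The data stream is monitored participant-by-participant: an analysis uses
    all participants enrolled at the moment cumulative new events since the
    last analysis first reach ``trigger``.  The final analysis at full
    enrollment is appended regardless of event count.
    """
    y = np.asarray(y)
    n = len(y)
    pts: list[int] = []
    events_at_last = 0
    cum = 0
    for i in range(n):
        cum += int(y[i])
        if cum - events_at_last >= trigger and i + 1 < n:
            pts.append(i + 1)
            events_at_last = cum
    pts.append(n)
    return pts


def snapshot_tte(outcomes: pd.DataFrame, calendar_time: float) -> pd.DataFrame:
    """Administrative snapshot of a time-to-event trial at a calendar time.

    Participants enrolled by ``calendar_time`` are included; each contributes
    T = min(latent event time, calendar_time - enrollment time) with the
    event indicator delta set accordingly.
    """
    if calendar_time < 0:
        raise ValueError("calendar_time must be nonnegative")
    enrolled = outcomes[outcomes["enroll_time"] <= calendar_time].copy()
    follow = calendar_time - enrolled["enroll_time"].to_numpy()
    latent = enrolled["event_time_latent"].to_numpy()
    observed = latent <= follow
    enrolled["T"] = np.where(observed, latent, follow)
    enrolled["delta"] = observed.astype(int)
    return enrolled


def _analyze(
    model: ModelSpec,
    snap: pd.DataFrame,
    kind: EstimandKind,
    u: float,
    sampler: SamplerConfig,
    fit_seed,
    w_seed,
    time: float | None,
) -> tuple[float, bool, np.ndarray]:
    draws, report = fit_posterior(model, snap, sampler, fit_seed, time_upper=time)
    if not report.passed:
        warnings.warn(
            f"convergence check failed (max split-Rhat {report.max_rhat():.3f})",
            stacklevel=2,
        )
    if model.is_unadjusted:
        marg = marginalize(draws, None, time=time)
    else:
        weights = bootstrap_weights(len(snap), draws.n_draws, w_seed)
        marg = marginalize(draws, snap, weights=weights, time=time)
    gamma = contrast(marg, kind)
    dec = decision_statistic(gamma, kind, u)
    return dec.T, dec.superior, gamma


def run_trial(
    dgm: DGMSpec,
    model: ModelSpec,
    schedule: InterimSchedule,
    kind: EstimandKind,
    u: float,
    seed: int,
    sampler: SamplerConfig | None = None,
) -> TrialResult:
    """Simulate one adaptive trial end-to-end.

    Generates the population and outcomes from the DGM, fires analyses per the
    schedule, and stops at the first analysis whose decision statistic exceeds
    u.  A model-fit failure at an analysis is recorded on the result (the
    analysis then does not stop the trial) rather than dropping the replicate.
    """
    sampler = sampler or SamplerConfig()
    ss = np.random.SeedSequence(seed)
    seed_pop, seed_out, seed_ana = ss.spawn(3)
    plan_analyses(dgm, schedule)  # validate combination

    if dgm.endpoint == "tte":
        return _run_trial_tte(dgm, model, schedule, kind, u, sampler, seed_pop, seed_out, seed_ana)

    pop = sample_population(dgm, dgm.max_ss, "instant", seed_pop)
    data = simulate_outcomes(dgm, pop, None, seed_out)
    if schedule.mode == "enrollment_count":
        points = enrollment_analysis_points(dgm.max_ss, schedule.trigger)
    else:
        points = event_analysis_points(data["Y"].to_numpy(), schedule.trigger)

    analyses: list[AnalysisRecord] = []
    flagged: list[str] = []
    result_T, result_gamma = float("nan"), np.array([np.nan, np.nan])
    stop_idx, stopped_early, declared = len(points), False, False
    events_at_last = 0
    n_stop = dgm.max_ss
    for a_idx, n in enumerate(points, start=1):
        snap = data.iloc[:n]
        is_final = a_idx == len(points)
        events = int(snap["Y"].sum()) if dgm.endpoint == "binary" else 0
        fit_seed, w_seed = np.random.SeedSequence(
            entropy=seed_ana.entropy, spawn_key=(*seed_ana.spawn_key, a_idx)
        ).spawn(2)
        try:
            T, superior, gamma = _analyze(model, snap, kind, u, sampler, fit_seed, w_seed, None)
            flag = None
        except Exception as exc:  # fit failure: flag, do not stop here
            T, superior, gamma = float("nan"), False, None
            flag = f"analysis {a_idx}: {exc}"
            flagged.append(flag)
        analyses.append(
            AnalysisRecord(a_idx, 0.0, n, events, events - events_at_last, T, superior, is_final, flag)
        )
        events_at_last = events
        if gamma is not None:
            result_T, result_gamma = T, gamma
        if superior:
            stop_idx, stopped_early, declared = a_idx, not is_final, True
            n_stop = n
            break
        if is_final:
            stop_idx = a_idx
            n_stop = n
    return TrialResult(
        stopped_early=stopped_early,
        declared=declared,
        stop_analysis_index=stop_idx,
        n_enrolled=n_stop,
        n_events=analyses[-1].events,
        T_stop=result_T,
        gamma_draws=result_gamma if result_gamma is not None else np.array([]),
        gamma_median=float(np.median(result_gamma)),
        analyses=analyses,
        flagged=flagged,
    )


def _run_trial_tte(
    dgm: DGMSpec,
    model: ModelSpec,
    schedule: InterimSchedule,
    kind: EstimandKind,
    u: float,
    sampler: SamplerConfig,
    seed_pop,
    seed_out,
    seed_ana,
) -> TrialResult:
    accrual_end, horizon = schedule.accrual_end, schedule.horizon
    pop = sample_population(dgm, dgm.max_ss, ("uniform", accrual_end), seed_pop)
    pop["event_time_latent"] = latent_event_times(dgm, pop, seed_out)
    abs_event = pop["enroll_time"].to_numpy() + pop["event_time_latent"].to_numpy()

    # Interim calendar times: the moments at which cumulative new events since
    # the previous analysis reach the trigger, strictly before the horizon.
    event_times = np.sort(abs_event[abs_event < horizon])
    interim_times: list[float] = []
    last_count = 0
    for j, t_ev in enumerate(event_times, start=1):
        if j - last_count >= schedule.trigger:
            interim_times.append(float(t_ev))
            last_count = j
    times = [(t, False) for t in interim_times] + [(float(horizon), True)]

    analyses: list[AnalysisRecord] = []
    flagged: list[str] = []
    result_T, result_gamma = float("nan"), np.array([np.nan, np.nan])
    stop_idx, stopped_early, declared = len(times), False, False
    n_stop, events_stop = dgm.max_ss, 0
    events_at_last = 0
    for a_idx, (cal_t, is_final) in enumerate(times, start=1):
        snap = snapshot_tte(pop, cal_t)
        events = int(snap["delta"].sum())
        fit_seed, w_seed = np.random.SeedSequence(
            entropy=seed_ana.entropy, spawn_key=(*seed_ana.spawn_key, a_idx)
        ).spawn(2)
        try:
            T, superior, gamma = _analyze(
                model, snap, kind, u, sampler, fit_seed, w_seed, cal_t
            )
            flag = None
        except Exception as exc:
            T, superior, gamma = float("nan"), False, None
            flag = f"analysis {a_idx}: {exc}"
            flagged.append(flag)
        analyses.append(
            AnalysisRecord(
                a_idx, cal_t, len(snap), events, events - events_at_last, T, superior, is_final, flag
            )
        )
        events_at_last = events
        if gamma is not None:
            result_T, result_gamma = T, gamma
        if superior or is_final:
            stop_idx = a_idx
            stopped_early, declared = (superior and not is_final), superior or declared
            n_stop, events_stop = len(snap), events
            break
    return TrialResult(
        stopped_early=stopped_early,
        declared=declared,
        stop_analysis_index=stop_idx,
        n_enrolled=n_stop,
        n_events=events_stop,
        T_stop=result_T,
        gamma_draws=result_gamma if result_gamma is not None else np.array([]),
        gamma_median=float(np.median(result_gamma)),
        analyses=analyses,
        flagged=flagged,
    )
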