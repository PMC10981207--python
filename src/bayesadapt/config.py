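"""Scenario configuration, orchestration, and reproducibility manifests.

A scenario config (YAML or JSON) either references a built-in scenario by name
or spells out a DGM/schedule/rule block.  Outputs of a run are one
operating-characteristics CSV per adjustment model, per-trial JSON-lines logs,
and a manifest recording the config hash and every replicate seed so the run
is bit-for-bit reproducible.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Literal

import numpy as np
import yaml
from pydantic import BaseModel, Field, model_validator

from bayesadapt import scenarios as _scen
from bayesadapt.dgm import CovariateSpec, DGMSpec, TruncatedNormalSpec, calibrate_intercept
from bayesadapt.estimands import EstimandKind
from bayesadapt.models import SamplerConfig
from bayesadapt.oc import ScenarioTruth, run_replicates, summarize
from bayesadapt.sequential import InterimSchedule

__all__ = ["ScenarioConfig", "RunManifest", "load_config", "run_scenario"]


class TruncNormModel(BaseModel):
    lower: float
    upper: float
    q1: float
    q3: float
    mean: float
    sd: float


class CovariateModel(BaseModel):
    name: str
    law: Literal["bernoulli", "standard_normal", "truncated_normal"]
    p: float | None = None
    spec: TruncNormModel | None = None
    role: Literal["signal", "noise"] = "signal"

    @model_validator(mode="after")
    def _check(self):
        if self.law == "bernoulli" and self.p is None:
            raise ValueError("bernoulli law requires p")
        if self.law == "truncated_normal" and self.spec is None:
            raise ValueError("truncated_normal law requires spec")
        return self

    def build(self) -> CovariateSpec:
        if self.law == "bernoulli":
            law = ("bernoulli", self.p)
        elif self.law == "standard_normal":
            law = ("standard_normal",)
        else:
            law = ("truncated_normal", TruncatedNormalSpec(**self.spec.model_dump()))
        return CovariateSpec(self.name, law, self.role)


class DGMModel(BaseModel):
    endpoint: Literal["continuous", "binary", "tte"]
    covariates: list[CovariateModel]
    phi: float
    terms: dict[str, float] = Field(default_factory=dict)
    beta0: float | None = None  # binary: calibrated when omitted
    residual_sd: float = 1.0
    baseline_rate: float | None = None
    target_control_risk: float | None = None
    max_ss: int = Field(gt=0)

    def build(self) -> DGMSpec:
        dgm = DGMSpec(
            endpoint=self.endpoint,
            covariates=[c.build() for c in self.covariates],
            phi=self.phi,
            terms=dict(self.terms),
            beta0=self.beta0 if self.beta0 is not None else 0.0,
            residual_sd=self.residual_sd,
            baseline_rate=self.baseline_rate,
            target_control_risk=self.target_control_risk,
            max_ss=self.max_ss,
        )
        if self.endpoint == "binary" and self.beta0 is None:
            if self.target_control_risk is None:
                raise ValueError("binary DGM needs beta0 or target_control_risk")
            dgm.beta0 = calibrate_intercept(dgm, seed=_scen.CALIBRATION_SEED)
        return dgm


class ScheduleModel(BaseModel):
    mode: Literal["enrollment_count", "event_count"]
    trigger: int = Field(ge=1)
    accrual_end: float | None = None
    horizon: float | None = None

    def build(self) -> InterimSchedule:
        return InterimSchedule(self.mode, self.trigger, self.accrual_end, self.horizon)


class RuleModel(BaseModel):
    estimand: Literal["diff_means", "relative_risk", "odds_ratio", "hazard_ratio"]
    u: float = Field(gt=0, lt=1)


class SamplerModel(BaseModel):
    chains: int = Field(default=3, ge=1)
    draws: int = Field(default=1000, ge=2)

    def build(self) -> SamplerConfig:
        return SamplerConfig(chains=self.chains, draws=self.draws)


class ScenarioConfig(BaseModel):
    """Validated top-level run configuration."""

    builtin: str | None = None  # name in builtin_scenarios()
    dgm: DGMModel | None = None
    schedule: ScheduleModel | None = None
    rule: RuleModel | None = None
    models: list[str] = Field(default_factory=lambda: ["correct", "unadjusted"])
    replicates: int = Field(default=500, ge=1)
    master_seed: int = 1
    workers: int = Field(default=1, ge=1)
    sampler: SamplerModel = Field(default_factory=SamplerModel)
    scaled: bool = False  # quarter the replicate count and draw budget

    @model_validator(mode="after")
    def _check(self):
        if self.builtin is None and (self.dgm is None or self.schedule is None or self.rule is None):
            raise ValueError("provide either 'builtin' or all of dgm/schedule/rule")
        if self.builtin is not None and self.builtin not in _scen.builtin_scenarios():
            raise ValueError(f"unknown builtin scenario {self.builtin!r}")
        return self

    def resolve(self) -> _scen.Scenario:
        if self.builtin is not None:
            return _scen.builtin_scenarios()[self.builtin]
        dgm = self.dgm.build()
        return _scen.Scenario(
            name="custom",
            dgm=dgm,
            schedule=self.schedule.build(),
            kind=EstimandKind(self.rule.estimand),
            gamma_table=float("nan"),
            u=self.rule.u,
        )


class RunManifest(BaseModel):
    config_hash: str
    version: str
    replicates: int
    replicate_seeds: list[int]
    convergence_failures: int
    wall_seconds: float


def load_config(path: str | Path) -> ScenarioConfig:
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    return ScenarioConfig.model_validate(raw)


def _replicate_seeds(master_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def run_scenario(config: ScenarioConfig, outdir: str | Path) -> RunManifest:
    """Execute a scenario for every requested adjustment model.

    Writes ``oc_<model>.csv`` (operating characteristics), ``trials_<model>.jsonl``
    (per-analysis decisions) and ``manifest.json`` under ``outdir``.
    Deterministic given the config and master seed.
    """
    from bayesadapt import __version__
    from bayesadapt.dgm import true_marginal_estimand

    t0 = time.monotonic()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scenario = config.resolve()
    n_reps = config.replicates
    sampler = config.sampler.build()
    if config.scaled:
        n_reps = max(1, n_reps // 4)
        sampler = SamplerConfig(chains=sampler.chains, draws=max(2, sampler.draws // 4))
    variants = _scen.model_variants(scenario)
    unknown = [m for m in config.models if m not in variants]
    if unknown:
        raise ValueError(f"models {unknown} not available for scenario {scenario.name!r}")
    if np.isnan(scenario.gamma_table):
        gamma_star = true_marginal_estimand(
            scenario.dgm, scenario.kind, mc_n=200_000, seed=_scen.CALIBRATION_SEED
        )
    else:
        gamma_star = scenario.gamma_table
    truth = ScenarioTruth(gamma_star, scenario.kind, scenario.dgm.max_ss)

    conv_failures = 0
    for model_name in config.models:
        results = run_replicates(
            scenario.dgm,
            variants[model_name],
            scenario.schedule,
            scenario.kind,
            scenario.u,
            n_reps,
            config.master_seed,
            sampler,
        )
        conv_failures += sum(len(r.flagged) for r in results)
        table = summarize(results, truth)
        df = table.to_frame()
        df.insert(0, "model", model_name)
        df.insert(0, "scenario", scenario.name)
        df.to_csv(outdir / f"oc_{model_name}.csv", index=False)
        with open(outdir / f"trials_{model_name}.jsonl", "w") as fh:
            for r_idx, res in enumerate(results):
                for a in res.analyses:
                    fh.write(
                        json.dumps(
                            {
                                "replicate": r_idx,
                                "analysis": a.index,
                                "calendar_time": a.calendar_time,
                                "n_t": a.n_t,
                                "events": a.events,
                                "T": None if not np.isfinite(a.T) else a.T,
                                "superior": a.superior,
                                "final": a.is_final,
                            }
                        )
                        + "\n"
                    )

    payload = json.dumps(config.model_dump(), sort_keys=True, default=str).encode()
    manifest = RunManifest(
        config_hash=hashlib.sha256(payload).hexdigest(),
        version=__version__,
        replicates=n_reps,
        replicate_seeds=_replicate_seeds(config.master_seed, n_reps),
        convergence_failures=conv_failures,
        wall_seconds=time.monotonic() - t0,
    )
    (outdir / "manifest.json").write_text(manifest.model_dump_json(indent=2))
    return manifest
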