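"""Shared fixtures: small DGMs, cached scenario registry, fast sampler configs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from bayesadapt.dgm import CovariateSpec, DGMSpec
from bayesadapt.models import SamplerConfig
from bayesadapt.scenarios import builtin_scenarios


@pytest.fixture(scope="session")
def registry():
    return builtin_scenarios()


@pytest.fixture
def continuous_dgm():
    """The continuous grid DGM at a fixed non-null effect."""
    return DGMSpec(
        "continuous",
        [
            CovariateSpec("X1", ("bernoulli", 0.5)),
            CovariateSpec("X2", ("bernoulli", 0.5)),
            CovariateSpec("X3", ("standard_normal",)),
            CovariateSpec("X5", ("standard_normal",)),
            CovariateSpec("X6", ("bernoulli", 0.5), role="noise"),
        ],
        phi=-0.5,
        terms={"X1": 0.5, "X2": -0.25, "X3": 0.5, "X3^2": -0.05, "X5": 0.25},
        beta0=0.0,
        residual_sd=1.0,
        max_ss=200,
    )


@pytest.fixture
def tte_dgm():
    return DGMSpec(
        "tte",
        [CovariateSpec("X1", ("bernoulli", 0.5)), CovariateSpec("X3", ("standard_normal",))],
        phi=-0.6,
        terms={"X1": 1.0, "X3": 1.0},
        baseline_rate=0.02,
        max_ss=200,
    )


@pytest.fixture
def fast_sampler():
    """Small draw budget for tests exercising machinery rather than accuracy."""
    return SamplerConfig(chains=2, draws=150)


@pytest.fixture
def normal_data():
    """A fixed small continuous-outcome dataset with treatment and one covariate."""
    rng = np.random.default_rng(7)
    n = 80
    a = rng.binomial(1, 0.5, n).astype(float)
    x = rng.standard_normal(n)
    y = 0.3 - 0.4 * a + 0.8 * x + rng.standard_normal(n)
    return pd.DataFrame({"A": a, "X": x, "Y": y})
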