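"""Unit and distributional tests for the data-generating mechanisms."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy import special, stats

from bayesadapt.dgm import (
    CovariateSpec,
    DGMSpec,
    TruncatedNormalSpec,
    calibrate_intercept,
    latent_event_times,
    sample_population,
    sample_truncated_normal,
    simulate_outcomes,
    solve_truncated_normal,
    true_marginal_estimand,
)
from bayesadapt.estimands import EstimandKind
from bayesadapt.scenarios import CCEDRRN_AGE


class TestTruncatedNormal:
    def test_solver_matches_post_truncation_moments(self):
        mu, sigma = solve_truncated_normal(CCEDRRN_AGE)
        a = (CCEDRRN_AGE.lower - mu) / sigma
        b = (CCEDRRN_AGE.upper - mu) / sigma
        m, v = stats.truncnorm(a, b, loc=mu, scale=sigma).stats(moments="mv")
        assert float(m) == pytest.approx(CCEDRRN_AGE.mean, abs=1e-6)
        assert math.sqrt(float(v)) == pytest.approx(CCEDRRN_AGE.sd, abs=1e-6)

    def test_samples_match_moments_and_support(self):
        x = sample_truncated_normal(CCEDRRN_AGE, 200_000, seed=3)
        assert x.min() >= CCEDRRN_AGE.lower and x.max() <= CCEDRRN_AGE.upper
        assert x.mean() == pytest.approx(CCEDRRN_AGE.mean, abs=0.15)
        assert x.std(ddof=1) == pytest.approx(CCEDRRN_AGE.sd, abs=0.15)

    def test_age_quartiles_close_to_registry_summaries(self):
        # The quartiles over-determine the law; for the age spec they are
        # nonetheless nearly attained by the moment-matched solution.
        x = sample_truncated_normal(CCEDRRN_AGE, 200_000, seed=4)
        q1, q3 = np.quantile(x, [0.25, 0.75])
        assert q1 == pytest.approx(CCEDRRN_AGE.q1, abs=1.5)
        assert q3 == pytest.approx(CCEDRRN_AGE.q3, abs=1.5)

    def test_ks_against_fitted_law(self):
        mu, sigma = solve_truncated_normal(CCEDRRN_AGE)
        a = (CCEDRRN_AGE.lower - mu) / sigma
        b = (CCEDRRN_AGE.upper - mu) / sigma
        x = sample_truncated_normal(CCEDRRN_AGE, 20_000, seed=5)
        stat = stats.kstest(x, stats.truncnorm(a, b, loc=mu, scale=sigma).cdf)
        assert stat.pvalue > 0.01

    def test_infeasible_sd_raises(self):
        # SD above the uniform limit (upper-lower)/sqrt(12) is unattainable.
        spec = TruncatedNormalSpec(lower=0, upper=10, q1=3, q3=7, mean=5, sd=4.0)
        with pytest.raises(ValueError, match="infeasible"):
            solve_truncated_normal(spec)

    def test_invalid_orderings_raise(self):
        with pytest.raises(ValueError):
            TruncatedNormalSpec(lower=5, upper=4, q1=2, q3=3, mean=4.5, sd=1)
        with pytest.raises(ValueError):
            TruncatedNormalSpec(lower=0, upper=10, q1=7, q3=3, mean=5, sd=1)
        with pytest.raises(ValueError):
            TruncatedNormalSpec(lower=0, upper=10, q1=3, q3=7, mean=5, sd=-1)


class TestSpecsValidation:
    def test_noise_covariate_cannot_enter_terms(self):
        with pytest.raises(ValueError, match="noise"):
            DGMSpec(
                "continuous",
                [CovariateSpec("X6", ("bernoulli", 0.5), role="noise")],
                phi=0.0,
                terms={"X6": 1.0},
            )

    def test_unknown_term_covariate_raises(self):
        with pytest.raises(ValueError, match="unknown covariate"):
            DGMSpec("continuous", [], phi=0.0, terms={"X9": 1.0})

    def test_tte_requires_baseline_rate(self):
        with pytest.raises(ValueError, match="baseline_rate"):
            DGMSpec("tte", [], phi=0.0)


class TestPopulation:
    def test_columns_order_and_randomization(self, continuous_dgm):
        pop = sample_population(continuous_dgm, 200, "instant", seed=11)
        assert list(pop.columns[:3]) == ["id", "enroll_time", "A"]
        assert set(pop["A"].unique()) <= {0, 1}
        assert np.all(pop["enroll_time"] == 0.0)

    def test_eta_recomputes_from_columns(self, continuous_dgm):
        pop = sample_population(continuous_dgm, 50, "instant", seed=12)
        eta = (
            continuous_dgm.phi * pop["A"]
            + 0.5 * pop["X1"]
            - 0.25 * pop["X2"]
            + 0.5 * pop["X3"]
            - 0.05 * pop["X3"] ** 2
            + 0.25 * pop["X5"]
        )
        np.testing.assert_allclose(pop["eta"], eta, atol=1e-12)

    def test_uniform_accrual_sorted_within_bounds(self, tte_dgm):
        pop = sample_population(tte_dgm, 200, ("uniform", 25.0), seed=13)
        t = pop["enroll_time"].to_numpy()
        assert np.all(np.diff(t) >= 0)
        assert t.min() >= 0 and t.max() <= 25.0

    def test_n_beyond_max_ss_raises(self, tte_dgm):
        with pytest.raises(ValueError, match="max_ss"):
            sample_population(tte_dgm, 201, "instant", seed=1)

    def test_treatment_independent_of_covariates(self, continuous_dgm):
        big = DGMSpec(
            "continuous",
            continuous_dgm.covariates,
            phi=0.0,
            terms=continuous_dgm.terms,
            max_ss=50_000,
        )
        pop = sample_population(big, 50_000, "instant", seed=14)
        for col in ("X1", "X3"):
            r = np.corrcoef(pop["A"], pop[col])[0, 1]
            assert abs(r) < 0.02


class TestOutcomes:
    def test_continuous_residual_sd(self, continuous_dgm):
        pop = sample_population(continuous_dgm, 200, "instant", seed=21)
        data = simulate_outcomes(continuous_dgm, pop, None, seed=22)
        resid = data["Y"] - data["eta"]
        assert resid.std(ddof=1) == pytest.approx(1.0, abs=0.15)
        tight = DGMSpec(
            "continuous", continuous_dgm.covariates, phi=-0.5,
            terms=continuous_dgm.terms, residual_sd=1e-9, max_ss=200,
        )
        data2 = simulate_outcomes(tight, pop, None, seed=23)
        np.testing.assert_allclose(data2["Y"], pop["eta"], atol=1e-6)

    def test_binary_mean_matches_expit(self):
        dgm = DGMSpec(
            "binary", [CovariateSpec("X3", ("standard_normal",))],
            phi=0.0, terms={"X3": 1.0}, beta0=-1.0, max_ss=200_000,
        )
        pop = sample_population(dgm, 200_000, "instant", seed=24)
        data = simulate_outcomes(dgm, pop, None, seed=25)
        assert data["Y"].mean() == pytest.approx(
            special.expit(pop["eta"]).mean(), abs=0.005
        )

    def test_latent_event_times_exponential_oracle(self, tte_dgm):
        # rate * T should be Exponential(1) regardless of covariates.
        big = DGMSpec(
            "tte", tte_dgm.covariates, phi=-0.6, terms=tte_dgm.terms,
            baseline_rate=0.02, max_ss=50_000,
        )
        pop = sample_population(big, 50_000, "instant", seed=26)
        latent = latent_event_times(big, pop, seed=27)
        rate = 0.02 * np.exp(pop["eta"].to_numpy())
        stat = stats.kstest(rate * latent, "expon")
        assert stat.pvalue > 0.01

    def test_tte_censoring_consistency(self, tte_dgm):
        pop = sample_population(tte_dgm, 200, ("uniform", 25.0), seed=28)
        data = simulate_outcomes(tte_dgm, pop, horizon=50.0, seed=29)
        follow = 50.0 - data["enroll_time"]
        events = data["delta"] == 1
        assert np.all(data.loc[events, "T"] <= follow[events] + 1e-12)
        np.testing.assert_allclose(data.loc[~events, "T"], follow[~events])
        np.testing.assert_allclose(
            data["T"], np.minimum(data["event_time_latent"], follow)
        )

    def test_horizon_misuse_raises(self, continuous_dgm, tte_dgm):
        pop = sample_population(continuous_dgm, 20, "instant", seed=1)
        with pytest.raises(ValueError, match="horizon"):
            simulate_outcomes(continuous_dgm, pop, horizon=10.0, seed=1)
        pop_t = sample_population(tte_dgm, 20, "instant", seed=1)
        with pytest.raises(ValueError, match="horizon"):
            simulate_outcomes(tte_dgm, pop_t, None, seed=1)


class TestCalibrationAndTruth:
    def test_calibrated_intercept_hits_target(self, registry):
        dgm = registry["binary_ss100_null"].dgm
        pop = sample_population(
            DGMSpec("binary", dgm.covariates, phi=0.0, terms=dgm.terms,
                    beta0=dgm.beta0, max_ss=400_000),
            400_000, "instant", seed=31,
        )
        # Null scenario: eta has no treatment contribution, so mean expit(eta)
        # is the marginal control risk.
        assert special.expit(pop["eta"]).mean() == pytest.approx(0.3, abs=0.005)

    def test_calibration_requires_binary(self, continuous_dgm):
        with pytest.raises(ValueError, match="binary"):
            calibrate_intercept(continuous_dgm, 0.3)

    def test_diff_means_collapsible_exact(self, continuous_dgm):
        assert true_marginal_estimand(continuous_dgm, EstimandKind.DIFF_MEANS) == -0.5

    def test_null_effects_give_null_estimands(self, registry):
        dgm_b = registry["binary_ss100_null"].dgm
        rr = true_marginal_estimand(dgm_b, EstimandKind.RELATIVE_RISK, mc_n=50_000, seed=32)
        assert rr == pytest.approx(1.0, abs=1e-12)
        dgm_t = registry["tte_ss100_null"].dgm
        hr = true_marginal_estimand(dgm_t, EstimandKind.HAZARD_RATIO, mc_n=50_000, seed=33)
        assert hr == pytest.approx(1.0, abs=1e-12)

    def test_marginal_or_attenuated_versus_conditional(self, registry):
        dgm = registry["binary_ss100_eff2"].dgm  # phi = -0.99
        marg_or = true_marginal_estimand(dgm, EstimandKind.ODDS_RATIO, mc_n=400_000, seed=34)
        cond_or = math.exp(dgm.phi)
        # Non-collapsibility: the marginal OR lies between the conditional OR and 1.
        assert cond_or < marg_or < 1.0
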