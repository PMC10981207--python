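"""Outcome-model tests: priors, likelihood oracles, and posterior samplers."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from scipy import special
from scipy.integrate import quad

from bayesadapt.dgm import sample_population, simulate_outcomes
from bayesadapt.models import (
    ModelSpec,
    SamplerConfig,
    design_matrix,
    fit_posterior,
    log_likelihood,
    resolve_priors,
)
from bayesadapt.splines import SplineConfig, ispline_basis, mspline_basis


class TestModelSpec:
    def test_requires_treatment_term(self):
        with pytest.raises(ValueError, match="'A'"):
            ModelSpec("normal", ("X1",))

    def test_informative_priors_need_centers(self):
        with pytest.raises(ValueError, match="prior_centers"):
            ModelSpec("normal", ("A", "X1"), prior_mode="centered")

    def test_unadjusted_flag(self):
        assert ModelSpec("normal", ("A",)).is_unadjusted
        assert not ModelSpec("normal", ("A", "X1")).is_unadjusted


class TestDesignMatrix:
    def test_square_and_interaction_terms(self):
        data = pd.DataFrame({"A": [0.0, 1.0], "X": [2.0, 3.0]})
        X = design_matrix(("A", "X", "X^2", "A:X"), data)
        np.testing.assert_allclose(X[:, 2], [4.0, 9.0])
        np.testing.assert_allclose(X[:, 3], [0.0, 3.0])

    def test_a_override_switches_interactions(self):
        data = pd.DataFrame({"A": [0.0, 1.0], "X": [2.0, 3.0]})
        X = design_matrix(("A", "A:X"), data, a_override=1.0)
        np.testing.assert_allclose(X[:, 0], [1.0, 1.0])
        np.testing.assert_allclose(X[:, 1], [2.0, 3.0])


class TestResolvePriors:
    def test_autoscaling_normal_family(self, normal_data):
        spec = ModelSpec("normal", ("A", "X"))
        pri = resolve_priors(spec, normal_data)
        s_y = normal_data["Y"].std(ddof=1)
        assert pri.intercept_loc == pytest.approx(normal_data["Y"].mean())
        assert pri.intercept_scale == pytest.approx(2.5 * s_y)
        assert pri.sigma_rate == pytest.approx(1.0 / s_y)
        for j, term in enumerate(("A", "X")):
            s_x = normal_data[term].std(ddof=1)
            assert pri.locs[j] == 0.0
            assert pri.scales[j] == pytest.approx(2.5 * s_y / s_x)

    def test_logistic_unit_outcome_scale(self, normal_data):
        data = normal_data.assign(Y=(normal_data["Y"] > 0).astype(float))
        pri = resolve_priors(ModelSpec("bernoulli_logit", ("A", "X")), data)
        assert pri.intercept_loc == 0.0
        assert pri.intercept_scale == pytest.approx(2.5)
        assert pri.scales[1] == pytest.approx(2.5 / data["X"].std(ddof=1))

    def test_strong_prior_centers_and_tightens(self, normal_data):
        spec = ModelSpec(
            "normal", ("A", "X"), prior_mode="strong", prior_centers={"X": 0.8}
        )
        pri = resolve_priors(spec, normal_data)
        s_y = normal_data["Y"].std(ddof=1)
        s_x = normal_data["X"].std(ddof=1)
        assert pri.locs[1] == 0.8
        assert pri.scales[1] == pytest.approx(s_y / s_x)
        # Treatment prior stays weak and zero-centered even in informative modes.
        assert pri.locs[0] == 0.0
        assert pri.scales[0] == pytest.approx(2.5 * s_y / normal_data["A"].std(ddof=1))

    def test_zero_variance_column_raises(self):
        data = pd.DataFrame({"A": [1.0, 1.0, 1.0], "Y": [0.0, 1.0, 2.0]})
        with pytest.raises(ValueError, match="zero variance"):
            resolve_priors(ModelSpec("normal", ("A",)), data)


class TestLogLikelihood:
    def test_normal_single_point(self):
        data = pd.DataFrame({"A": [1.0], "Y": [0.5]})
        # y == eta, sigma = 1: density is the standard normal mode.
        ll = log_likelihood(
            ModelSpec("normal", ("A",)), {"beta": [0.0, 0.5], "sigma": 1.0}, data
        )
        assert ll == pytest.approx(-0.5 * math.log(2 * math.pi))

    def test_logistic_even_odds(self):
        data = pd.DataFrame({"A": [0.0, 1.0], "Y": [1.0, 0.0]})
        ll = log_likelihood(ModelSpec("bernoulli_logit", ("A",)), {"beta": [0.0, 0.0]}, data)
        assert ll == pytest.approx(2 * math.log(0.5))

    def test_ph_likelihood_quadrature_oracle(self):
        spline = SplineConfig(knots=(0.0, 15.0, 50.0), degree=3)
        rng = np.random.default_rng(1)
        psi = rng.dirichlet(np.ones(spline.size))
        data = pd.DataFrame({"A": [1.0, 0.0], "T": [12.0, 30.0], "delta": [1, 0]})
        beta = np.array([0.1, -0.4])
        ll = log_likelihood(
            ModelSpec("ph_mspline", ("A",)), {"beta": beta, "psi": psi}, data, spline
        )
        # Reference: h(t|x) = M(t) psi * exp(eta), H via numerical integration.
        ref = 0.0
        for t_i, d_i, a_i in zip(data["T"], data["delta"], data["A"]):
            eta = beta[0] + beta[1] * a_i
            cum, _ = quad(lambda s: float(mspline_basis(np.array([s]), spline)[0] @ psi), 0, t_i, limit=200)
            if d_i:
                ref += math.log(float(mspline_basis(np.array([t_i]), spline)[0] @ psi)) + eta
            ref -= cum * math.exp(eta)
        assert ll == pytest.approx(ref, abs=1e-6)

    def test_ispline_equals_integral_inside_likelihood(self):
        spline = SplineConfig(knots=(0.0, 15.0, 50.0), degree=3)
        psi = np.full(spline.size, 1.0 / spline.size)
        t = 23.0
        cum, _ = quad(lambda s: float(mspline_basis(np.array([s]), spline)[0] @ psi), 0, t, limit=200)
        assert float(ispline_basis(np.array([t]), spline)[0] @ psi) == pytest.approx(cum, abs=1e-8)


class TestNormalSampler:
    def test_conjugate_oracle_sigma_fixed(self, normal_data):
        spec = ModelSpec("normal", ("A", "X"))
        cfg = SamplerConfig(chains=3, draws=20_000, sigma_fixed=1.0)
        draws, report = fit_posterior(spec, normal_data, cfg, seed=42)
        assert report.passed

        # Analytic conjugate posterior on the centered scale.
        pri = resolve_priors(spec, normal_data)
        X = design_matrix(spec.terms, normal_data)
        Xd = np.column_stack([np.ones(len(normal_data)), X - pri.column_means])
        y = normal_data["Y"].to_numpy()
        m0 = np.concatenate([[pri.intercept_loc], pri.locs])
        s0 = np.concatenate([[pri.intercept_scale], pri.scales])
        prec = Xd.T @ Xd + np.diag(1.0 / s0**2)
        cov = np.linalg.inv(prec)
        mean_c = cov @ (Xd.T @ y + m0 / s0**2)
        mean = mean_c.copy()
        mean[0] -= mean_c[1:] @ pri.column_means

        emp_mean = draws.coefs.mean(axis=0)
        np.testing.assert_allclose(emp_mean[1:], mean[1:], atol=0.01)
        assert emp_mean[0] == pytest.approx(mean[0], abs=0.01)
        # Marginal SDs of the slope block match the conjugate covariance.
        np.testing.assert_allclose(
            draws.coefs[:, 1:].std(axis=0), np.sqrt(np.diag(cov)[1:]), rtol=0.05
        )

    def test_prior_only_reproduces_prior(self, normal_data):
        spec = ModelSpec("normal", ("A", "X"))
        pri = resolve_priors(spec, normal_data)
        cfg = SamplerConfig(chains=2, draws=20_000, prior_only=True)
        draws, _ = fit_posterior(spec, normal_data, cfg, seed=9)
        # Slopes are unaffected by uncentering; check their prior moments.
        assert draws.coefs[:, 1].mean() == pytest.approx(0.0, abs=0.05 * pri.scales[0])
        assert draws.coefs[:, 1].std() == pytest.approx(pri.scales[0], rel=0.03)
        assert draws.coefs[:, 2].std() == pytest.approx(pri.scales[1], rel=0.03)
        assert draws.sigma.mean() == pytest.approx(pri.s_y, rel=0.05)

    def test_seed_determinism(self, normal_data, fast_sampler):
        spec = ModelSpec("normal", ("A", "X"))
        d1, _ = fit_posterior(spec, normal_data, fast_sampler, seed=5)
        d2, _ = fit_posterior(spec, normal_data, fast_sampler, seed=5)
        d3, _ = fit_posterior(spec, normal_data, fast_sampler, seed=6)
        np.testing.assert_array_equal(d1.coefs, d2.coefs)
        assert not np.array_equal(d1.coefs, d3.coefs)


class TestGLMRecovery:
    def test_logistic_parameter_recovery_n5000(self, registry):
        dgm = registry["binary_ss100_eff2"].dgm  # phi = -0.99
        big = type(dgm)(
            "binary", dgm.covariates, phi=dgm.phi, terms=dgm.terms,
            beta0=dgm.beta0, max_ss=5000,
        )
        pop = sample_population(big, 5000, "instant", seed=100)
        data = simulate_outcomes(big, pop, None, seed=101)
        spec = ModelSpec("bernoulli_logit", ("A", "X1", "X2", "X3", "X3^2", "X5"))
        draws, report = fit_posterior(spec, data, SamplerConfig(chains=2, draws=1000), seed=102)
        assert report.passed
        post_mean = draws.coefs.mean(axis=0)
        truth = [dgm.beta0, dgm.phi, 1.0, -0.5, 1.0, -0.1, 0.5]
        np.testing.assert_allclose(post_mean, truth, atol=0.25)

    def test_ph_recovers_treatment_sign_and_magnitude(self, tte_dgm):
        big = type(tte_dgm)(
            "tte", tte_dgm.covariates, phi=-0.6, terms=tte_dgm.terms,
            baseline_rate=0.02, max_ss=2000,
        )
        pop = sample_population(big, 2000, "instant", seed=110)
        data = simulate_outcomes(big, pop, horizon=50.0, seed=111)
        spec = ModelSpec("ph_mspline", ("A", "X1", "X3"))
        draws, _ = fit_posterior(
            spec, data, SamplerConfig(chains=2, draws=500), seed=112, time_upper=50.0
        )
        phi_hat = draws.coefs[:, 1].mean()
        assert phi_hat == pytest.approx(-0.6, abs=0.2)
        # Simplex coefficients stay on the simplex.
        np.testing.assert_allclose(draws.psi.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(draws.psi >= 0)

    def test_needs_both_arms(self, normal_data):
        one_arm = normal_data.assign(A=1.0)
        with pytest.raises(ValueError, match="per arm"):
            fit_posterior(ModelSpec("normal", ("A",)), one_arm, SamplerConfig(chains=1, draws=10), seed=0)
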