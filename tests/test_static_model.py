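import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.optimize import minimize

from fevalence import (
    OutcomeSequence,
    SPVParams,
    StaticValenceModel,
    level2_free_energy,
    predict,
    run_spv_agent,
    sample_outcomes,
    sigmoid,
    update_posterior,
)
from fevalence.static_model import quadratic_trial_objective


class TestSigmoid:
    def test_symmetry_point(self):
        assert sigmoid(0.0) == pytest.approx(0.5)

    def test_logistic_symmetry(self):
        for x in (0.3, 1.7, 9.0):
            assert sigmoid(x) + sigmoid(-x) == pytest.approx(1.0)

    def test_saturation(self):
        assert sigmoid(20.0) == pytest.approx(1.0, abs=1e-8)
        assert sigmoid(-50.0) >= 0.0

    def test_strictly_increasing(self):
        x = np.linspace(-10, 10, 101)
        assert np.all(np.diff(sigmoid(x)) > 0)


class TestPrediction:
    def test_neutral_state(self):
        mu1_hat, sigma1_hat = predict(0.0)
        assert mu1_hat == pytest.approx(0.5)
        assert sigma1_hat == pytest.approx(0.25)

    def test_confident_limit(self):
        mu1_hat, sigma1_hat = predict(30.0)
        assert mu1_hat == pytest.approx(1.0, abs=1e-9)
        assert sigma1_hat == pytest.approx(0.0, abs=1e-9)

    def test_hand_evaluated_values(self):
        # mu2 = 1: s(1) = 1/(1+e^-1) = 0.7310585786, variance p(1-p)
        mu1_hat, sigma1_hat = predict(1.0)
        assert mu1_hat == pytest.approx(0.7310585786300049)
        assert sigma1_hat == pytest.approx(0.7310585786300049 * (1 - 0.7310585786300049))


class TestPosteriorUpdate:
    def test_hand_evaluated_update(self):
        # mu2=0, sigma2=1, u=1: sigma1_hat=0.25 so 1/sigma_new = 1.25,
        # sigma_new = 0.8, delta1 = 0.5, mu_new = 0.8*0.5 = 0.4
        mu_new, s_new, d1 = update_posterior(0.0, 1.0, 1)
        assert d1 == pytest.approx(0.5)
        assert s_new == pytest.approx(0.8)
        assert mu_new == pytest.approx(0.4)

    def test_update_direction_and_symmetry(self):
        up, s1, d1 = update_posterior(0.0, 1.0, 1)
        dn, s0, d0 = update_posterior(0.0, 1.0, 0)
        assert d1 == pytest.approx(0.5) and up > 0
        assert dn == pytest.approx(-up)
        assert s0 == pytest.approx(s1)

    def test_variance_strictly_shrinks(self):
        for mu in (-2.0, 0.0, 3.0):
            for s in (0.1, 1.0, 5.0):
                _, s_new, _ = update_posterior(mu, s, 1)
                assert 0 < s_new < s

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            update_posterior(0.0, 1.0, 2)
        with pytest.raises(ValueError):
            update_posterior(0.0, -1.0, 1)

    def test_closed_form_minimizes_trial_objective(self, rng):
        # independent route: numerical minimization of the variational
        # trial objective over (mu2, log sigma2)
        for _ in range(25):
            mu0 = rng.uniform(-3, 3)
            s0 = rng.uniform(0.1, 2.0)
            u = int(rng.integers(0, 2))
            mu_new, s_new, _ = update_posterior(mu0, s0, u)
            res = minimize(
                lambda th: quadratic_trial_objective(th[0], np.exp(th[1]), u, mu0, s0),
                [mu0, np.log(s0)],
                method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 2000},
            )
            assert abs(mu_new - res.x[0]) < 1e-3
            assert abs(s_new - np.exp(res.x[1])) / np.exp(res.x[1]) < 1e-2

    def test_update_near_exact_free_energy_minimum(self, rng):
        # the second-order expansion behind the closed form deviates from
        # the exact Gaussian-expectation optimum by O(sigma^3)
        for _ in range(10):
            mu0 = rng.uniform(-2, 2)
            s0 = rng.uniform(0.1, 1.5)
            u = int(rng.integers(0, 2))
            mu_new, s_new, _ = update_posterior(mu0, s0, u)
            res = minimize(
                lambda th: level2_free_energy(th[0], np.exp(th[1]), u, mu0, s0),
                [mu_new, np.log(s_new)],
                method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 2000},
            )
            assert abs(mu_new - res.x[0]) < 0.15
            assert abs(s_new - np.exp(res.x[1])) / np.exp(res.x[1]) < 0.15


class TestFreeEnergy:
    def test_expected_input_has_lower_free_energy(self):
        F1 = level2_free_energy(3.0, 0.5, 1, 3.0, 0.5)
        F0 = level2_free_energy(3.0, 0.5, 0, 3.0, 0.5)
        assert F1 < F0

    def test_complexity_vanishes_when_posterior_equals_prior(self):
        # with q = p the KL term is zero, so F reduces to expected surprise,
        # which tends to zero as the prediction becomes certain and correct
        F = level2_free_energy(12.0, 1e-4, 1, 12.0, 1e-4)
        assert F == pytest.approx(0.0, abs=1e-4)

    def test_matches_adaptive_quadrature(self, rng):
        for _ in range(12):
            mu = rng.uniform(-3, 3)
            s2 = rng.uniform(0.05, 2.5)
            pm = rng.uniform(-3, 3)
            ps2 = rng.uniform(0.05, 2.5)
            u = int(rng.integers(0, 2))
            sd = np.sqrt(s2)

            def integrand(x):
                logp = -np.logaddexp(0.0, -x if u == 1 else x)
                dens = np.exp(-((x - mu) ** 2) / (2 * s2)) / (sd * np.sqrt(2 * np.pi))
                return logp * dens

            acc, _ = quad(integrand, mu - 12 * sd, mu + 12 * sd, limit=200)
            kl = 0.5 * (np.log(ps2 / s2) + (s2 + (mu - pm) ** 2) / ps2 - 1.0)
            assert level2_free_energy(mu, s2, u, pm, ps2) == pytest.approx(
                kl - acc, abs=1e-8
            )

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError):
            level2_free_energy(0.0, -1.0, 1, 0.0, 1.0)


class TestAgentTrajectories:
    def test_unregulated_variance_strictly_decreases(self, reference_outcomes):
        trace = run_spv_agent(reference_outcomes, SPVParams())
        s2 = trace["sigma2_post"].to_numpy()
        assert np.all(np.diff(s2) < 0)
        assert np.all(s2 > 0)
        # no regulation: carried variance equals the Bayesian posterior
        assert np.allclose(s2, trace["sigma2_pre"].to_numpy())

    def test_unregulated_prediction_converges_to_half(self, reference_schedule):
        finals = []
        for seed in range(5):
            oc = sample_outcomes(reference_schedule, seed)
            trace = run_spv_agent(oc, SPVParams())
            finals.append(sigmoid(trace["mu2"].iloc[-1]))
        assert abs(np.mean(finals) - 0.5) < 0.05

    def test_constant_input_gives_monotone_tendency(self):
        oc = OutcomeSequence(u=np.ones(50, dtype=int), stages=np.full(50, "a", dtype=object))
        for params in (SPVParams(), SPVParams(alpha=0.8, tau=-0.13)):
            trace = run_spv_agent(oc, params)
            assert np.all(np.diff(trace["mu2"].to_numpy()) >= 0)

    def test_outcome_relabelling_negates_tendency_trajectory(self, reference_outcomes):
        params = SPVParams(alpha=0.4, tau=-0.13)
        trace = run_spv_agent(reference_outcomes, params)
        flipped = OutcomeSequence(
            u=1 - reference_outcomes.u, stages=reference_outcomes.stages
        )
        trace_f = run_spv_agent(flipped, params)
        assert np.allclose(trace_f["mu2"], -trace["mu2"], atol=1e-10)
        assert np.allclose(trace_f["F"], trace["F"], atol=1e-10)
        assert np.allclose(trace_f["sigma2_post"], trace["sigma2_post"], atol=1e-10)

    def test_variance_stays_positive_across_parameter_grid(self, reference_outcomes):
        # moods much below ~-0.3 enter the runaway-inflation regime in
        # which estimation uncertainty grows without bound (see docs)
        for alpha in (0.0, 0.4, 1.0):
            for tau in (-0.25, 0.0, 0.3):
                trace = run_spv_agent(
                    reference_outcomes, SPVParams(alpha=alpha, tau=tau)
                )
                assert np.all(trace["sigma2_pre"] > 0)
                assert np.all(trace["sigma2_post"] > 0)

    def test_trace_bookkeeping_invariants(self, reference_outcomes):
        trace = run_spv_agent(reference_outcomes, SPVParams(alpha=0.4, tau=-0.13))
        assert np.allclose(trace["delta1"], trace["u"] - trace["mu1_hat"])
        assert np.all((trace["mu1_hat"] > 0) & (trace["mu1_hat"] < 1))
        assert np.isnan(trace["V"].iloc[0]) and np.isfinite(trace["V"].iloc[1])
        assert trace["emotion"].iloc[0] == "undefined"
        assert trace["emotion"].iloc[1] == "undefined"
        assert set(trace["emotion"].iloc[2:]) <= {
            "happiness", "unhappiness", "hope", "fear", "neutral_surprise",
            "relief", "disappointment",
        }
        # valence telescopes to the net free-energy change
        V = trace["V"].to_numpy()
        assert np.nansum(V) == pytest.approx(trace["F"].iloc[0] - trace["F"].iloc[-1])


class TestModelResultsAPI:
    def test_fit_matches_functional_route(self, reference_outcomes):
        res = StaticValenceModel(reference_outcomes, alpha=0.4, tau=-0.13).fit()
        direct = run_spv_agent(reference_outcomes, SPVParams(alpha=0.4, tau=-0.13))
        pd.testing.assert_frame_equal(res.trace, direct)

    def test_from_dataframe_roundtrip(self, reference_outcomes):
        frame = reference_outcomes.to_frame()
        res = StaticValenceModel.from_dataframe(frame, alpha=0.4, tau=-0.13).fit()
        direct = run_spv_agent(reference_outcomes, SPVParams(alpha=0.4, tau=-0.13))
        pd.testing.assert_frame_equal(res.trace, direct)

    def test_summary_reports_key_quantities(self, reference_outcomes):
        res = StaticValenceModel(reference_outcomes, alpha=0.4, tau=-0.13).fit()
        text = res.summary()
        assert "sensitiveness alpha" in text and "0.400" in text
        assert "mood tau" in text and "-0.130" in text
        assert f"{res.final_prediction:.4f}" in text

    def test_plain_array_input(self):
        res = StaticValenceModel([1, 1, 0, 1, 0, 1]).fit()
        assert len(res.trace) == 6
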