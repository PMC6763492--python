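"""Tests of perception, policy evaluation, action selection and learning."""

import dataclasses

import numpy as np
import pytest

from attnmdp.core import FactorSpec, GenerativeModel, ModalitySpec, PolicySet
from attnmdp.engine import (
    DirichletCounts,
    EngineConfig,
    bayesian_model_average,
    expected_free_energy,
    expected_outcomes,
    free_energy,
    infer_states,
    novelty_term,
    policy_posterior,
    select_action,
    update_counts,
)
from conftest import CONVERGED
from toys import (
    efe_enumeration_oracle,
    exact_marginals,
    max_kl,
    random_observations,
    random_single_factor_model,
    random_two_factor_model,
)


def _static_model(A_col, D):
    """One static factor, one modality."""
    n = len(D)
    no = A_col.shape[0]
    return GenerativeModel(
        factors=(FactorSpec("state", tuple(f"l{i}" for i in range(n))),),
        modalities=(ModalitySpec("obs", tuple(f"o{i}" for i in range(no))),),
        A={"obs": A_col},
        B={"state": np.eye(n)[:, :, None]},
        C={"obs": np.zeros(no)},
        D={"state": np.asarray(D, dtype=float)},
        policies=PolicySet(np.zeros((1, 1, 1), dtype=int)),
    )


class TestInferStates:
    def test_deterministic_likelihood_one_observation(self):
        model = _static_model(np.eye(3), np.full(3, 1 / 3))
        ba = infer_states(model, [{"obs": 1}], [], CONVERGED)
        assert np.allclose(ba.s["state"][0], [0, 1, 0], atol=1e-9)

    def test_zero_precision_modality_leaves_prior(self, colour_shape_z0):
        model, make_process = colour_shape_z0
        # agent sits at the shape quadrant and sees a triangle; with
        # zeta_shape = 0 under rule categorise-colour, the shape posterior
        # stays at its prior
        obs = {"rule": 0, "where": 2, "colours": 3, "shapes": 2}
        ba = infer_states(model, [obs], [], CONVERGED)
        assert np.allclose(ba.s["shape"][0], 1 / 3, atol=1e-9)

    def test_matches_exact_bayes_on_single_factor(self):
        rng = np.random.default_rng(123)
        for _ in range(30):
            model = random_single_factor_model(rng)
            obs, acts = random_observations(rng, model, int(rng.integers(1, 4)))
            ba = infer_states(model, obs, acts, CONVERGED)
            exact, _ = exact_marginals(model, obs, acts)
            assert max_kl(exact, ba) < 1e-6

    def test_two_factor_mean_field_close_to_exact(self):
        rng = np.random.default_rng(321)
        for _ in range(20):
            model = random_two_factor_model(rng, coupling=0.05)
            obs, acts = random_observations(rng, model, int(rng.integers(1, 4)))
            ba = infer_states(model, obs, acts, CONVERGED)
            exact, _ = exact_marginals(model, obs, acts)
            assert max_kl(exact, ba) < 1e-3

    def test_future_timesteps_are_pure_predictions(self):
        rng = np.random.default_rng(5)
        model = random_single_factor_model(rng)
        obs, acts = random_observations(rng, model, 2)
        acts = acts + [{"state": 1}]
        ba = infer_states(model, obs, acts, CONVERGED, horizon=3)
        expect = model.B["state"][:, :, 1] @ ba.s["state"][1]
        assert np.allclose(ba.s["state"][2], expect, atol=1e-8)

    def test_posteriors_normalised(self):
        rng = np.random.default_rng(9)
        model = random_two_factor_model(rng)
        obs, acts = random_observations(rng, model, 3)
        ba = infer_states(model, obs, acts, EngineConfig())
        for S in ba.s.values():
            assert np.allclose(S.sum(axis=1), 1.0, atol=1e-8)

    def test_invalid_observation_rejected(self):
        model = _static_model(np.eye(3), np.full(3, 1 / 3))
        with pytest.raises(ValueError, match="outside"):
            infer_states(model, [{"obs": 7}], [], CONVERGED)


class TestFreeEnergy:
    def test_flat_everything_gives_outcome_entropy(self):
        # posterior = prior and uniform likelihood: no complexity, and the
        # accuracy term contributes -ln(1/N) per observation
        A = np.full((4, 3), 0.25)
        model = _static_model(A, np.full(3, 1 / 3))
        obs = [{"obs": 2}, {"obs": 0}]
        ba = infer_states(model, obs, [{}], CONVERGED)
        F = free_energy(ba, obs, [{}], model)
        assert np.isclose(F, 2 * np.log(4), atol=1e-9)

    def test_equals_negative_log_evidence_at_exact_posterior(self):
        rng = np.random.default_rng(77)
        for _ in range(20):
            model = random_single_factor_model(rng, stochastic_B=False)
            obs, acts = random_observations(rng, model, int(rng.integers(1, 4)))
            ba = infer_states(model, obs, acts, CONVERGED)
            _, evidence = exact_marginals(model, obs, acts)
            F = free_energy(ba, obs, acts, model)
            assert abs(F + np.log(evidence)) < 1e-6

    def test_depends_on_past_only(self):
        # identical observations and beliefs => identical F, whatever the
        # policy's future actions would be
        rng = np.random.default_rng(8)
        model = random_single_factor_model(rng)
        obs, acts = random_observations(rng, model, 2)
        ba = infer_states(model, obs, acts, CONVERGED)
        assert free_energy(ba, obs, acts, model) == free_energy(
            ba, obs, acts, model
        )


class TestExpectedOutcomes:
    def test_one_hot_beliefs_pick_a_column(self):
        A = {"m": np.array([[0.6, 0.1], [0.4, 0.9]])}
        out = expected_outcomes(A, {"f": np.array([0.0, 1.0])}, ["f"])
        assert np.allclose(out["m"], [0.1, 0.9])

    def test_uniform_beliefs_identity_likelihood(self):
        A = {"m": np.eye(4)}
        out = expected_outcomes(A, {"f": np.full(4, 0.25)}, ["f"])
        assert np.allclose(out["m"], 0.25)

    def test_mixture_oracle(self):
        A = {"m": np.array([[0.5, 0.2, 0.9], [0.5, 0.8, 0.1]])}
        s = np.array([0.2, 0.3, 0.5])
        out = expected_outcomes(A, {"f": s}, ["f"])
        assert np.allclose(out["m"], A["m"] @ s, atol=1e-12)


class TestExpectedFreeEnergy:
    def test_uniform_likelihood_has_zero_epistemic_value(self):
        A = np.full((4, 3), 0.25)
        model = _static_model(A, np.full(3, 1 / 3))
        efe = expected_free_energy(model, {"state": np.array([0.2, 0.5, 0.3])})
        assert abs(efe["epistemic"]) < 1e-12

    def test_terms_match_enumeration_oracle(self):
        rng = np.random.default_rng(1234)
        for _ in range(10):
            model = random_two_factor_model(rng, coupling=0.3)
            beliefs = {
                f.name: rng.dirichlet(np.ones(f.n)) for f in model.factors
            }
            got = expected_free_energy(model, beliefs, A=model.A)
            want = efe_enumeration_oracle(model, beliefs)
            for k in want:
                assert np.isclose(got[k], want[k], atol=1e-8), k

    def test_risk_ambiguity_identity(self):
        # risk + ambiguity = -(epistemic + extrinsic) with novelty off
        rng = np.random.default_rng(555)
        for _ in range(25):
            model = random_two_factor_model(rng, coupling=0.4)
            model = dataclasses.replace(
                model,
                C={m.name: rng.normal(0, 2, m.n) for m in model.modalities},
            )
            beliefs = {
                f.name: rng.dirichlet(np.ones(f.n)) for f in model.factors
            }
            efe = expected_free_energy(model, beliefs, A=model.A)
            lhs = efe["risk"] + efe["ambiguity"]
            rhs = -(efe["epistemic"] + efe["extrinsic"])
            assert abs(lhs - rhs) < 1e-8

    def test_nonnegative_terms(self):
        rng = np.random.default_rng(99)
        model = random_two_factor_model(rng, coupling=0.2)
        beliefs = {f.name: rng.dirichlet(np.ones(f.n)) for f in model.factors}
        efe = expected_free_energy(model, beliefs, A=model.A)
        assert efe["risk"] >= -1e-12
        assert efe["ambiguity"] >= -1e-12
        assert efe["epistemic"] >= -1e-12


class TestPolicyPosterior:
    def test_zero_gamma_equal_F_uniform(self):
        cfg = EngineConfig(gamma=0.0)
        post = policy_posterior(np.zeros(3), np.array([1.0, 5.0, 9.0]), cfg)
        assert np.allclose(post, 1 / 3)

    def test_direct_softmax_evaluation(self):
        cfg = EngineConfig(gamma=1.0)
        post = policy_posterior(np.zeros(2), np.array([0.0, np.log(9.0)]), cfg)
        assert np.allclose(post, [0.9, 0.1], atol=1e-12)

    def test_shift_invariance(self):
        cfg = EngineConfig(gamma=2.0)
        G = np.array([0.3, 1.2, -0.5])
        a = policy_posterior(np.zeros(3), G, cfg)
        b = policy_posterior(np.zeros(3), G + 10.0, cfg)
        assert np.allclose(a, b, atol=1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            policy_posterior(np.zeros(2), np.array([0.0, np.inf]), EngineConfig())


class TestSelectAction:
    def _policies(self):
        acts = np.zeros((2, 1, 1), dtype=int)
        acts[1, 0, 0] = 1
        return PolicySet(acts)

    def test_one_hot_posterior_deterministic(self):
        rng = np.random.default_rng(0)
        pol = self._policies()
        for _ in range(10):
            assert select_action(np.array([0.0, 1.0]), pol, rng)[0] == 1

    def test_even_posterior_samples_evenly(self):
        rng = np.random.default_rng(42)
        pol = self._policies()
        draws = [select_action(np.array([0.5, 0.5]), pol, rng)[0] for _ in range(10000)]
        assert abs(np.mean(draws) - 0.5) < 0.02

    def test_shared_action_mass_is_pooled(self):
        acts = np.zeros((3, 1, 1), dtype=int)
        acts[2, 0, 0] = 1  # policies 0 and 1 share action 0
        pol = PolicySet(acts)
        rng = np.random.default_rng(1)
        for _ in range(10):
            assert select_action(np.array([0.5, 0.5, 0.0]), pol, rng)[0] == 0


class TestBayesianModelAverage:
    def test_convex_mixture(self):
        b1 = {"f": np.array([1.0, 0.0])}
        b2 = {"f": np.array([0.0, 1.0])}
        out = bayesian_model_average(np.array([0.5, 0.5]), [b1, b2])
        assert np.allclose(out["f"], [0.5, 0.5])

    def test_one_hot_posterior_returns_that_policy(self):
        b1 = {"f": np.array([0.9, 0.1])}
        b2 = {"f": np.array([0.2, 0.8])}
        out = bayesian_model_average(np.array([0.0, 1.0]), [b1, b2])
        assert np.allclose(out["f"], b2["f"])


class TestDirichletLearning:
    def _counts(self, shape=(2, 3), a0=0.25):
        return DirichletCounts(a={"m": np.full(shape, a0)}, a0=a0)

    def test_zero_eta_leaves_counts(self):
        c = self._counts()
        before = c.a["m"].copy()
        update_counts(c, {"m": 1}, {"f": np.array([1.0, 0.0, 0.0])}, 0.0, ["f"])
        assert np.array_equal(c.a["m"], before)

    def test_one_hot_increment(self):
        c = self._counts()
        update_counts(c, {"m": 1}, {"f": np.array([0.0, 1.0, 0.0])}, 1.0, ["f"])
        expect = np.full((2, 3), 0.25)
        expect[1, 1] += 1.0
        assert np.allclose(c.a["m"], expect)

    def test_counts_converge_to_true_column(self):
        c = self._counts(a0=0.25)
        for _ in range(50):
            update_counts(c, {"m": 0}, {"f": np.array([1.0, 0.0, 0.0])}, 1.0, ["f"])
        col = c.expected_likelihood()["m"][:, 0]
        assert np.abs(col - np.array([1.0, 0.0])).sum() < 0.05

    def test_novelty_hand_value(self):
        c = DirichletCounts(a={"m": np.ones((2, 2))}, a0=1.0)
        val = novelty_term(
            c, {"m": np.array([0.5, 0.5])}, {"f": np.array([1.0, 0.0])}, ["f"]
        )
        assert np.isclose(val, 0.25, atol=1e-12)

    def test_novelty_shrinks_with_counts(self):
        o = {"m": np.array([0.5, 0.5])}
        s = {"f": np.array([1.0, 0.0])}
        small = DirichletCounts(a={"m": np.ones((2, 2))}, a0=1.0)
        big = DirichletCounts(a={"m": np.full((2, 2), 100.0)}, a0=1.0)
        huge = DirichletCounts(a={"m": np.full((2, 2), 1e9)}, a0=1.0)
        v1 = novelty_term(small, o, s, ["f"])
        v2 = novelty_term(big, o, s, ["f"])
        v3 = novelty_term(huge, o, s, ["f"])
        assert v1 > v2 > v3 >= 0
        assert v3 < 1e-9
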