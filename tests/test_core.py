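"""Unit tests for the single-level active-inference machinery."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from apraxim.core import (
    Categorical,
    DegenerateEvidenceError,
    action_marginal,
    entropy,
    expected_free_energy,
    floor_log,
    infer_states,
    kl_divergence,
    policy_posterior,
    sample_action,
    softmax,
    variational_free_energy,
)
from oracles import bayes_posterior_enumeration, random_prior, random_stochastic_matrix


class TestCategorical:
    def test_validates_normalization_and_labels(self):
        with pytest.raises(ValueError):
            Categorical(np.array([0.5, 0.6]))
        with pytest.raises(ValueError):
            Categorical(np.array([1.2, -0.2]))
        with pytest.raises(ValueError):
            Categorical(np.array([0.5, 0.5]), labels=("only_one",))
        c = Categorical.delta(1, 3, ("a", "b", "c"))
        assert c.label_of_mode() == "b"
        assert len(c) == 3

    def test_uniform_entropy(self):
        assert Categorical.uniform(4).entropy() == pytest.approx(np.log(4))


class TestInferStates:
    def test_identity_likelihood_gives_delta(self):
        post = infer_states(Categorical.uniform(4), np.eye(4), obs=2)
        np.testing.assert_allclose(post.probs, [0, 0, 1, 0], atol=1e-12)

    def test_flat_likelihood_returns_prior(self):
        prior = Categorical(np.array([0.6, 0.3, 0.1]))
        A = np.full((5, 3), 0.2)
        post = infer_states(prior, A, obs=3)
        np.testing.assert_allclose(post.probs, prior.probs, atol=1e-12)

    def test_worked_example_matches_enumeration(self):
        prior = Categorical(np.array([0.5, 0.3, 0.2]))
        A = np.array([[0.7, 0.2, 0.1],
                      [0.3, 0.8, 0.9]])
        post = infer_states(prior, A, obs=0)
        np.testing.assert_allclose(post.probs * 0.43, [0.35, 0.06, 0.02], atol=1e-12)
        oracle = bayes_posterior_enumeration(prior.probs, A, 0)
        np.testing.assert_allclose(post.probs, oracle, atol=1e-12)

    @pytest.mark.parametrize("trial", range(25))
    def test_matches_enumeration_oracle_on_random_instances(self, trial):
        rng = np.random.default_rng(trial)
        n_states = int(rng.integers(2, 7))
        n_obs = int(rng.integers(2, 7))
        prior = Categorical(random_prior(rng, n_states))
        A = random_stochastic_matrix(rng, n_obs, n_states)
        obs = int(rng.integers(n_obs))
        post = infer_states(prior, A, obs)
        oracle = bayes_posterior_enumeration(prior.probs, A, obs)
        np.testing.assert_allclose(post.probs, oracle, atol=1e-6)
        assert post.probs.sum() == pytest.approx(1.0, abs=1e-8)

    def test_zero_evidence_raises(self):
        A = np.array([[0.0, 0.0], [1.0, 1.0]])
        with pytest.raises(DegenerateEvidenceError):
            infer_states(Categorical.uniform(2), A, obs=0)


class TestVariationalFreeEnergy:
    def test_posterior_q_gives_negative_log_evidence(self):
        # uniform 4-state prior, identity likelihood: p(o) = 1/4, F = ln 4
        prior = Categorical.uniform(4)
        A = np.eye(4)
        q = Categorical.delta(2, 4)
        F = variational_free_energy(q, prior, A, obs=2)
        assert F == pytest.approx(np.log(4), abs=1e-10)

    @pytest.mark.parametrize("trial", range(20))
    def test_decompositions_agree(self, trial):
        rng = np.random.default_rng(100 + trial)
        prior = Categorical(random_prior(rng, 3))
        A = random_stochastic_matrix(rng, 4, 3)
        q = Categorical(random_prior(rng, 3))
        obs = int(rng.integers(4))
        f1 = variational_free_energy(q, prior, A, obs, form="divergence")
        f2 = variational_free_energy(q, prior, A, obs, form="energy")
        assert f1 == pytest.approx(f2, abs=1e-8)

    def test_minimized_at_exact_posterior(self):
        rng = np.random.default_rng(7)
        prior = Categorical(random_prior(rng, 3))
        A = random_stochastic_matrix(rng, 3, 3)
        obs = 1
        post = infer_states(prior, A, obs)
        f_star = variational_free_energy(post, prior, A, obs)
        for _ in range(300):
            q = Categorical(random_prior(rng, 3))
            assert variational_free_energy(q, prior, A, obs) >= f_star - 1e-9


class TestExpectedFreeEnergy:
    def _single_step(self):
        belief = Categorical(np.array([0.5, 0.5]))
        B = np.stack([np.eye(2)])  # one "stay" action
        A = np.array([[0.9, 0.1], [0.1, 0.9]])
        return belief, B, A

    def test_worked_two_state_instance(self):
        belief, B, A = self._single_step()
        C = floor_log(np.array([0.8, 0.2]))
        G = expected_free_energy(np.array([0]), belief, B, A, C)
        risk = kl_divergence([0.5, 0.5], [0.8, 0.2])
        ambiguity = entropy([0.9, 0.1])
        assert risk == pytest.approx(0.2231435, abs=1e-6)
        assert ambiguity == pytest.approx(0.3250830, abs=1e-6)
        assert G == pytest.approx(risk + ambiguity, abs=1e-10)
        assert G == pytest.approx(0.5482266, abs=1e-6)

    def test_deterministic_likelihood_has_zero_ambiguity(self):
        belief = Categorical(np.array([0.3, 0.7]))
        B = np.stack([np.eye(2), np.array([[0, 1.0], [1.0, 0]])])
        A = np.eye(2)
        C = floor_log(np.array([0.5, 0.5]))  # flat preferences: risk = 0 too? no:
        # with flat preferences risk equals KL(q(o) || uniform) which is
        # nonnegative; zero ambiguity means G is exactly that KL.
        for policy in ([0], [1], [0, 1]):
            G = expected_free_energy(np.array(policy), belief, B, A, C)
            q = belief.probs
            expected_risk = 0.0
            for a in policy:
                q = B[a] @ q
                expected_risk += kl_divergence(A @ q, [0.5, 0.5])
            assert G == pytest.approx(expected_risk, abs=1e-10)

    def test_matching_preferences_have_zero_risk(self):
        belief, B, A = self._single_step()
        q_o = A @ belief.probs
        C = floor_log(q_o)
        G = expected_free_energy(np.array([0]), belief, B, A, C)
        assert G == pytest.approx(entropy([0.9, 0.1]), abs=1e-8)

    def test_additive_over_steps(self):
        belief, B, A = self._single_step()
        C = floor_log(np.array([0.8, 0.2]))
        g1 = expected_free_energy(np.array([0]), belief, B, A, C)
        g2 = expected_free_energy(np.array([0, 0]), belief, B, A, C)
        assert g2 == pytest.approx(2 * g1, abs=1e-10)


class TestPolicyPosterior:
    def test_uniform_prior_zero_energies_is_uniform(self):
        post = policy_posterior(np.full(5, 0.2), 0.0, np.zeros(5))
        np.testing.assert_allclose(post.probs, 0.2, atol=1e-12)

    def test_delta_prior_dominates(self):
        E = np.zeros(4)
        E[2] = 1.0
        post = policy_posterior(E, 0.0, np.ones(4))
        assert post.probs[2] >= 1 - 10e-16

    def test_matches_independent_softmax(self):
        E = np.array([0.5, 0.3, 0.2])
        F = np.array([0.1, 0.7, 0.2])
        G = np.array([1.0, 0.2, 0.5])
        post = policy_posterior(E, F, G)
        logits = np.log(E) - F - G
        expected = np.exp(logits) / np.exp(logits).sum()
        np.testing.assert_allclose(post.probs, expected, atol=1e-10)


class TestSampleAction:
    def test_bitwise_reproducible_under_fixed_seed(self):
        post = Categorical(np.array([0.5, 0.2, 0.3]))
        policies = np.array([[0, 1], [1, 0], [2, 2]])
        draws1 = [sample_action(post, policies, 2.0, np.random.default_rng(9))
                  for _ in range(10)]
        draws2 = [sample_action(post, policies, 2.0, np.random.default_rng(9))
                  for _ in range(10)]
        assert draws1 == draws2

    def test_action_marginal_sums_policy_mass(self):
        post = Categorical(np.array([0.5, 0.2, 0.3]))
        policies = np.array([[0, 1], [1, 0], [0, 2]])
        m = action_marginal(post, policies, n_actions=3)
        np.testing.assert_allclose(m, [0.8, 0.2, 0.0], atol=1e-12)

    def test_rejects_negative_precision(self):
        with pytest.raises(ValueError):
            sample_action(Categorical.uniform(2), np.array([[0], [1]]),
                          -1.0, np.random.default_rng(0))


@given(st.lists(st.floats(0.01, 10.0), min_size=2, max_size=6))
def test_softmax_normalizes_and_orders(weights):
    x = np.array(weights)
    p = softmax(x)
    assert p.sum() == pytest.approx(1.0, abs=1e-10)
    assert np.argmax(p) == np.argmax(x)
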