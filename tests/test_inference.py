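"""Belief filtering, expected free energy, policy softmax, trial loop."""

import math
from types import SimpleNamespace

import numpy as np
import pytest

from habitcache import (
    belief_update,
    context_marginal,
    expected_free_energy,
    policy_posterior,
    predict_states,
    run_trial_full,
    select_action,
    state_index,
)
from habitcache.inference import (
    ImpossibleObservationError,
    action_marginal,
    efe_terms,
    evaluate_policies,
)
from habitcache.model import Policy
from habitcache.world import Observation


def delta(idx1: int, n: int = 40) -> np.ndarray:
    v = np.zeros(n)
    v[idx1 - 1] = 1.0
    return v


class TestBeliefUpdate:
    def test_deterministic_transition_and_diagnostic_cue(self, model):
        belief = delta(state_index(6, "A"))
        obs = Observation(location=5, cue="red")
        post = belief_update(belief, "left", obs, model)
        np.testing.assert_allclose(post, delta(state_index(5, "A")), atol=1e-12)

    def test_uninformative_cue_leaves_belief_unchanged(self, model):
        belief = 0.5 * delta(state_index(1, "A")) + 0.5 * delta(state_index(1, "D"))
        post = belief_update(belief, None, Observation(1, "white"), model)
        np.testing.assert_allclose(post, belief, atol=1e-12)

    def test_missed_reward_discounts_the_context(self, model):
        # hand Bayes: P(white@5 | ctx A) = 0.05, P(white@5 | ctx D) = 1
        belief = 0.5 * delta(state_index(6, "A")) + 0.5 * delta(state_index(6, "D"))
        post = belief_update(belief, "left", Observation(5, "white"), model)
        p_a = context_marginal(post)[0]
        assert p_a == pytest.approx(0.05 / 1.05, abs=1e-12)

    def test_impossible_observation_raises(self, model):
        belief = delta(state_index(1, "A"))
        with pytest.raises(ImpossibleObservationError):
            belief_update(belief, None, Observation(9, "red"), model)


class TestPrediction:
    def test_policy_one_lands_on_state_17(self, model):
        belief = delta(state_index(1, "A"))
        pol = model.policy_for_actions(("up", "left", "up", "left"))
        out = predict_states(belief, pol, 0, 4, model)
        np.testing.assert_allclose(out, delta(state_index(5, "A")), atol=1e-12)

    def test_tau_equal_t_is_identity(self, model):
        belief = np.full(40, 1 / 40)
        pol = model.policies[0]
        np.testing.assert_array_equal(predict_states(belief, pol, 2, 2, model), belief)

    def test_context_marginal_is_preserved(self, model):
        belief = np.zeros(40)
        for ctx in "ABCD":
            belief[state_index(1, ctx) - 1] = 0.25
        pol = model.policy_for_actions(("up", "right", "up", "right"))
        out = predict_states(belief, pol, 0, 4, model)
        np.testing.assert_allclose(context_marginal(out), 0.25, atol=1e-12)
        assert out.reshape(10, 4)[9].sum() == pytest.approx(1.0)

    def test_horizon_error(self, model):
        with pytest.raises(ValueError):
            predict_states(np.full(40, 1 / 40), model.policies[0], 0, 5, model)


def toy_model():
    """Two states, two outcomes, hand-set matrices, horizon 4."""
    A = np.array([[0.7, 0.2], [0.3, 0.8]])
    B = {
        "up": np.array([[0.0, 1.0], [1.0, 0.0]]),
        "stay": np.eye(2),
        "left": np.array([[0.9, 0.4], [0.1, 0.6]]),
    }
    lnC = np.log(np.array([0.25, 0.75]))
    with np.errstate(divide="ignore", invalid="ignore"):
        xlogx = np.where(A > 0, A * np.log(A), 0.0)
    return SimpleNamespace(A=A, B=B, lnC=lnC, C=np.exp(lnC), H_A=-xlogx.sum(axis=0))


def brute_force_G(m, actions, belief, t):
    """Direct evaluation of the path integral with explicit scalar loops."""
    total = 0.0
    s = list(belief)
    n_s = len(s)
    n_o = m.A.shape[0]
    for tau in range(t + 1, 5):
        Bm = m.B[actions[tau - 1]]
        s = [sum(Bm[i][j] * s[j] for j in range(n_s)) for i in range(n_s)]
        o = [sum(m.A[i][j] * s[j] for j in range(n_s)) for i in range(n_o)]
        ambiguity = 0.0
        for j in range(n_s):
            h = -sum(
                m.A[i][j] * math.log(m.A[i][j]) for i in range(n_o) if m.A[i][j] > 0
            )
            ambiguity -= h * s[j]
        risk = 0.0
        for i in range(n_o):
            if o[i] > 0:
                risk -= o[i] * (math.log(o[i]) - m.lnC[i])
        total += ambiguity + risk
    return total


class TestExpectedFreeEnergy:
    @pytest.mark.parametrize("actions", [("up", "stay", "up", "left"),
                                         ("left", "left", "up", "stay"),
                                         ("stay", "stay", "stay", "stay")])
    @pytest.mark.parametrize("t", [0, 1, 3])
    def test_matches_brute_force_oracle_on_toy_model(self, actions, t):
        m = toy_model()
        pol = Policy(id=1, actions=actions, trajectory=(0, 0, 0, 0, 0),
                     reaches_reward_location=False)
        belief = np.array([0.35, 0.65])
        got = expected_free_energy(pol, belief, t, m)
        want = brute_force_G(m, actions, belief, t)
        assert got == pytest.approx(want, abs=1e-12)

    def test_zero_when_predictions_equal_preferences_and_A_deterministic(self):
        m = toy_model()
        m.A = np.eye(2)
        m.H_A = np.zeros(2)
        m.lnC = np.log(np.array([0.5, 0.5]))
        m.C = np.exp(m.lnC)
        m.B = {"stay": np.eye(2)}
        pol = Policy(id=1, actions=("stay",) * 4, trajectory=(0,) * 5,
                     reaches_reward_location=False)
        G = expected_free_energy(pol, np.array([0.5, 0.5]), 0, m)
        assert G == pytest.approx(0.0, abs=1e-12)

    def test_every_term_is_non_positive(self, model, rng):
        for _ in range(20):
            w = rng.random(40)
            belief = w / w.sum()
            pol = model.policies[rng.integers(17)]
            t = int(rng.integers(4))
            for _, _, g in efe_terms(pol, belief, t, model):
                assert g <= 1e-12

    def test_flat_preferences_make_distinct_terminals_equivalent(self, topology):
        from habitcache.model import build_model

        m = build_model(utility=0.0, p_reward_model=1.0)
        belief = delta(state_index(1, "A"))
        G = evaluate_policies(m, belief, 0)
        rewarders = [p.id - 1 for p in m.policies if p.reaches_reward_location]
        np.testing.assert_allclose(G[rewarders], G[rewarders[0]], atol=1e-10)


class TestPolicyPosterior:
    def test_equal_G_gives_uniform(self):
        post = policy_posterior(np.zeros(17), 4.0)
        np.testing.assert_allclose(post, 1 / 17, atol=1e-15)

    def test_two_policy_closed_form(self):
        post = policy_posterior(np.array([0.0, -1.0]), 1.0)
        np.testing.assert_allclose(post, [0.7311, 0.2689], atol=1e-4)

    def test_large_gamma_approaches_argmax(self):
        post = policy_posterior(np.array([-1.0, -2.0, -3.0]), 500.0)
        assert post[0] == pytest.approx(1.0, abs=1e-12)

    def test_mask_zeroes_disallowed_policies(self):
        post = policy_posterior(np.zeros(4), 1.0, allowed=np.array([True, False, True, False]))
        np.testing.assert_allclose(post, [0.5, 0.0, 0.5, 0.0], atol=1e-15)

    def test_non_finite_G_rejected(self):
        with pytest.raises(ValueError):
            policy_posterior(np.array([0.0, np.nan]), 1.0)


class TestActionSelection:
    def test_point_mass_posterior_is_deterministic(self, model, rng):
        post = np.zeros(17)
        post[0] = 1.0
        assert select_action(post, model.policies, 0, rng) == "up"

    def test_shared_prefix_gives_common_action(self, model, rng):
        p1 = model.policy_for_actions(("up", "left", "up", "left"))
        p2 = model.policy_for_actions(("up", "left", "up", "right"))
        post = np.zeros(17)
        post[p1.id - 1] = post[p2.id - 1] = 0.5
        assert select_action(post, model.policies, 1, rng) == "left"

    def test_sampling_frequency_matches_marginal(self, model):
        rng = np.random.default_rng(99)
        p_left = model.policy_for_actions(("up", "left", "up", "left"))
        p_right = model.policy_for_actions(("up", "right", "up", "right"))
        post = np.zeros(17)
        post[p_left.id - 1], post[p_right.id - 1] = 0.6, 0.4
        n = 10_000
        lefts = sum(select_action(post, model.policies, 1, rng) == "left" for _ in range(n))
        assert abs(lefts / n - 0.6) < 4 * np.sqrt(0.6 * 0.4 / n)

    def test_marginal_sums_posterior_mass_by_action(self, model):
        post = np.full(17, 1 / 17)
        m = action_marginal(post, model.policies, 0)
        assert m[0] == pytest.approx(1.0)  # every policy starts with "up"


class TestTrialLoop:
    def test_cost_counter_is_68_evaluations(self, model, rng):
        rec = run_trial_full(model, np.full(4, 0.25), "A", 0.95, rng)
        assert rec.n_efe_evals == 4 * 17
        assert rec.n_efe_terms == 17 * (4 + 3 + 2 + 1)

    def test_beliefs_and_posteriors_stay_normalised(self, model, rng):
        rec = run_trial_full(model, np.full(4, 0.25), "A", 0.95, rng)
        assert rec.final_belief.sum() == pytest.approx(1.0, abs=1e-10)
        for post in rec.policy_posteriors:
            assert post.sum() == pytest.approx(1.0, abs=1e-10)

    def test_confident_agent_ends_trial_on_state_17(self):
        from habitcache.model import build_model

        m = build_model(gamma=8.0, utility=6.0, p_reward_model=1.0, stability=1.0)
        rng = np.random.default_rng(3)
        rec = run_trial_full(m, np.array([1.0, 0, 0, 0]), "A", 1.0, rng)
        assert rec.actions == ("up", "left", "up", "left")
        np.testing.assert_allclose(rec.final_belief, delta(state_index(5, "A")), atol=1e-12)
        assert rec.rewarded

    def test_reward_rate_reaches_one_under_ideal_conditions(self):
        from habitcache.model import build_model

        m = build_model(gamma=8.0, utility=6.0, p_reward_model=1.0, stability=1.0)
        rng = np.random.default_rng(11)
        prev = np.full(4, 0.25)
        rewards = []
        for _ in range(15):
            rec = run_trial_full(m, prev, "A", 1.0, rng)
            prev = rec.context_posterior
            rewards.append(rec.rewarded)
        assert all(rewards[-10:])

    def test_fixed_seed_reproduces_a_run_exactly(self, model):
        outs = []
        for _ in range(2):
            rng = np.random.default_rng(42)
            prev = np.full(4, 0.25)
            trace = []
            for _ in range(5):
                rec = run_trial_full(model, prev, "A", 0.95, rng)
                prev = rec.context_posterior
                trace.append((rec.actions, rec.rewarded, rec.final_belief.tobytes()))
            outs.append(trace)
        assert outs[0] == outs[1]
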