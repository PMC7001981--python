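"""Policy-probability caching and the three habitisation schemes.

The cache stores P(pi|s): the probability of each of the 17 policies
conditioned on each of the 40 hidden states. During deliberative processing
it is written by a delta rule weighted by state occupancy,

    P(pi|s) <- P(pi|s) + eta * s_hat(s) * (pi_hat(pi) - P(pi|s)),

which preserves per-state normalisation exactly. Its read-out is the
expectation of the cached column under a state belief,

    E_{s_hat}[P(pi|s)] = sum_i s_hat(i) P(pi|s_i),

and a habit fires when that expectation strictly exceeds the habitisation
threshold ``p_th``. The three schemes differ in *when* the cache is
consulted:

* **Scheme 1** checks once, before the trial starts, under the previous
  trial's final belief; a firing habit replaces the whole trial with
  open-loop execution of the cached policy (beliefs are still filtered, so
  context monitoring survives).
* **Scheme 2** checks during planning: at every decision point, each
  still-executable policy's one-step predicted state is tested; a firing
  habit takes over the remainder of the trial.
* **Scheme 3** checks during policy evaluation: the path integral of a
  policy's expected free energy is interleaved with the cache read-out at
  every predicted step and terminated early on the first threshold
  crossing.

Habitually executed portions of a trial never update the cache.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .inference import (
    TrialRecord,
    _collapsed_posterior,
    belief_update,
    efe_terms,
    evaluate_policies,
    execute_policy_open_loop,
    policy_posterior,
    select_action,
)
from .model import GenerativeModel, Policy
from .world import (
    N_STATES,
    RED,
    TRIAL_LENGTH,
    Observation,
    WorldState,
    initial_observation,
    world_step,
)


@dataclass
class PolicyCache:
    """Cached policy probabilities P(pi|s), one column per hidden state."""

    table: np.ndarray  # (n_policies, n_states)
    eta: float = 0.85
    p_th: float = 0.90

    def __post_init__(self) -> None:
        if not 0.0 < self.eta <= 1.0:
            raise ValueError(f"eta must be in (0, 1], got {self.eta}")
        self.table = np.asarray(self.table, dtype=float)

    @classmethod
    def uniform(
        cls, n_policies: int = 17, n_states: int = N_STATES, eta: float = 0.85, p_th: float = 0.90
    ) -> "PolicyCache":
        """A fresh cache: every state's column is uniform over policies."""
        return cls(np.full((n_policies, n_states), 1.0 / n_policies), eta=eta, p_th=p_th)

    def copy(self) -> "PolicyCache":
        return PolicyCache(self.table.copy(), eta=self.eta, p_th=self.p_th)

    def expected(self, belief: np.ndarray) -> np.ndarray:
        """E_{belief}[P(pi|s)] for every policy."""
        return self.table @ np.asarray(belief, dtype=float)

    def update(self, belief: np.ndarray, posterior: np.ndarray) -> None:
        """Delta-rule update of every state's column, weighted by occupancy."""
        belief = np.asarray(belief, dtype=float)
        posterior = np.asarray(posterior, dtype=float)
        self.table += self.eta * belief[None, :] * (posterior[:, None] - self.table)


def expected_policy_prob(cache: PolicyCache, belief: np.ndarray) -> np.ndarray:
    """Expectation of the cached policy probabilities under a state belief."""
    return cache.expected(belief)


def cache_update(
    cache: PolicyCache, belief: np.ndarray, posterior: np.ndarray
) -> PolicyCache:
    """Functional form of the delta rule: returns an updated copy."""
    new = cache.copy()
    new.update(belief, posterior)
    return new


@dataclass(frozen=True)
class HabitDecision:
    """Outcome of a threshold check on the cache read-out."""

    habitual: bool
    policy: Optional[Policy]
    expected_prob: float
    stage: str  # "pre_trial", "planning" or "evaluation"
    step: int  # 0-based decision point at which the check was made


def habit_check(
    expected: np.ndarray,
    p_th: float,
    policies: List[Policy],
    stage: str = "pre_trial",
    step: int = 0,
) -> HabitDecision:
    """Fire a habit iff the maximum expectation strictly exceeds ``p_th``.

    Ties in the argmax resolve to the lowest policy id.
    """
    expected = np.asarray(expected, dtype=float)
    best = int(np.argmax(expected))  # argmax returns the first (lowest id) maximiser
    if expected[best] > p_th:
        return HabitDecision(True, policies[best], float(expected[best]), stage, step)
    return HabitDecision(False, None, float(expected[best]), stage, step)


def _habit_flags(habitised_at: Optional[int]) -> Tuple[bool, bool, bool, bool]:
    if habitised_at is None:
        return (False, False, False, False)
    return tuple(cp >= habitised_at for cp in range(1, TRIAL_LENGTH + 1))


def run_trial_scheme1(
    model: GenerativeModel,
    cache: PolicyCache,
    prev_final_belief: Optional[np.ndarray],
    prev_context_posterior: np.ndarray,
    true_context: str,
    p_reward: float,
    rng: np.random.Generator,
) -> TrialRecord:
    """Scheme 1: consult the cache once, before the trial begins.

    The check uses the previous trial's final belief s_hat(T); trial 1 (no
    previous belief) is always deliberative. A firing habit executes the
    cached policy open-loop for the whole trial with zero policy
    evaluations; beliefs are still filtered so the context estimate stays
    current. The cache is never updated on habitual trials.
    """
    if prev_final_belief is not None:
        expected = cache.expected(prev_final_belief)
    else:
        # no previous trial: record the read-out under the trial-start prior
        expected = cache.expected(model.initial_D(prev_context_posterior))
    max_expected = float(expected.max())

    decision = None
    if prev_final_belief is not None:
        decision = habit_check(expected, cache.p_th, model.policies, "pre_trial", 0)

    if decision is not None and decision.habitual:
        topo = model.topology
        ws = WorldState(location=topo.start, true_context=true_context)
        obs0 = initial_observation(topo, ws)
        belief = belief_update(
            model.initial_D(prev_context_posterior), None, obs0, model
        )
        belief, ws, actions, observations = execute_policy_open_loop(
            model, belief, decision.policy, 0, ws, p_reward, rng
        )
        observations = [obs0] + observations
        return TrialRecord(
            actions=tuple(actions),
            observations=tuple(observations),
            rewarded=any(o.cue == RED for o in observations),
            final_belief=belief,
            habit_flags=(True, True, True, True),
            habitised_at=1,
            habit_policy_id=decision.policy.id,
            executed_policy_id=decision.policy.id,
            policy_posteriors=[None] * TRIAL_LENGTH,
            n_efe_evals=0,
            n_efe_terms=0,
            max_expected_policy_prob=max_expected,
        )

    from .inference import run_trial_full

    record = run_trial_full(
        model, prev_context_posterior, true_context, p_reward, rng, cache=cache
    )
    record.max_expected_policy_prob = max_expected
    return record


def _deliberate_then_step(
    model: GenerativeModel,
    cache: PolicyCache,
    belief: np.ndarray,
    allowed: np.ndarray,
    t: int,
    ws: WorldState,
    p_reward: float,
    rng: np.random.Generator,
    G: Optional[np.ndarray] = None,
):
    """Shared deliberative tail of a decision point: softmax, update, act."""
    if G is None:
        G = evaluate_policies(model, belief, t)
    post = policy_posterior(G, model.gamma, allowed)
    cache.update(belief, post)
    action = select_action(post, model.policies, t, rng)
    allowed = allowed & np.array([p.actions[t] == action for p in model.policies])
    ws, obs = world_step(model.topology, ws, action, p_reward, rng)
    belief = belief_update(belief, action, obs, model)
    return post, action, allowed, ws, obs, belief


def run_trial_scheme2(
    model: GenerativeModel,
    cache: PolicyCache,
    prev_context_posterior: np.ndarray,
    true_context: str,
    p_reward: float,
    rng: np.random.Generator,
) -> TrialRecord:
    """Scheme 2: consult the cache during planning (one step ahead).

    At each decision point, every still-executable policy's one-step
    predicted state is formed and the cache read-out taken over it; a policy
    whose own cached probability exceeds ``p_th`` there is adopted for the
    remainder of the trial. Otherwise the decision point is fully
    deliberative (with a cache update).
    """
    topo = model.topology
    ws = WorldState(location=topo.start, true_context=true_context)
    obs0 = initial_observation(topo, ws)
    belief = belief_update(model.initial_D(prev_context_posterior), None, obs0, model)

    allowed = np.ones(model.n_policies, dtype=bool)
    actions: List[str] = []
    observations: List[Observation] = [obs0]
    posteriors: List[Optional[np.ndarray]] = []
    n_evals = 0
    n_terms = 0
    habitised_at: Optional[int] = None
    habit_policy: Optional[Policy] = None
    max_expected = -np.inf

    for t in range(TRIAL_LENGTH):
        # planning check: one-step prediction under each executable policy
        expected = np.full(model.n_policies, -np.inf)
        for j, pol in enumerate(model.policies):
            if not allowed[j]:
                continue
            s_next = model.B[pol.actions[t]] @ belief
            expected[j] = float(cache.table[j] @ s_next)
        max_expected = max(max_expected, float(expected.max()))
        decision = habit_check(expected, cache.p_th, model.policies, "planning", t)
        if decision.habitual:
            habitised_at = t + 1
            habit_policy = decision.policy
            belief, ws, tail_actions, tail_obs = execute_policy_open_loop(
                model, belief, habit_policy, t, ws, p_reward, rng
            )
            actions.extend(tail_actions)
            observations.extend(tail_obs)
            posteriors.extend([None] * (TRIAL_LENGTH - t))
            break
        post, action, allowed, ws, obs, belief = _deliberate_then_step(
            model, cache, belief, allowed, t, ws, p_reward, rng
        )
        n_evals += model.n_policies
        n_terms += model.n_policies * (TRIAL_LENGTH - t)
        actions.append(action)
        observations.append(obs)
        posteriors.append(post)

    executed = model.policy_for_actions(actions)
    if habitised_at is None:
        cache.update(belief, _collapsed_posterior(model.n_policies, executed.id))

    return TrialRecord(
        actions=tuple(actions),
        observations=tuple(observations),
        rewarded=any(o.cue == RED for o in observations),
        final_belief=belief,
        habit_flags=_habit_flags(habitised_at),
        habitised_at=habitised_at,
        habit_policy_id=None if habit_policy is None else habit_policy.id,
        executed_policy_id=executed.id,
        policy_posteriors=posteriors,
        n_efe_evals=n_evals,
        n_efe_terms=n_terms,
        max_expected_policy_prob=max_expected,
    )


def run_trial_scheme3(
    model: GenerativeModel,
    cache: PolicyCache,
    prev_context_posterior: np.ndarray,
    true_context: str,
    p_reward: float,
    rng: np.random.Generator,
) -> TrialRecord:
    """Scheme 3: consult the cache during policy evaluation.

    Policies are scanned in canonical id order. While accumulating a
    policy's path integral, the cache read-out is taken over each predicted
    state; the first strict threshold crossing (for a still-executable
    policy) terminates all evaluation and the policy is adopted for the
    remainder of the trial. With no crossing, evaluation completes and the
    decision point proceeds deliberatively.

    ``n_efe_evals`` counts completed policy evaluations; ``n_efe_terms``
    counts every per-(policy, tau) path-integral step, the granularity at
    which this scheme truncates.
    """
    topo = model.topology
    ws = WorldState(location=topo.start, true_context=true_context)
    obs0 = initial_observation(topo, ws)
    belief = belief_update(model.initial_D(prev_context_posterior), None, obs0, model)

    allowed = np.ones(model.n_policies, dtype=bool)
    actions: List[str] = []
    observations: List[Observation] = [obs0]
    posteriors: List[Optional[np.ndarray]] = []
    n_evals = 0
    n_terms = 0
    habitised_at: Optional[int] = None
    habit_policy: Optional[Policy] = None
    max_expected = -np.inf

    for t in range(TRIAL_LENGTH):
        G = np.empty(model.n_policies)
        crossing: Optional[Policy] = None
        for j, pol in enumerate(model.policies):
            g_total = 0.0
            for tau, s_tau, g_tau in efe_terms(pol, belief, t, model):
                g_total += g_tau
                n_terms += 1
                if allowed[j]:
                    e = float(cache.table[j] @ s_tau)
                    max_expected = max(max_expected, e)
                    if e > cache.p_th:
                        crossing = pol
                        break
            if crossing is not None:
                break
            G[j] = g_total
            n_evals += 1
        if crossing is not None:
            habitised_at = t + 1
            habit_policy = crossing
            belief, ws, tail_actions, tail_obs = execute_policy_open_loop(
                model, belief, crossing, t, ws, p_reward, rng
            )
            actions.extend(tail_actions)
            observations.extend(tail_obs)
            posteriors.extend([None] * (TRIAL_LENGTH - t))
            break
        post, action, allowed, ws, obs, belief = _deliberate_then_step(
            model, cache, belief, allowed, t, ws, p_reward, rng, G=G
        )
        actions.append(action)
        observations.append(obs)
        posteriors.append(post)

    executed = model.policy_for_actions(actions)
    if habitised_at is None:
        cache.update(belief, _collapsed_posterior(model.n_policies, executed.id))

    return TrialRecord(
        actions=tuple(actions),
        observations=tuple(observations),
        rewarded=any(o.cue == RED for o in observations),
        final_belief=belief,
        habit_flags=_habit_flags(habitised_at),
        habitised_at=habitised_at,
        habit_policy_id=None if habit_policy is None else habit_policy.id,
        executed_policy_id=executed.id,
        policy_posteriors=posteriors,
        n_efe_evals=n_evals,
        n_efe_terms=n_terms,
        max_expected_policy_prob=max_expected,
    )
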