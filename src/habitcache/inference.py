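"""Deliberative Active Inference: filtering, policy evaluation, selection.

A trial is four moves. At each decision point the agent (stage A) updates
its posterior over the 40 hidden states from the latest observation,
(stages B-C) evaluates every policy's expected free energy

    G_pi = sum_{tau=t+1..T} [ -H[P(o|s)] . s_pi(tau)
                              - (ln o_pi(tau) - ln C) . o_pi(tau) ]

i.e. an ambiguity term (expected outcome entropy given states) plus a risk
term (KL divergence of predicted from preferred outcomes), both
non-positive, (stage D) forms the precision-weighted softmax posterior over
policies and samples the next action from its action marginal, and
(stage E) acts. Beliefs are propagated by exact discrete Bayesian filtering,
which is exact for this model size; the policy posterior is conditioned on
the action history (policies inconsistent with the actions already executed
receive zero mass), although every policy is still evaluated at every
decision point.

Between trials only the context marginal of the final belief survives (it
seeds the next trial's initial-state prior); the location factor resets to
the start.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import rel_entr

from .model import GenerativeModel, Policy, observation_index
from .world import (
    ACTIONS,
    N_CONTEXTS,
    RED,
    TRIAL_LENGTH,
    Observation,
    WorldState,
    initial_observation,
    world_step,
)

class ImpossibleObservationError(ValueError):
    """The observation has zero probability under the predicted states."""


def context_marginal(belief: np.ndarray) -> np.ndarray:
    """Marginal over the 4 contexts of a 40-state belief."""
    return np.asarray(belief).reshape(-1, N_CONTEXTS).sum(axis=0)


def belief_update(
    belief: np.ndarray,
    action: Optional[str],
    observation: Observation,
    model: GenerativeModel,
) -> np.ndarray:
    """Bayesian filtering step: predict through ``action``, condition on ``observation``.

    With ``action=None`` (trial start) the prediction step is omitted and the
    prior is conditioned directly.
    """
    prior = np.asarray(belief, dtype=float)
    if action is not None:
        prior = model.B[action] @ prior
    o = observation_index(observation.location, observation.cue) - 1
    post = model.A[o, :] * prior
    total = post.sum()
    if total <= 0.0:
        raise ImpossibleObservationError(
            f"observation {observation} has zero probability under the predicted states"
        )
    return post / total


def predict_states(
    belief: np.ndarray,
    policy: Policy,
    t: int,
    tau: int,
    model: GenerativeModel,
) -> np.ndarray:
    """Predicted state distribution s_pi(tau) from the step-``t`` belief."""
    if tau < t:
        raise ValueError(f"tau ({tau}) must be >= current step ({t})")
    if tau > TRIAL_LENGTH:
        raise ValueError(f"tau ({tau}) exceeds the trial horizon {TRIAL_LENGTH}")
    s = np.asarray(belief, dtype=float)
    for step in range(t, tau):
        s = model.B[policy.actions[step]] @ s
    return s


def efe_terms(
    policy: Policy,
    belief: np.ndarray,
    t: int,
    model: GenerativeModel,
) -> Iterator[Tuple[int, np.ndarray, float]]:
    """Yield (tau, s_pi(tau), G(pi, tau)) for tau = t+1 .. T.

    Each per-step term is ambiguity + risk, both non-positive. This is the
    single code path used by every scheme, so truncated (Scheme 3) and full
    path integrals accumulate identical floating-point values.
    """
    C = model.C
    s = np.asarray(belief, dtype=float)
    for tau in range(t + 1, TRIAL_LENGTH + 1):
        s = model.B[policy.actions[tau - 1]] @ s
        o = model.A @ s
        ambiguity = -float(model.H_A @ s)
        risk = -float(rel_entr(o, C).sum())
        yield tau, s, ambiguity + risk


def expected_free_energy(
    policy: Policy,
    belief: np.ndarray,
    t: int,
    model: GenerativeModel,
) -> float:
    """Path integral G_pi of expected free energy over the remaining steps."""
    return sum(g for _, _, g in efe_terms(policy, belief, t, model))


def evaluate_policies(
    model: GenerativeModel,
    belief: np.ndarray,
    t: int,
) -> np.ndarray:
    """G_pi for every policy in id order."""
    G = np.empty(model.n_policies)
    for j, policy in enumerate(model.policies):
        G[j] = expected_free_energy(policy, belief, t, model)
    return G


def policy_posterior(
    G: np.ndarray,
    gamma: float,
    allowed: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Precision-weighted softmax over policies, with max-subtraction.

    ``allowed`` masks policies inconsistent with the executed action history;
    masked policies receive exactly zero mass.
    """
    if gamma <= 0:
        raise ValueError(f"gamma must be > 0, got {gamma}")
    G = np.asarray(G, dtype=float)
    if not np.all(np.isfinite(G)):
        raise ValueError("non-finite expected free energy")
    z = gamma * G
    if allowed is not None:
        allowed = np.asarray(allowed, dtype=bool)
        if not allowed.any():
            raise ValueError("no allowed policies")
        z = np.where(allowed, z, -np.inf)
    z = z - z.max()
    w = np.exp(z)
    return w / w.sum()


def action_marginal(
    posterior: np.ndarray,
    policies: Sequence[Policy],
    t: int,
) -> np.ndarray:
    """Marginal probability of each action at step ``t`` under the posterior."""
    if t >= TRIAL_LENGTH:
        raise ValueError(f"step t={t} out of range")
    m = np.zeros(len(ACTIONS))
    for p, pol in zip(posterior, policies):
        m[ACTIONS.index(pol.actions[t])] += p
    return m


def select_action(
    posterior: np.ndarray,
    policies: Sequence[Policy],
    t: int,
    rng: np.random.Generator,
) -> str:
    """Sample the next action from the policy posterior's action marginal."""
    m = action_marginal(posterior, policies, t)
    m = np.clip(m, 0.0, None)
    m = m / m.sum()
    return ACTIONS[rng.choice(len(ACTIONS), p=m)]


@dataclass
class TrialRecord:
    """Everything recorded about one trial."""

    actions: Tuple[str, ...]
    observations: Tuple[Observation, ...]  # initial cue included (5 entries)
    rewarded: bool
    final_belief: np.ndarray
    habit_flags: Tuple[bool, bool, bool, bool]
    habitised_at: Optional[int]  # 1-based choice point, None if deliberative
    habit_policy_id: Optional[int]
    executed_policy_id: int
    policy_posteriors: List[Optional[np.ndarray]]
    n_efe_evals: int
    n_efe_terms: int
    max_expected_policy_prob: float = float("nan")

    @property
    def context_posterior(self) -> np.ndarray:
        return context_marginal(self.final_belief)


def _collapsed_posterior(n_policies: int, policy_id: int) -> np.ndarray:
    post = np.zeros(n_policies)
    post[policy_id - 1] = 1.0
    return post


def run_trial_full(
    model: GenerativeModel,
    prev_context_posterior: np.ndarray,
    true_context: str,
    p_reward: float,
    rng: np.random.Generator,
    cache=None,
) -> TrialRecord:
    """One fully deliberative trial (stages A-E, four times).

    When a ``cache`` (see :mod:`habitcache.caching`) is supplied, its delta
    rule is applied after every policy-posterior computation and once more
    after the final observation, with the posterior collapsed onto the single
    policy consistent with all four executed actions.
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

    for t in range(TRIAL_LENGTH):
        G = evaluate_policies(model, belief, t)
        n_evals += model.n_policies
        n_terms += model.n_policies * (TRIAL_LENGTH - t)
        post = policy_posterior(G, model.gamma, allowed)
        if cache is not None:
            cache.update(belief, post)
        action = select_action(post, model.policies, t, rng)
        allowed &= np.array([p.actions[t] == action for p in model.policies])
        ws, obs = world_step(topo, ws, action, p_reward, rng)
        belief = belief_update(belief, action, obs, model)
        actions.append(action)
        observations.append(obs)
        posteriors.append(post)

    executed = model.policy_for_actions(actions)
    if cache is not None:
        cache.update(belief, _collapsed_posterior(model.n_policies, executed.id))

    return TrialRecord(
        actions=tuple(actions),
        observations=tuple(observations),
        rewarded=any(o.cue == RED for o in observations),
        final_belief=belief,
        habit_flags=(False, False, False, False),
        habitised_at=None,
        habit_policy_id=None,
        executed_policy_id=executed.id,
        policy_posteriors=posteriors,
        n_efe_evals=n_evals,
        n_efe_terms=n_terms,
    )


def execute_policy_open_loop(
    model: GenerativeModel,
    belief: np.ndarray,
    policy: Policy,
    start_step: int,
    ws: WorldState,
    p_reward: float,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, WorldState, List[str], List[Observation]]:
    """Run a policy's remaining actions without deliberation.

    Actions are executed open-loop, but belief filtering still runs on every
    received observation so the context posterior stays current.
    """
    actions: List[str] = []
    observations: List[Observation] = []
    for t in range(start_step, TRIAL_LENGTH):
        action = policy.actions[t]
        ws, obs = world_step(model.topology, ws, action, p_reward, rng)
        belief = belief_update(belief, action, obs, model)
        actions.append(action)
        observations.append(obs)
    return belief, ws, actions, observations
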