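"""The agent's generative model of the double T-maze.

Hidden states factorise as location x context: 10 locations and 4 contexts
give 40 hidden states, indexed (1-based) as ``(location - 1) * 4 + context``
so that e.g. location 5 in context A is state 17 and location 10 in context D
is state 40. Observations factorise as location x cue (white/red): 20
outcomes indexed ``(location - 1) * 2 + cue`` with white first.

The model comprises

* ``A`` — a 20 x 40 likelihood mapping states to outcome probabilities: the
  baited terminal of each context emits the red cue with probability
  ``p_reward_model``, every other location emits white with certainty;
* ``B`` — one deterministic 40 x 40 transition matrix per action, the maze
  move graph on the location factor tensored with the identity on context;
* ``lnC`` — log prior preferences over the 20 outcomes, a softmax that puts
  ``utility`` log-units of preference on every red outcome;
* ``D`` — the initial-state prior for a trial: a point mass on the start
  location tensored with a context prior obtained by smoothing the previous
  trial's context posterior with a stability kernel;
* the exhaustively enumerated set of 17 length-4 policies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import logsumexp, xlogy

from .world import (
    ACTIONS,
    CONTEXTS,
    N_CONTEXTS,
    N_LOCATIONS,
    N_OBSERVATIONS,
    N_STATES,
    RED,
    STAY,
    TRIAL_LENGTH,
    WHITE,
    MazeTopology,
    build_topology,
)

_ACTION_RANK = {a: i for i, a in enumerate(ACTIONS)}


def state_index(location: int, context: str) -> int:
    """1-based hidden-state index of (location, context)."""
    return (location - 1) * N_CONTEXTS + CONTEXTS.index(context) + 1


def state_of_index(index: int) -> Tuple[int, str]:
    """Inverse of :func:`state_index` (1-based)."""
    if not 1 <= index <= N_STATES:
        raise ValueError(f"state index out of range: {index}")
    loc0, ctx0 = divmod(index - 1, N_CONTEXTS)
    return loc0 + 1, CONTEXTS[ctx0]


def observation_index(location: int, cue: str) -> int:
    """1-based observation index of (location, cue); white precedes red."""
    return (location - 1) * 2 + (1 if cue == WHITE else 2)


@dataclass(frozen=True)
class Policy:
    """A fixed length-4 action sequence with its induced location trajectory."""

    id: int  # 1-based, assigned in canonical order
    actions: Tuple[str, str, str, str]
    trajectory: Tuple[int, int, int, int, int]  # 5 locations, start included
    reaches_reward_location: bool


def enumerate_policies(topology: MazeTopology) -> List[Policy]:
    """Exhaustively enumerate the allowable length-4 action sequences.

    The first action is the unique move at the start (the agent must commit
    to entering the maze, so ``stay`` is unavailable on the first step). At
    every subsequent non-terminal location the available actions are the
    defined moves plus ``stay``; terminals absorb (only ``stay``). Policies
    are returned in lexicographic order over actions (up < left < right <
    stay) with ids assigned in that order.
    """
    start_actions = [a for a in topology.available_actions(topology.start) if a != STAY]
    sequences: List[Tuple[Tuple[str, ...], Tuple[int, ...]]] = []

    def extend(actions: Tuple[str, ...], path: Tuple[int, ...]) -> None:
        if len(actions) == TRIAL_LENGTH:
            sequences.append((actions, path))
            return
        loc = path[-1]
        if loc in topology.terminals:
            options = (STAY,)
        else:
            options = topology.available_actions(loc)
        for a in options:
            extend(actions + (a,), path + (topology.step(loc, a),))

    for a in start_actions:
        extend((a,), (topology.start, topology.step(topology.start, a)))

    sequences.sort(key=lambda item: tuple(_ACTION_RANK[a] for a in item[0]))
    reward_locs = set(topology.reward_location_of_context.values())
    return [
        Policy(
            id=i + 1,
            actions=tuple(actions),
            trajectory=tuple(path),
            reaches_reward_location=bool(reward_locs & set(path)),
        )
        for i, (actions, path) in enumerate(sequences)
    ]


def policy_by_actions(policies: Sequence[Policy], actions: Sequence[str]) -> Policy:
    """Look a policy up by its action sequence."""
    key = tuple(actions)
    for pol in policies:
        if pol.actions == key:
            return pol
    raise KeyError(f"no policy with actions {key}")


def build_A(topology: MazeTopology, p_reward_model: float) -> np.ndarray:
    """Likelihood P(o|s) as a (20, 40) column-stochastic matrix."""
    if not 0.0 <= p_reward_model <= 1.0:
        raise ValueError(f"p_reward_model must be in [0, 1], got {p_reward_model}")
    A = np.zeros((N_OBSERVATIONS, N_STATES))
    for loc in range(1, N_LOCATIONS + 1):
        for ctx in CONTEXTS:
            s = state_index(loc, ctx) - 1
            if loc == topology.reward_location_of_context[ctx]:
                A[observation_index(loc, RED) - 1, s] = p_reward_model
                A[observation_index(loc, WHITE) - 1, s] = 1.0 - p_reward_model
            else:
                A[observation_index(loc, WHITE) - 1, s] = 1.0
    return A


def build_B(topology: MazeTopology) -> Dict[str, np.ndarray]:
    """Per-action (40, 40) transition matrices; context factor is identity.

    Undefined moves fall back to ``stay`` semantics, so every column is a
    valid 0/1 distribution (the enumerated policies never rely on this).
    """
    B: Dict[str, np.ndarray] = {}
    eye_ctx = np.eye(N_CONTEXTS)
    for action in ACTIONS:
        L = np.zeros((N_LOCATIONS, N_LOCATIONS))
        for loc in range(1, N_LOCATIONS + 1):
            new_loc = topology.moves.get((loc, action), loc)
            L[new_loc - 1, loc - 1] = 1.0
        B[action] = np.kron(L, eye_ctx)
    return B


def build_lnC(utility: float) -> np.ndarray:
    """Log preference distribution over the 20 outcomes.

    Every red outcome carries ``utility`` log-units of unnormalised
    preference, every white outcome 0; the result is the log of the softmax
    over all 20 outcomes.
    """
    if utility < 0:
        raise ValueError(f"utility must be >= 0, got {utility}")
    weights = np.zeros(N_OBSERVATIONS)
    for loc in range(1, N_LOCATIONS + 1):
        weights[observation_index(loc, RED) - 1] = utility
    return weights - logsumexp(weights)


def context_transition(stability: float) -> np.ndarray:
    """Between-trial context kernel: keep with prob ``stability``, else spread."""
    if not 0.0 <= stability <= 1.0:
        raise ValueError(f"stability must be in [0, 1], got {stability}")
    T = np.full((N_CONTEXTS, N_CONTEXTS), (1.0 - stability) / (N_CONTEXTS - 1))
    np.fill_diagonal(T, stability)
    return T


def build_D(
    prev_context_posterior: np.ndarray,
    stability: float,
    start: int = 1,
) -> np.ndarray:
    """Initial-state prior for a trial.

    The previous trial's context posterior is smoothed by the stability
    kernel; the location factor is a point mass on the start location. On
    trial 1 pass the uniform context distribution.
    """
    prev = np.asarray(prev_context_posterior, dtype=float)
    if prev.shape != (N_CONTEXTS,) or np.any(prev < 0) or not np.isclose(prev.sum(), 1.0):
        raise ValueError("prev_context_posterior must be a distribution over 4 contexts")
    ctx_prior = context_transition(stability) @ prev
    D = np.zeros(N_STATES)
    for i, ctx in enumerate(CONTEXTS):
        D[state_index(start, ctx) - 1] = ctx_prior[i]
    return D


@dataclass
class GenerativeModel:
    """Bundle of likelihood, transitions, preferences and the policy set."""

    topology: MazeTopology
    A: np.ndarray
    B: Dict[str, np.ndarray]
    lnC: np.ndarray
    policies: List[Policy]
    gamma: float
    p_reward_model: float
    utility: float
    stability: float
    #: per-state entropy of A's columns, precomputed for the ambiguity term
    H_A: np.ndarray = field(init=False)
    #: preference distribution exp(lnC), precomputed for the risk term
    C: np.ndarray = field(init=False)
    #: policy id keyed by action sequence
    _by_actions: Dict[Tuple[str, ...], Policy] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        with np.errstate(divide="ignore", invalid="ignore"):
            self.H_A = -xlogy(self.A, self.A).sum(axis=0)
        self.C = np.exp(self.lnC)
        self._by_actions = {p.actions: p for p in self.policies}

    @property
    def n_policies(self) -> int:
        return len(self.policies)

    def policy_for_actions(self, actions: Sequence[str]) -> Policy:
        return self._by_actions[tuple(actions)]

    def initial_D(self, prev_context_posterior: np.ndarray) -> np.ndarray:
        return build_D(prev_context_posterior, self.stability, self.topology.start)

    def to_json(self) -> str:
        """Serialise the model matrices for inspection."""
        payload = {
            "A": self.A.tolist(),
            "B": {a: m.tolist() for a, m in self.B.items()},
            "lnC": self.lnC.tolist(),
            "gamma": self.gamma,
            "p_reward_model": self.p_reward_model,
            "utility": self.utility,
            "stability": self.stability,
            "policies": [
                {
                    "id": p.id,
                    "actions": list(p.actions),
                    "trajectory": list(p.trajectory),
                    "reaches_reward": p.reaches_reward_location,
                }
                for p in self.policies
            ],
        }
        return json.dumps(payload)


def build_model(
    gamma: float = 3.0,
    utility: float = 1.3,
    p_reward_model: float = 0.95,
    stability: float = 0.99,
    topology: Optional[MazeTopology] = None,
) -> GenerativeModel:
    """Construct the full generative model with validated components."""
    if gamma <= 0:
        raise ValueError(f"gamma must be > 0, got {gamma}")
    topo = topology if topology is not None else build_topology()
    policies = enumerate_policies(topo)
    if len(policies) != 17:
        raise AssertionError(
            f"policy enumeration produced {len(policies)} policies, expected 17"
        )
    return GenerativeModel(
        topology=topo,
        A=build_A(topo, p_reward_model),
        B=build_B(topo),
        lnC=build_lnC(utility),
        policies=policies,
        gamma=gamma,
        p_reward_model=p_reward_model,
        utility=utility,
        stability=stability,
    )


def policy_table(policies: Sequence[Policy]):
    """Policy set as a tidy DataFrame (id, actions, trajectory, reaches_reward)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "id": [p.id for p in policies],
            "actions": [",".join(p.actions) for p in policies],
            "trajectory": [",".join(map(str, p.trajectory)) for p in policies],
            "reaches_reward": [p.reaches_reward_location for p in policies],
        }
    )
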