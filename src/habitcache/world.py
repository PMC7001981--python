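"""Ground-truth double T-maze environment.

The maze has 10 locations. The agent enters at location 1, climbs to the
central junction (3), chooses a left or right corridor (2 or 4), climbs to a
second junction (6 or 9) and finally enters one of four terminal arms
(5, 7, 8, 10). Exactly one terminal is baited on each trial; which one is
determined by the hidden context (A..D). Terminals are absorbing: once
entered, only ``stay`` is available.

A trial lasts four moves. Reward delivery is stochastic: when the agent sits
in the baited terminal it observes the red (reward) cue with probability
``p_reward`` and the white (no-reward) cue otherwise; every other location
always yields the white cue. A failed delivery is modelled as non-delivery,
never as relocation of the reward.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np

UP, LEFT, RIGHT, STAY = "up", "left", "right", "stay"
#: Canonical action order, used for policy enumeration and transition stacking.
ACTIONS: Tuple[str, ...] = (UP, LEFT, RIGHT, STAY)

CONTEXTS: Tuple[str, ...] = ("A", "B", "C", "D")

WHITE, RED = "white", "red"

N_LOCATIONS = 10
N_CONTEXTS = 4
N_STATES = N_LOCATIONS * N_CONTEXTS
N_CUES = 2
N_OBSERVATIONS = N_LOCATIONS * N_CUES
TRIAL_LENGTH = 4  # moves per trial

START_LOCATION = 1


class InvalidMoveError(ValueError):
    """Raised when a (location, action) pair has no defined move."""


@dataclass(frozen=True)
class MazeTopology:
    """The fixed double T-maze graph.

    ``moves`` is a partial map (location, action) -> location. It is
    deterministic; ``stay`` maps every location to itself and is the only
    action defined at terminals.
    """

    locations: Tuple[int, ...]
    start: int
    terminals: frozenset
    moves: Dict[Tuple[int, str], int]
    reward_location_of_context: Dict[str, int]

    def available_actions(self, location: int) -> Tuple[str, ...]:
        """Actions with a defined move at ``location``, in canonical order."""
        return tuple(a for a in ACTIONS if (location, a) in self.moves)

    def step(self, location: int, action: str) -> int:
        try:
            return self.moves[(location, action)]
        except KeyError:
            raise InvalidMoveError(
                f"no move defined for action {action!r} at location {location}"
            ) from None


# The unique move graph: 1-up->3; 3-left->2, 3-right->4; 2-up->6; 4-up->9;
# 6-left->5, 6-right->7; 9-left->8, 9-right->10. Terminals absorb.
_CORRIDOR_MOVES = {
    (1, UP): 3,
    (3, LEFT): 2,
    (3, RIGHT): 4,
    (2, UP): 6,
    (4, UP): 9,
    (6, LEFT): 5,
    (6, RIGHT): 7,
    (9, LEFT): 8,
    (9, RIGHT): 10,
}

_TERMINALS = frozenset({5, 7, 8, 10})

_REWARD_LOCATIONS = {"A": 5, "B": 7, "C": 8, "D": 10}


def build_topology() -> MazeTopology:
    """Return the fixed double T-maze topology.

    ``stay`` is defined at every location; terminals admit only ``stay``.
    The four reward locations are exactly the terminals.
    """
    moves = dict(_CORRIDOR_MOVES)
    for loc in range(1, N_LOCATIONS + 1):
        moves[(loc, STAY)] = loc
    for term in _TERMINALS:
        for action in (UP, LEFT, RIGHT):
            moves.pop((term, action), None)
    return MazeTopology(
        locations=tuple(range(1, N_LOCATIONS + 1)),
        start=START_LOCATION,
        terminals=_TERMINALS,
        moves=moves,
        reward_location_of_context=dict(_REWARD_LOCATIONS),
    )


@dataclass(frozen=True)
class Observation:
    """What the agent sees after a move: its location and a colour cue."""

    location: int
    cue: str  # "white" or "red"

    @property
    def rewarded(self) -> bool:
        return self.cue == RED


@dataclass
class WorldState:
    """Ground-truth state of the environment within a trial."""

    location: int
    true_context: str
    trial: int = 1
    step: int = 0


def initial_observation(topology: MazeTopology, state: WorldState) -> Observation:
    """The (uninformative) cue delivered at the start location.

    The start location is never a terminal, so the cue is always white.
    """
    return Observation(location=state.location, cue=WHITE)


def world_step(
    topology: MazeTopology,
    state: WorldState,
    action: str,
    p_reward: float,
    rng: np.random.Generator,
) -> Tuple[WorldState, Observation]:
    """Execute ``action`` and sample the resulting observation.

    The cue is red with probability ``p_reward`` iff the new location is the
    true context's reward location; otherwise it is white with certainty.
    Undefined (location, action) pairs raise :class:`InvalidMoveError`.
    """
    if not 0.0 <= p_reward <= 1.0:
        raise ValueError(f"p_reward must be in [0, 1], got {p_reward}")
    new_loc = topology.step(state.location, action)
    baited = topology.reward_location_of_context[state.true_context]
    cue = WHITE
    if new_loc == baited and rng.random() < p_reward:
        cue = RED
    new_state = WorldState(
        location=new_loc,
        true_context=state.true_context,
        trial=state.trial,
        step=state.step + 1,
    )
    return new_state, Observation(location=new_loc, cue=cue)


def context_at_trial(trial: int, schedule: Sequence[Tuple[int, str]]) -> str:
    """Context in force at ``trial`` under a (first_trial, context) schedule.

    The schedule must be non-empty, sorted by first_trial, and start at
    trial 1.
    """
    if trial < 1:
        raise ValueError(f"trial must be >= 1, got {trial}")
    if not schedule:
        raise ValueError("schedule must be non-empty")
    firsts = [entry[0] for entry in schedule]
    if firsts[0] != 1 or firsts != sorted(firsts):
        raise ValueError("schedule must be sorted and start at trial 1")
    current = schedule[0][1]
    for first, ctx in schedule:
        if ctx not in CONTEXTS:
            raise ValueError(f"unknown context {ctx!r}")
        if trial >= first:
            current = ctx
        else:
            break
    return current
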