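"""Maze geometries and reward-rule automata for the spatial-alternation tasks.

Three elevated mazes are modelled. Each has four reward locations (arm ends,
labelled 1-4) and every transition between two locations is summarised by the
egocentric actions taken at the intersections along the way: left turn (``L``),
straight (``S``) or right turn (``R``).

* ``plus`` -- a single four-way intersection; every transition is one action.
  The task rule is the continuous alternation 1, 2, 1, 3, 1, 2, ... with
  Location 4 never rewarded and outside the control logic.
* ``H`` and ``2T`` -- two three-way junctions joined by a central segment
  (topologically the same tree, geometrically distinct); transitions take one
  or two actions.  The rule is simple alternation between the two rewarded
  ends (labelled 3 and 4 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

ACTIONS = ("L", "S", "R")

_MIRROR = {"L": "R", "R": "L", "S": "S"}


class MazeDefinitionError(ValueError):
    """Raised when a maze specification is internally inconsistent."""


def mirrored(actions: str) -> str:
    """Action string for retracing a path: reversed, with L and R swapped."""
    return "".join(_MIRROR[a] for a in reversed(actions))


@dataclass(frozen=True)
class MazeSpec:
    """Geometry of a maze as a map from ordered location pairs to actions.

    Parameters
    ----------
    name : str
        Maze identifier (``"plus"``, ``"H"`` or ``"2T"``).
    locations : frozenset of int
        The four reward-location ids.
    action_map : dict
        ``(from_loc, to_loc) -> action string`` over ``{L, S, R}``,
        defined for every ordered pair of distinct locations.
    rewarded_locations : frozenset of int
        Locations that can ever deliver reward under the maze's task rule.
    """

    name: str
    locations: frozenset
    action_map: dict
    rewarded_locations: frozenset

    def __post_init__(self):
        locs = sorted(self.locations)
        if len(locs) != 4:
            raise MazeDefinitionError(f"{self.name}: expected 4 locations, got {locs}")
        for a in locs:
            for b in locs:
                if a == b:
                    continue
                if (a, b) not in self.action_map:
                    raise MazeDefinitionError(f"{self.name}: missing transition ({a}, {b})")
                s = self.action_map[(a, b)]
                if not (1 <= len(s) <= 2) or any(c not in ACTIONS for c in s):
                    raise MazeDefinitionError(f"{self.name}: bad action string {s!r} for ({a}, {b})")
                if self.action_map[(b, a)] != mirrored(s):
                    raise MazeDefinitionError(
                        f"{self.name}: ({b}, {a}) must mirror ({a}, {b})"
                    )
        if not self.rewarded_locations <= self.locations:
            raise MazeDefinitionError(f"{self.name}: rewarded locations outside maze")


def actions_for_transition(maze: MazeSpec, from_loc: int, to_loc: int) -> str:
    """Egocentric action string for travelling ``from_loc -> to_loc``."""
    if from_loc not in maze.locations or to_loc not in maze.locations:
        raise MazeDefinitionError(
            f"unknown location in ({from_loc}, {to_loc}) for maze {maze.name}"
        )
    if from_loc == to_loc:
        raise ValueError("from_loc and to_loc must differ")
    return maze.action_map[(from_loc, to_loc)]


def _complete_map(half: dict) -> dict:
    out = dict(half)
    for (a, b), s in half.items():
        out[(b, a)] = mirrored(s)
    return out


# Plus maze: arm 1 at the bottom, 3 opposite, 2 on the left-turn side, 4 on
# the right-turn side (the L/R assignment of the 1<->2 leg is a convention;
# only the mirror-symmetric multiset is constrained by the geometry).
PLUS_MAZE = MazeSpec(
    name="plus",
    locations=frozenset({1, 2, 3, 4}),
    action_map=_complete_map(
        {(1, 2): "L", (1, 3): "S", (1, 4): "R", (2, 3): "L", (2, 4): "S", (3, 4): "L"}
    ),
    rewarded_locations=frozenset({1, 2, 3}),
)

# H maze: ends 1, 2 at the top, rewarded ends 3, 4 at the bottom; two
# junctions joined by the crossbar.  The rewarded cycle 3->4->3 is two right
# turns then two left turns.
H_MAZE = MazeSpec(
    name="H",
    locations=frozenset({1, 2, 3, 4}),
    action_map=_complete_map(
        {(1, 2): "LL", (1, 3): "S", (1, 4): "LR", (2, 3): "RL", (2, 4): "S", (3, 4): "RR"}
    ),
    rewarded_locations=frozenset({3, 4}),
)

# 2T maze: a straight run with ends 3 (rewarded) and 2, and two stems hanging
# from the junctions with ends 1 and 4 (rewarded).  The rewarded cycle
# 3->4->3 mixes straight segments with turns: (S, R, L, S).
TWO_T_MAZE = MazeSpec(
    name="2T",
    locations=frozenset({1, 2, 3, 4}),
    action_map=_complete_map(
        {(3, 4): "SR", (3, 1): "R", (3, 2): "SS", (1, 4): "RR", (1, 2): "RS", (4, 2): "R"}
    ),
    rewarded_locations=frozenset({3, 4}),
)

MAZES = {"plus": PLUS_MAZE, "H": H_MAZE, "2T": TWO_T_MAZE}

# Canonical rewarded visit cycle per task (plus: 1-2-1-3; H/2T: 3-4).
REWARD_CYCLES = {"plus": (1, 2, 1, 3), "H": (3, 4), "2T": (3, 4)}


@dataclass(frozen=True)
class RuleState:
    """State of a task's reward-rule automaton.

    For the plus maze the controller tracks which outer arm (2 or 3) the
    animal most recently visited (``last_outer``) and whether the next
    rewarded visit must be the home arm 1 (``need_home``).  For the H/2T
    alternation tasks ``last_outer`` holds the last rewarded end visited and
    ``need_home`` is unused.
    """

    task: str
    last_outer: int
    need_home: bool = False

    @property
    def expected_next(self) -> int:
        """The location that would be rewarded if visited next."""
        if self.task == "plus":
            if self.need_home:
                return 1
            return 3 if self.last_outer == 2 else 2
        ends = sorted(MAZES[self.task].rewarded_locations)
        return ends[0] if self.last_outer == ends[1] else ends[1]

    @property
    def step_index(self) -> int:
        """Position within the task's repeating reward sequence."""
        cycle = REWARD_CYCLES[self.task]
        if self.task == "plus":
            # cycle (1, 2, 1, 3): index of the slot expected_next occupies,
            # disambiguated by which outer arm was seen last.
            return {(True, 3): 0, (False, 3): 1, (True, 2): 2, (False, 2): 3}[
                (self.need_home, self.last_outer)
            ]
        return cycle.index(self.expected_next)


def evaluate_visit(state: RuleState, visit: int):
    """Apply one reward-location visit to the rule automaton.

    Returns ``(rewarded, new_state)``.  On the plus maze, Location 4 is never
    rewarded and does not advance the controller; an out-of-sequence visit to
    arm 2 or 3 updates ``last_outer`` (the animal has now "previously
    visited" that arm and must return home) without advancing the repeating
    sequence.
    """
    maze = MAZES[state.task]
    if visit not in maze.locations:
        raise MazeDefinitionError(f"location {visit} not on maze {maze.name}")
    if state.task == "plus":
        if visit == 4:
            return False, state
        if visit == 1:
            if state.need_home:
                return True, replace(state, need_home=False)
            return False, state
        # visit is an outer arm (2 or 3)
        rewarded = (not state.need_home) and visit == state.expected_next
        return rewarded, RuleState(state.task, last_outer=visit, need_home=True)
    # H / 2T: alternation between the two rewarded ends; other ends inert.
    if visit not in maze.rewarded_locations:
        return False, state
    rewarded = visit != state.last_outer
    return rewarded, replace(state, last_outer=visit)


def random_start_state(task: str, seed) -> RuleState:
    """Uniformly random phase of the task's repeating reward sequence.

    ``seed`` may be an int or a ``numpy.random.Generator``.  Mirrors the
    control program being "initiated at a random step in the visit location
    sequence" at the start of each session.
    """
    if task not in MAZES:
        raise MazeDefinitionError(f"unknown task {task!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if task == "plus":
        need_home, last_outer = [(True, 3), (False, 3), (True, 2), (False, 2)][
            rng.integers(4)
        ]
        return RuleState("plus", last_outer=last_outer, need_home=need_home)
    ends = sorted(MAZES[task].rewarded_locations)
    return RuleState(task, last_outer=ends[rng.integers(2)])


def correct_next(state: RuleState) -> int:
    """The next location a perfectly performing animal should visit."""
    return state.expected_next


def reward_cycle_actions(maze: MazeSpec, task: str) -> str:
    """Concatenated action string over one full correct reward cycle."""
    cycle = REWARD_CYCLES[task]
    path = list(cycle) + [cycle[0]]
    return "".join(
        actions_for_transition(maze, a, b) for a, b in zip(path[:-1], path[1:])
    )
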