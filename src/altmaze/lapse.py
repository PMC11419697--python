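"""Alternation vs reference-location error classification and lapse models.

On the plus maze, errors decompose by the departure location: an
*alternation error* is an out-of-sequence choice departing Location 1
(failing to alternate to the not-previously-visited outer arm; working
memory), and a *reference location error* is an out-of-sequence choice
departing Location 2 or 3 (failing to return home to Location 1; reference
memory).  A *lapse* is the first error immediately following four
consecutive correct visits, isolating sudden failures in an animal that
demonstrably knows the rule.

Two analytic lapse strategies are modelled.  A turn-bias strategy samples
the next action from a fixed distribution over (L, S, R); a location-bias
strategy samples the next arm proportionally to fixed location weights with
the current arm reweighted to zero.  For each strategy the conditional error
probability of each decision type is the equal-weight average over its two
contexts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import mazes
from .codec import UndefinedStatisticError, VisitLog
from .mazes import PLUS_MAZE, MazeSpec

ACTIONS = ("L", "S", "R")

# (previous location, current location) -> correct next location, per type
ALTERNATION_CONTEXTS = (((3, 1), 2), ((2, 1), 3))
REFERENCE_CONTEXTS = (((1, 2), 1), ((1, 3), 1))


@dataclass
class ErrorCounts:
    """Lapse-eligible error and opportunity tallies for one analysis window."""

    alternation_errors: int = 0
    alternation_opportunities: int = 0
    reference_errors: int = 0
    reference_opportunities: int = 0
    window: str = ""

    def __post_init__(self):
        if min(
            self.alternation_errors, self.alternation_opportunities,
            self.reference_errors, self.reference_opportunities,
        ) < 0:
            raise ValueError("counts must be nonnegative")
        if (
            self.alternation_errors > self.alternation_opportunities
            or self.reference_errors > self.reference_opportunities
        ):
            raise ValueError("errors cannot exceed opportunities")

    @property
    def alternation_rate(self) -> float:
        if self.alternation_opportunities == 0:
            raise UndefinedStatisticError("no alternation opportunities")
        return self.alternation_errors / self.alternation_opportunities

    @property
    def reference_rate(self) -> float:
        if self.reference_opportunities == 0:
            raise UndefinedStatisticError("no reference opportunities")
        return self.reference_errors / self.reference_opportunities

    def __add__(self, other: "ErrorCounts") -> "ErrorCounts":
        return ErrorCounts(
            self.alternation_errors + other.alternation_errors,
            self.alternation_opportunities + other.alternation_opportunities,
            self.reference_errors + other.reference_errors,
            self.reference_opportunities + other.reference_opportunities,
            self.window or other.window,
        )


@dataclass
class LapseStrategy:
    """A lapse behavior: turn bias over actions or location bias over arms.

    ``action_probs`` (turn_bias) is a distribution over (L, S, R);
    ``location_weights`` (location_bias) holds nonnegative weights for
    Locations 1-4, ideally [2, 1, 1, 0] (visit frequencies under the rule).
    ``p_lapse`` is the per-trial probability of following the strategy.
    """

    kind: str  # "turn_bias" | "location_bias"
    action_probs: tuple = (0.25, 0.5, 0.25)
    location_weights: tuple = (2.0, 1.0, 1.0, 0.0)
    p_lapse: float = 0.1

    def __post_init__(self):
        if self.kind not in ("turn_bias", "location_bias"):
            raise ValueError(f"unknown lapse strategy kind {self.kind!r}")
        if self.kind == "turn_bias" and not np.isclose(sum(self.action_probs), 1.0):
            raise ValueError("action_probs must sum to 1")
        if self.kind == "location_bias" and (
            min(self.location_weights) < 0 or sum(self.location_weights) == 0
        ):
            raise ValueError("location_weights must be nonnegative, not all zero")
        if not 0.0 <= self.p_lapse <= 1.0:
            raise ValueError("p_lapse must lie in [0, 1]")


def classify_lapse_errors(
    log: VisitLog, run_length: int = 4, window: str = ""
) -> ErrorCounts:
    """Tally lapse-eligible alternation/reference errors in a plus-maze log.

    A decision counts (as an opportunity, and as an error if the visit is
    out of sequence) only when the ``run_length`` visits immediately before
    it were all correct.  Decisions departing Location 4 are excluded from
    both types, but unrewarded visits -- including visits to 4 -- break the
    run of correct visits.
    """
    if log.task not in (None, "plus"):
        raise ValueError(f"lapse errors are defined on the plus maze, not {log.task}")
    counts = ErrorCounts(window=window)
    run = 0
    prev_loc = None
    for v in log.visits:
        if prev_loc is not None and run >= run_length:
            if prev_loc == 1:
                counts.alternation_opportunities += 1
                if not v.rewarded:
                    counts.alternation_errors += 1
            elif prev_loc in (2, 3):
                counts.reference_opportunities += 1
                if not v.rewarded:
                    counts.reference_errors += 1
            # departures from Location 4 are excluded from both types
        run = run + 1 if v.rewarded else 0
        prev_loc = v.location
    return counts


def error_rate_difference(counts: ErrorCounts) -> float:
    """Alternation error rate minus reference location error rate."""
    return counts.alternation_rate - counts.reference_rate


def ideal_action_probs(maze: MazeSpec, task: str | None = None) -> dict:
    """Empirical action frequencies over one full correct reward cycle."""
    cycle = mazes.reward_cycle_actions(maze, task or maze.name)
    return {a: cycle.count(a) / len(cycle) for a in ACTIONS}


def _correct_action(maze: MazeSpec, current: int, target: int) -> str:
    s = maze.action_map[(current, target)]
    if len(s) != 1:
        raise ValueError("turn-bias lapse contexts need single-action transitions")
    return s


def turn_bias_lapse_rates(action_probs, maze: MazeSpec = PLUS_MAZE):
    """Analytic (P_alt_error, P_ref_error) for a turn-bias lapse strategy.

    ``action_probs`` is the (L, S, R) distribution the lapse follows (e.g. a
    maze's ideal action probabilities); errors are evaluated against the
    plus-maze decision contexts and the two contexts of each type are
    averaged with equal weight.
    """
    if isinstance(action_probs, dict):
        p = {a: float(action_probs[a]) for a in ACTIONS}
    else:
        p = dict(zip(ACTIONS, map(float, action_probs)))
    if not np.isclose(sum(p.values()), 1.0):
        raise ValueError("action_probs must sum to 1")
    out = []
    for contexts in (ALTERNATION_CONTEXTS, REFERENCE_CONTEXTS):
        errs = [
            1.0 - p[_correct_action(maze, cur, target)]
            for ((_prev, cur), target) in contexts
        ]
        out.append(float(np.mean(errs)))
    return tuple(out)


def location_bias_lapse_rates(weights=(2.0, 1.0, 1.0, 0.0)):
    """Analytic (P_alt_error, P_ref_error) for a location-bias lapse strategy.

    On a lapse the next arm is drawn proportionally to ``weights`` (for
    Locations 1-4) with the current arm reweighted to zero; contexts of each
    type are averaged with equal weight.
    """
    w = np.asarray(weights, dtype=float)
    if w.min() < 0:
        raise ValueError("weights must be nonnegative")
    if w.sum() == 0:
        raise UndefinedStatisticError("all location weights are zero")
    out = []
    for kind, contexts in (
        ("alternation", ALTERNATION_CONTEXTS), ("reference", REFERENCE_CONTEXTS)
    ):
        errs = []
        for (_prev, cur), target in contexts:
            ww = w.copy()
            ww[cur - 1] = 0.0
            total = ww.sum()
            if total == 0:
                warnings.warn(
                    f"all reachable weights zero from Location {cur}; "
                    f"{kind} error rate undefined"
                )
                errs.append(np.nan)
            else:
                errs.append(1.0 - ww[target - 1] / total)
        out.append(float(np.mean(errs)))
    return tuple(out)


def last_sessions(logs, n: int = 5):
    """The final ``n`` (day, session) pairs present, across the given logs."""
    keys = sorted({(log.day, log.session) for log in logs})[-n:]
    return [log for log in logs if (log.day, log.session) in keys]


def error_report(logs, n_sessions: int = 5, run_length: int = 4):
    """Per-rat error table over each rat's last ``n_sessions`` sessions.

    Returns a list of dicts with alternation/reference rates and their
    difference, pooling the window's sessions before computing rates.
    """
    rows = []
    rats = sorted({log.rat_id for log in logs})
    for rat in rats:
        mine = [log for log in logs if log.rat_id == rat and log.phase == 2]
        windowed = last_sessions(mine, n_sessions)
        total = ErrorCounts(window=f"last {n_sessions} sessions")
        for log in windowed:
            total = total + classify_lapse_errors(log, run_length)
        rows.append(
            {
                "rat_id": rat,
                "group": mine[0].group if mine else "",
                "alternation_rate": total.alternation_rate,
                "reference_rate": total.reference_rate,
                "difference": error_rate_difference(total),
                "alternation_opportunities": total.alternation_opportunities,
                "reference_opportunities": total.reference_opportunities,
            }
        )
    return rows
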