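"""Visit logs and their first/second/third-order behavioral descriptions.

First-order behavior is the sequence of reward-location visits.  Second-order
behavior is the egocentric action (L/S/R) taken at each maze intersection
along a transition.  Third-order behavior classifies consecutive action pairs
into repeats and transitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import mazes
from .mazes import MazeSpec

THIRD_ORDER_CATEGORIES = ("repeat_turn", "repeat_straight", "turn_turn", "turn_straight")


class UndefinedStatisticError(ValueError):
    """A statistic is undefined on this input (e.g. too few trials)."""


class VisitDataError(ValueError):
    """A visit log violates its invariants."""


@dataclass(frozen=True)
class Visit:
    trial_index: int
    location: int
    rewarded: bool


@dataclass
class VisitLog:
    """Ordered reward-location visits for one rat in one session.

    ``task`` names the maze/task the session ran on (``plus``, ``H`` or
    ``2T``); it is carried as metadata because switching-group animals run
    different mazes in the two daily sessions.
    """

    rat_id: str
    group: str  # "non-switching" | "switching"
    phase: int  # 1 or 2
    day: int
    session: int  # 1 or 2 within day
    visits: list = field(default_factory=list)
    task: str | None = None

    def __post_init__(self):
        self.validate()

    def validate(self):
        last = None
        for v in self.visits:
            if last is not None:
                if v.trial_index <= last.trial_index:
                    raise VisitDataError(
                        f"{self.rat_id}: trial_index not strictly increasing "
                        f"at {v.trial_index}"
                    )
                if v.location == last.location:
                    raise VisitDataError(
                        f"{self.rat_id}: consecutive visits to location "
                        f"{v.location} at trial {v.trial_index}"
                    )
            last = v

    @property
    def locations(self):
        return [v.location for v in self.visits]

    @property
    def rewards(self):
        return [v.rewarded for v in self.visits]

    def __len__(self):
        return len(self.visits)


@dataclass
class ActionTrace:
    """Flattened second-order action sequence with visit provenance.

    ``trial_of_action[k]`` gives the ``(from_trial_index, to_trial_index)``
    visit pair that produced action ``actions[k]``; on H/2T a single
    transition contributes up to two actions that share a source pair.
    """

    actions: list
    trial_of_action: list

    def __len__(self):
        return len(self.actions)


def encode_actions(log: VisitLog, maze: MazeSpec) -> ActionTrace:
    """Convert a visit log into its second-order action sequence."""
    actions, src = [], []
    for a, b in zip(log.visits[:-1], log.visits[1:]):
        try:
            s = mazes.actions_for_transition(maze, a.location, b.location)
        except mazes.MazeDefinitionError as e:
            raise VisitDataError(
                f"{log.rat_id}: transition ({a.location}, {b.location}) "
                f"not on maze {maze.name}"
            ) from e
        for c in s:
            actions.append(c)
            src.append((a.trial_index, b.trial_index))
    return ActionTrace(actions, src)


def _pair_category(a: str, b: str) -> str:
    if a == b:
        return "repeat_straight" if a == "S" else "repeat_turn"
    if "S" in (a, b):
        return "turn_straight"
    return "turn_turn"


def classify_third_order(trace: ActionTrace) -> dict:
    """Counts of third-order categories over consecutive action pairs.

    Categories: ``repeat_turn`` (LL, RR), ``repeat_straight`` (SS),
    ``turn_turn`` (LR, RL) and ``turn_straight`` (LS, SL, RS, SR).  The four
    categories partition all consecutive pairs.
    """
    counts = {c: 0 for c in THIRD_ORDER_CATEGORIES}
    acts = trace.actions if isinstance(trace, ActionTrace) else list(trace)
    for a, b in zip(acts[:-1], acts[1:]):
        counts[_pair_category(a, b)] += 1
    return counts


def turn_straight_proportion(trace: ActionTrace) -> float:
    """Fraction of consecutive action pairs that switch between turn and S."""
    acts = trace.actions if isinstance(trace, ActionTrace) else list(trace)
    n_pairs = len(acts) - 1
    if n_pairs < 1:
        raise UndefinedStatisticError("need at least 2 actions")
    counts = classify_third_order(trace)
    return counts["turn_straight"] / n_pairs


def third_order_proportions(trace: ActionTrace) -> dict:
    """All four third-order category proportions."""
    acts = trace.actions if isinstance(trace, ActionTrace) else list(trace)
    n_pairs = len(acts) - 1
    if n_pairs < 1:
        raise UndefinedStatisticError("need at least 2 actions")
    counts = classify_third_order(trace)
    return {k: v / n_pairs for k, v in counts.items()}


def turn_after_straight_frequency(trace) -> float:
    """Empirical P(next action is a turn | previous action was S).

    The conditional counterpart of :func:`turn_straight_proportion`; it is
    the statistic the behavioral-state mixture predicts in steady state.
    """
    acts = trace.actions if isinstance(trace, ActionTrace) else list(trace)
    n_s = sum(1 for a in acts[:-1] if a == "S")
    if n_s == 0:
        raise UndefinedStatisticError("no straight actions precede another action")
    n_turn = sum(1 for a, b in zip(acts[:-1], acts[1:]) if a == "S" and b != "S")
    return n_turn / n_s


def reward_rate(log: VisitLog) -> float:
    """Proportion of visits that were rewarded."""
    if len(log) == 0:
        raise UndefinedStatisticError("empty visit log")
    return sum(log.rewards) / len(log)


def first_n_trials(log: VisitLog, n: int) -> VisitLog:
    """Restrict a log to its first ``n`` visits (first-order trials)."""
    return VisitLog(
        log.rat_id, log.group, log.phase, log.day, log.session, log.visits[:n], log.task
    )


def concatenate_logs(logs, rat_id=None) -> VisitLog:
    """Concatenate session logs (in the given order) into one visit stream.

    Trial indices are re-based so they stay strictly increasing; a synthetic
    boundary is allowed to repeat a location across sessions, in which case
    the first visit of the later session is dropped (the animal is placed on
    the maze afresh each session, so the pair spans no real transition).
    """
    logs = list(logs)
    if not logs:
        raise UndefinedStatisticError("no logs to concatenate")
    head = logs[0]
    visits = list(head.visits)
    offset = (visits[-1].trial_index + 1) if visits else 0
    for log in logs[1:]:
        vs = log.visits
        if visits and vs and vs[0].location == visits[-1].location:
            vs = vs[1:]
        for i, v in enumerate(vs):
            visits.append(Visit(offset + i, v.location, v.rewarded))
        offset = visits[-1].trial_index + 1 if visits else offset
    return VisitLog(
        rat_id or head.rat_id, head.group, head.phase, head.day, head.session,
        visits, head.task,
    )


def encode_first_n(logs, maze: MazeSpec, n: int) -> ActionTrace:
    """Actions of the first ``n`` visits across sessions, encoded per session.

    Sessions are taken in the given order; the pair spanning a session
    boundary is not encoded (the animal is removed from the maze between
    sessions, so it is not a real transition).
    """
    actions, src = [], []
    remaining = n
    for log in logs:
        sub = first_n_trials(log, remaining)
        tr = encode_actions(sub, maze)
        actions.extend(tr.actions)
        src.extend(tr.trial_of_action)
        remaining -= len(sub)
        if remaining <= 0:
            break
    return ActionTrace(actions, src)


def replay_consistent(log: VisitLog, task: str | None = None) -> bool:
    """True if some rule start state replays the log's reward flags exactly."""
    task = task or log.task
    if task is None:
        raise VisitDataError("log carries no task and none was given")
    n_states = 4 if task == "plus" else 2
    for k in range(n_states):
        state = _enumerated_state(task, k)
        ok = True
        for v in log.visits:
            rewarded, state = mazes.evaluate_visit(state, v.location)
            if rewarded != v.rewarded:
                ok = False
                break
        if ok:
            return True
    return False


def _enumerated_state(task: str, k: int):
    if task == "plus":
        need_home, last_outer = [(True, 3), (False, 3), (True, 2), (False, 2)][k]
        return mazes.RuleState("plus", last_outer=last_outer, need_home=need_home)
    ends = sorted(mazes.MAZES[task].rewarded_locations)
    return mazes.RuleState(task, last_outer=ends[k])
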