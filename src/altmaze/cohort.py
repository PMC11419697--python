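"""Synthetic two-phase cohorts of visit logs emulating the study design.

The generator reproduces the experiment's structure: 19 rats split into a
non-switching group (n = 10, five per Phase-1 maze) and a switching group
(n = 9, maze order counterbalanced with five running 2T-then-H); Phase 1 on
the H and/or 2T mazes (two sessions per day, up to 10 days, alternation
between the two rewarded ends); Phase 2 on the plus maze (two sessions per
day, 5 days, 1-2-1-3 alternation with the never-rewarded fourth arm and a
random rule start per session).  Rewards are always computed by the task
automaton, so generated logs replay cleanly.

Agent policies supply the choices: a lapse agent (perfect except on
``p_lapse`` trials), a ddCRP generative agent, a Markov mixture agent, or a
uniform random agent.  Group-specific parameters let every downstream
analysis stage demonstrate recovery of known contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import ddcrp, markov, mazes
from .codec import Visit, VisitLog
from .ddcrp import DdcrpParams
from .lapse import LapseStrategy
from .markov import MixtureParams


@dataclass
class AgentPolicy:
    """A choice policy: kind plus parameters, with per-group overrides."""

    kind: str  # "ddcrp" | "markov_mixture" | "lapse" | "random"
    params: dict = field(default_factory=dict)
    per_group: dict = field(default_factory=dict)

    def for_group(self, group: str) -> dict:
        out = dict(self.params)
        out.update(self.per_group.get(group, {}))
        return out


def _default_phase2_early() -> AgentPolicy:
    # Group-specific ddCRP processes for early plus-maze exploration: the
    # switching-like group has a longer timescale, stronger context
    # dependence and a repeat-avoiding base measure.
    return AgentPolicy(
        kind="ddcrp",
        per_group={
            "non-switching": {
                "params": DdcrpParams(
                    tau=1.5, context_weights=(0.02, 0.01), alpha=3.0, beta=1.8
                )
            },
            "switching": {
                "params": DdcrpParams(
                    tau=80.0, context_weights=(0.99, 0.95), alpha=0.6, beta=0.35
                )
            },
        },
    )


def _default_phase2_late() -> AgentPolicy:
    # Stable-performance lapse strategies: the non-switching-like group has a
    # home-location bias (alternation > reference errors); the switching-like
    # group a left-leaning turn bias (reference > alternation errors).
    return AgentPolicy(
        kind="lapse",
        per_group={
            "non-switching": {
                "strategy": LapseStrategy(
                    "location_bias", location_weights=(3.0, 1.0, 1.0, 0.0), p_lapse=0.22
                )
            },
            "switching": {
                "strategy": LapseStrategy(
                    "turn_bias", action_probs=(0.6, 0.4, 0.0), p_lapse=0.13
                )
            },
        },
    )


def _default_phase1() -> AgentPolicy:
    # Near-criterion Phase-1 performance: perfect alternation with occasional
    # lapses to a uniformly chosen other arm.
    return AgentPolicy(
        kind="lapse",
        params={
            "strategy": LapseStrategy(
                "location_bias", location_weights=(1.0, 1.0, 1.0, 1.0), p_lapse=0.2
            )
        },
    )


@dataclass
class CohortConfig:
    """Study-design parameters for a synthetic cohort."""

    n_nonswitching: int = 10
    n_switching: int = 9
    phase1_days: int = 10
    phase2_days: int = 5
    sessions_per_day: int = 2
    trials_per_session: int = 40
    agent: AgentPolicy = field(default_factory=_default_phase2_early)
    late_agent: AgentPolicy | None = field(default_factory=_default_phase2_late)
    late_start_session: int = 5  # phase-2 session number (1-based, across days)
    phase1_agent: AgentPolicy = field(default_factory=_default_phase1)
    seed: int = 0

    def __post_init__(self):
        for name in (
            "n_nonswitching", "n_switching", "phase1_days", "phase2_days",
            "sessions_per_day", "trials_per_session",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# Agents
# ---------------------------------------------------------------------------

def _arm_for_action(maze, current: int, action: str) -> int:
    for to in maze.locations:
        if to != current and maze.action_map[(current, to)] == action:
            return to
    raise ValueError(f"no arm reached by action {action!r} from {current}")


def run_lapse_agent(
    task: str,
    p_lapse: float,
    strategy: LapseStrategy,
    n_trials: int,
    seed,
    *,
    meta: dict | None = None,
    return_info: bool = False,
):
    """Visit log of an agent that is perfect except on lapse trials.

    On each trial the correct next location is chosen with probability
    ``1 - p_lapse``; otherwise the next location is drawn from the lapse
    strategy (turn bias: sample an action and move to the arm it leads to --
    plus maze only; location bias: sample from the reweighted location
    weights).  With ``return_info=True`` also returns a dict with the
    ground-truth lapse trial indices.
    """
    if strategy.kind == "turn_bias" and task != "plus":
        raise ValueError("turn-bias lapse sampling is defined on the plus maze")
    maze = mazes.MAZES[task]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    state = mazes.random_start_state(task, rng)
    visits = []
    lapse_trials = []
    current = None
    for t in range(n_trials):
        correct = state.expected_next
        if current is None:
            nxt = correct  # placed at the center; starts on the rule
        elif rng.random() < p_lapse:
            lapse_trials.append(t)
            if strategy.kind == "turn_bias":
                p = np.asarray(strategy.action_probs, dtype=float)
                a = int(rng.choice(3, p=p / p.sum()))
                nxt = _arm_for_action(maze, current, "LSR"[a])
            else:
                w = np.asarray(strategy.location_weights, dtype=float).copy()
                w[current - 1] = 0.0
                if w.sum() == 0:  # no reachable arm carries weight
                    nxt = correct
                else:
                    nxt = int(rng.choice(4, p=w / w.sum())) + 1
        else:
            nxt = correct
        rewarded, state = mazes.evaluate_visit(state, nxt)
        visits.append(Visit(t, nxt, rewarded))
        current = nxt
    m = meta or {}
    log = VisitLog(
        m.get("rat_id", "agent"), m.get("group", ""), m.get("phase", 2),
        m.get("day", 1), m.get("session", 1), visits, task,
    )
    if return_info:
        return log, {"lapse_trials": lapse_trials}
    return log


def _actions_to_log(actions, task: str, rng, meta: dict | None) -> VisitLog:
    """Map an egocentric action sequence onto plus-maze arm visits."""
    maze = mazes.MAZES[task]
    state = mazes.random_start_state(task, rng)
    current = int(rng.integers(4)) + 1  # free first choice from the center
    rewarded, state = mazes.evaluate_visit(state, current)
    visits = [Visit(0, current, rewarded)]
    for t, a in enumerate(actions, start=1):
        nxt = _arm_for_action(maze, current, a)
        rewarded, state = mazes.evaluate_visit(state, nxt)
        visits.append(Visit(t, nxt, rewarded))
        current = nxt
    m = meta or {}
    return VisitLog(
        m.get("rat_id", "agent"), m.get("group", ""), m.get("phase", 2),
        m.get("day", 1), m.get("session", 1), visits, task,
    )


def run_ddcrp_agent(
    params: DdcrpParams,
    n_trials: int,
    seed,
    *,
    meta: dict | None = None,
    history: list | None = None,
) -> VisitLog:
    """Plus-maze visit log generated by the ddCRP choice process.

    ``history`` (a mutable list of actions) lets one animal's choice process
    persist across sessions: new actions are conditioned on it and appended
    in place.  The session's first visit is a free choice from the center
    and consumes no action.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    given = history if history is not None else []
    actions = ddcrp.sample_sequence(params, max(n_trials - 1, 1), rng, given=given)
    actions = actions[: n_trials - 1]
    if history is not None:
        history.extend(actions)
    return _actions_to_log(actions, "plus", rng, meta)


def run_mixture_agent(
    chains: dict,
    m: MixtureParams,
    n_trials: int,
    seed,
    *,
    meta: dict | None = None,
) -> VisitLog:
    """Plus-maze visit log from the behavioral-state mixture process."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    B = markov.behavioral_state_matrix(m)
    s = int(rng.integers(3))  # uniform initial behavioral state
    actions: list[str] = []
    for _ in range(max(n_trials - 1, 0)):
        s = int(rng.choice(3, p=B[s]))
        if len(actions) < 2:
            p = np.full(3, 1.0 / 3.0)
        else:
            key = markov.BEHAVIOR_STATES[s]
            p = chains[key].conditional(actions[-2], actions[-1])
        actions.append("LSR"[int(rng.choice(3, p=p))])
    return _actions_to_log(actions, "plus", rng, meta)


def run_random_agent(task: str, n_trials: int, seed, *, meta: dict | None = None) -> VisitLog:
    """Uniform choice over the three other arms on every trial."""
    strategy = LapseStrategy("location_bias", location_weights=(1, 1, 1, 1), p_lapse=1.0)
    return run_lapse_agent(task, 1.0, strategy, n_trials, seed, meta=meta)


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

def _assign_rats(config: CohortConfig):
    rats = []
    half = config.n_nonswitching // 2
    for i in range(config.n_nonswitching):
        maze_name = "H" if i < half else "2T"
        rats.append(
            {
                "rat_id": f"NS{i + 1:02d}",
                "group": "non-switching",
                "session_mazes": (maze_name, maze_name),
            }
        )
    first_2t = (config.n_switching + 1) // 2  # 5 of 9 run 2T first
    for i in range(config.n_switching):
        order = ("2T", "H") if i < first_2t else ("H", "2T")
        rats.append(
            {"rat_id": f"SW{i + 1:02d}", "group": "switching", "session_mazes": order}
        )
    return rats


def _run_policy_session(
    policy: AgentPolicy, group: str, task: str, n_trials, rng, meta, history=None
):
    p = policy.for_group(group)
    if policy.kind == "lapse":
        strategy = p["strategy"]
        return run_lapse_agent(
            task, strategy.p_lapse, strategy, n_trials, rng, meta=meta
        )
    if policy.kind == "ddcrp":
        if task != "plus":
            raise ValueError("ddcrp agent runs on the plus maze")
        return run_ddcrp_agent(p["params"], n_trials, rng, meta=meta, history=history)
    if policy.kind == "markov_mixture":
        if task != "plus":
            raise ValueError("markov_mixture agent runs on the plus maze")
        return run_mixture_agent(p["chains"], p["mixture"], n_trials, rng, meta=meta)
    if policy.kind == "random":
        return run_random_agent(task, n_trials, rng, meta=meta)
    raise ValueError(f"unknown agent kind {policy.kind!r}")


def generate_cohort(config: CohortConfig | None = None) -> list:
    """Generate the full two-phase cohort of visit logs (deterministic per seed)."""
    config = config or CohortConfig()
    rats = _assign_rats(config)
    root = np.random.SeedSequence(config.seed)
    logs = []
    for rat, ss in zip(rats, root.spawn(len(rats))):
        rng = np.random.default_rng(ss)
        needs_chains = config.agent.kind == "markov_mixture" or (
            config.late_agent is not None and config.late_agent.kind == "markov_mixture"
        )
        rat_logs = []
        for day in range(1, config.phase1_days + 1):
            for sess in range(1, config.sessions_per_day + 1):
                task = rat["session_mazes"][(sess - 1) % 2]
                meta = {
                    "rat_id": rat["rat_id"], "group": rat["group"],
                    "phase": 1, "day": day, "session": sess,
                }
                rat_logs.append(
                    _run_policy_session(
                        config.phase1_agent, rat["group"], task,
                        config.trials_per_session, rng, meta,
                    )
                )
        chains = markov.estimate_phase1_chains(rat_logs) if needs_chains else None
        ddcrp_history: list = []  # one choice process per rat, across sessions
        session_no = 0
        for day in range(1, config.phase2_days + 1):
            for sess in range(1, config.sessions_per_day + 1):
                session_no += 1
                policy = config.agent
                if (
                    config.late_agent is not None
                    and session_no >= config.late_start_session
                ):
                    policy = config.late_agent
                if policy.kind == "markov_mixture":
                    policy = replace(
                        policy,
                        params={**policy.params, "chains": chains},
                    )
                meta = {
                    "rat_id": rat["rat_id"], "group": rat["group"],
                    "phase": 2, "day": day, "session": sess,
                }
                rat_logs.append(
                    _run_policy_session(
                        policy, rat["group"], "plus",
                        config.trials_per_session, rng, meta,
                        history=ddcrp_history,
                    )
                )
        logs.extend(rat_logs)
    return logs
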