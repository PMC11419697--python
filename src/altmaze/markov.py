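"""Second-order Markov chains and the behavioral-state mixture simulator.

Phase-1 behavior is summarised per rat as a second-order Markov chain over
actions: P(y_t = c | y_{t-1} = b, y_{t-2} = a) estimated with add-one
regularization.  Plus-maze behavior is then modelled as a mixture: a latent
behavioral state s_t in {M, A, E} selects which chain generates the next
action (morning task, afternoon task, or a flat exploratory chain), with
switching governed by q_E (probability of exploration) and q_S (probability
of switching task models).  The composite process over
(s_t, y_{t-1}, y_{t-2}) is a 27-state Markov chain whose steady state yields
analytic statistics such as the probability of turning after going straight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.base import BaseEstimator

from . import codec, mazes

ACTIONS = ("L", "S", "R")
_A2I = {a: i for i, a in enumerate(ACTIONS)}
BEHAVIOR_STATES = ("M", "A", "E")


@dataclass(frozen=True)
class SecondOrderChain:
    """3x3x3 table: probs[a, b, c] = P(y_t = c | y_{t-1} = b, y_{t-2} = a)."""

    probs: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (3, 3, 3):
            raise ValueError("probs must be 3x3x3")
        if not np.allclose(p.sum(axis=2), 1.0):
            raise ValueError("conditional distributions must sum to 1")
        if np.any(p <= 0):
            raise ValueError("entries must be strictly positive")
        object.__setattr__(self, "probs", p)

    def conditional(self, prev2: str, prev1: str) -> np.ndarray:
        return self.probs[_A2I[prev2], _A2I[prev1]]


@dataclass(frozen=True)
class MixtureParams:
    """q_E: probability of exploration; q_S: probability of switching tasks."""

    q_E: float
    q_S: float

    def __post_init__(self):
        if not (0.0 <= self.q_E <= 1.0 and 0.0 <= self.q_S <= 1.0):
            raise ValueError("q_E and q_S must lie in [0, 1]")


def estimate_chain(trace) -> SecondOrderChain:
    """Add-one regularized second-order transition estimate from a trace."""
    acts = getattr(trace, "actions", trace)
    y = [_A2I[a] for a in acts]
    counts = np.zeros((3, 3, 3))
    for a, b, c in zip(y[:-2], y[1:-1], y[2:]):
        counts[a, b, c] += 1
    counts += 1.0
    return SecondOrderChain(counts / counts.sum(axis=2, keepdims=True))


def flat_chain() -> SecondOrderChain:
    """Exploratory chain: every action has probability 1/3 in every context."""
    return SecondOrderChain(np.full((3, 3, 3), 1.0 / 3.0))


class SecondOrderMarkovChain(BaseEstimator):
    """sklearn-style wrapper over :func:`estimate_chain`.

    ``fit(actions)`` sets ``chain_`` / ``probs_``; ``predict_proba`` returns
    the conditional distribution for a 2-action history.
    """

    def fit(self, X, y=None):
        self.chain_ = estimate_chain(X)
        self.probs_ = self.chain_.probs
        return self

    def predict_proba(self, history) -> np.ndarray:
        a, b = history[-2], history[-1]
        return self.chain_.conditional(a, b)


def behavioral_state_matrix(m: MixtureParams) -> np.ndarray:
    """Row-stochastic 3x3 matrix over behavioral states (M, A, E)."""
    qE, qS = m.q_E, m.q_S
    return np.array(
        [
            [(1 - qS) * (1 - qE), qS * (1 - qE), qE],
            [qS * (1 - qE), (1 - qS) * (1 - qE), qE],
            [qE / 2.0, qE / 2.0, 1 - qE],
        ]
    )


@dataclass
class CompositeChain:
    """27-state chain over (behavioral state, y_{t-1}, y_{t-2}).

    State index = 9 * s + 3 * b + a for s over (M, A, E), b = previous
    action, a = action before that.  A transition
    (s, b, a) -> (s', c, b') is admissible only when b' == b; admissible
    entries carry B[s, s'] * P_{s'}(c | b, a).
    """

    transition: np.ndarray
    chains: dict = field(default_factory=dict)
    mixture: MixtureParams | None = None
    stationary: np.ndarray | None = None

    @staticmethod
    def state_index(s: str, prev1: str, prev2: str) -> int:
        return 9 * BEHAVIOR_STATES.index(s) + 3 * _A2I[prev1] + _A2I[prev2]

    @staticmethod
    def state_tuple(idx: int):
        s, rem = divmod(idx, 9)
        b, a = divmod(rem, 3)
        return BEHAVIOR_STATES[s], ACTIONS[b], ACTIONS[a]


def build_composite(chains: dict, m: MixtureParams) -> CompositeChain:
    """Compose the three per-state chains with the behavioral-state process."""
    B = behavioral_state_matrix(m)
    P = {k: chains[k].probs for k in BEHAVIOR_STATES}
    T = np.zeros((27, 27))
    for s in range(3):
        for b in range(3):
            for a in range(3):
                src = 9 * s + 3 * b + a
                for s2 in range(3):
                    for c in range(3):
                        dst = 9 * s2 + 3 * c + b  # y_{t-1} of target == b
                        T[src, dst] = B[s, s2] * P[BEHAVIOR_STATES[s2]][a, b, c]
    return CompositeChain(transition=T, chains=dict(chains), mixture=m)


def steady_state(chain: CompositeChain, tol: float = 1e-9) -> np.ndarray:
    """Stationary distribution pi with pi @ T = pi and sum(pi) = 1.

    Solved from the null space of (T' - I).  When the chain is reducible and
    the stationary distribution is not unique (e.g. q_E = 0), the limit of
    Cesaro-averaged power iteration from a uniform start is returned with a
    warning.
    """
    T = chain.transition
    n = T.shape[0]
    if not np.allclose(T.sum(axis=1), 1.0):
        raise ValueError("transition matrix rows must sum to 1")
    _, s, vt = linalg.svd(T.T - np.eye(n))
    null_dim = int(np.sum(s < 1e-8))
    if null_dim == 1:
        pi = np.real(vt[-1])
        pi = pi / pi.sum()
        if pi.min() < -1e-8:
            raise RuntimeError("stationary solve produced negative mass")
        pi = np.clip(pi, 0.0, None)
        pi /= pi.sum()
    else:
        warnings.warn(
            "composite chain has a non-unique stationary distribution; "
            "returning the Cesaro limit of power iteration from uniform"
        )
        x = np.full(n, 1.0 / n)
        avg = np.zeros(n)
        n_iter = 20000
        for k in range(n_iter):
            x = x @ T
            avg += x
        pi = avg / n_iter
        pi /= pi.sum()
    chain.stationary = pi
    return pi


def action_pair_marginal(pi: np.ndarray) -> np.ndarray:
    """Marginal over (y_{t-1}, y_{t-2}) pairs, summing out behavioral state."""
    return pi.reshape(3, 9).sum(axis=0).reshape(3, 3)


def turn_after_straight_prob(chain: CompositeChain) -> float:
    """P(y_t is a turn | y_{t-1} = S) in steady state."""
    pi = chain.stationary if chain.stationary is not None else steady_state(chain)
    s_idx = _A2I["S"]
    mask_src = np.zeros(27, dtype=bool)
    for u in range(27):
        _, b, _ = CompositeChain.state_tuple(u)
        mask_src[u] = b == "S"
    p_prev_s = pi[mask_src].sum()
    if p_prev_s <= 0:
        raise codec.UndefinedStatisticError("pi(y_{t-1} = S) is zero")
    mask_turn = np.zeros(27, dtype=bool)
    for v in range(27):
        _, c, _ = CompositeChain.state_tuple(v)
        mask_turn[v] = c != "S"
    num = pi[mask_src] @ chain.transition[np.ix_(mask_src, mask_turn)].sum(axis=1)
    return float(num / p_prev_s)


def simulate_walk(chain: CompositeChain, n_steps: int, seed) -> np.ndarray:
    """Sample a state-index path of the composite chain (for Monte-Carlo checks)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cum = np.cumsum(chain.transition, axis=1)
    path = np.empty(n_steps, dtype=np.int64)
    x = int(rng.integers(27))
    u = rng.random(n_steps)
    for t in range(n_steps):
        x = int(np.searchsorted(cum[x], u[t]))
        path[t] = min(x, 26)
    return path


def sweep_mixture(chains: dict, grid, observed: float) -> pd.DataFrame:
    """Model-vs-observed turn/straight difference over a (q_E, q_S) grid.

    ``grid`` is an iterable of (q_E, q_S) pairs or ``None`` for the default
    0..1 lattice in steps of 0.05.  Returns a tidy DataFrame with columns
    q_E, q_S, predicted, observed, difference.
    """
    if grid is None:
        vals = np.round(np.arange(0.0, 1.0001, 0.05), 10)
        grid = [(qe, qs) for qe in vals for qs in vals]
    rows = []
    for qe, qs in grid:
        comp = build_composite(chains, MixtureParams(qe, qs))
        pred = turn_after_straight_prob(comp)
        rows.append(
            {
                "q_E": qe,
                "q_S": qs,
                "predicted": pred,
                "observed": observed,
                "difference": pred - observed,
            }
        )
    return pd.DataFrame(rows)


def estimate_phase1_chains(logs, last_days: int = 5) -> dict:
    """Per-rat morning/afternoon chains from Phase-1 logs.

    Session 1 of each day is the morning session (-> P_M), session 2 the
    afternoon (-> P_A); only the last ``last_days`` calendar days present are
    used.  Returns ``{"M": chain, "A": chain, "E": flat_chain()}``.
    """
    p1 = [log for log in logs if log.phase == 1]
    if not p1:
        raise ValueError("no phase-1 logs")
    days = sorted({log.day for log in p1})[-last_days:]
    out = {}
    for key, sess in (("M", 1), ("A", 2)):
        acts = []
        for log in sorted(p1, key=lambda l: (l.day, l.session)):
            if log.day in days and log.session == sess:
                if log.task is None:
                    raise ValueError(f"{log.rat_id}: phase-1 log carries no task")
                acts.extend(codec.encode_actions(log, mazes.MAZES[log.task]).actions)
        out[key] = estimate_chain(acts)
    out["E"] = flat_chain()
    return out
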