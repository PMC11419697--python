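"""Modified sequential distance-dependent Chinese restaurant process (ddCRP).

The model describes a sequence of egocentric actions y_1, y_2, ... over
{L, S, R}.  The probability of action A on trial i is

    p(y_i = A | y_{1:i-1}, theta)  propto  alpha * G_i(A) + sum_{j<i, y_j=A} f(i, j)

with the distance function

    f(i, j) = exp(-|i - j| / tau) * prod_{d=1..D} (1 - C_d)^{m_d(i, j)},

where m_d(i, j) = 0 when trials i and j share the same context of depth d
(the d actions immediately preceding each trial agree) and 1 otherwise.  The
base measure G_i puts weight proportional to beta on the previous action and
1 on the other two (a switch/stay bias); alpha concentrates choices toward
the base measure.  With C_d = 0 and tau -> infinity every past trial has
weight 1 and the rule reduces to the standard Chinese restaurant process.

Parameters are estimated in a Bayesian framework by adaptive random-walk
Metropolis MCMC with independent priors tau ~ Gamma(2, 20),
C_d ~ Uniform(0, 1), alpha ~ Gamma(2, 2), beta ~ Gamma(20, 1/20)
(shape/scale); convergence is assessed with rank-normalized split R-hat and
the posterior median is the point estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

ACTIONS = ("L", "S", "R")
_A2I = {a: i for i, a in enumerate(ACTIONS)}

PARAM_NAMES = ("tau", "C1", "C2", "alpha", "beta")


@dataclass(frozen=True)
class DdcrpParams:
    """The four ddCRP parameters (context weights may have depth D >= 1)."""

    tau: float
    context_weights: tuple = (0.0, 0.0)  # C_d for d = 1..D
    alpha: float = 1.0
    beta: float = 1.0

    def __post_init__(self):
        if not self.tau > 0:
            raise ValueError("tau must be positive")
        if any(not (0.0 <= c <= 1.0) for c in self.context_weights):
            raise ValueError("context weights must lie in [0, 1]")
        if not self.alpha > 0 or not self.beta > 0:
            raise ValueError("alpha and beta must be positive")

    def as_dict(self):
        d = {"tau": self.tau, "alpha": self.alpha, "beta": self.beta}
        for i, c in enumerate(self.context_weights, start=1):
            d[f"C{i}"] = c
        return d


@dataclass(frozen=True)
class DdcrpPriors:
    """Independent priors, gamma ones parameterized as (shape, scale)."""

    tau: tuple = (2.0, 20.0)
    alpha: tuple = (2.0, 2.0)
    beta: tuple = (20.0, 1.0 / 20.0)
    c_bounds: tuple = (0.0, 1.0)

    def sample_params(self, rng: np.random.Generator, depth: int = 2) -> DdcrpParams:
        lo, hi = self.c_bounds
        return DdcrpParams(
            tau=rng.gamma(*self.tau_shape_scale()),
            context_weights=tuple(rng.uniform(lo, hi, size=depth)),
            alpha=rng.gamma(self.alpha[0], self.alpha[1]),
            beta=rng.gamma(self.beta[0], self.beta[1]),
        )

    def tau_shape_scale(self):
        return self.tau

    def medians(self, depth: int = 2) -> dict:
        med = {
            "tau": stats.gamma.median(self.tau[0], scale=self.tau[1]),
            "alpha": stats.gamma.median(self.alpha[0], scale=self.alpha[1]),
            "beta": stats.gamma.median(self.beta[0], scale=self.beta[1]),
        }
        for d in range(1, depth + 1):
            med[f"C{d}"] = 0.5 * (self.c_bounds[0] + self.c_bounds[1])
        return med


def _to_int(actions) -> np.ndarray:
    acts = getattr(actions, "actions", actions)
    return np.array([_A2I[a] for a in acts], dtype=np.int64)


def _context_mismatch(y: np.ndarray, depth: int) -> np.ndarray:
    """M[d-1, i, j] = m_d(i+1, j+1) for the realized trace (0-based trials).

    m_d = 0 iff the d actions preceding trials i and j agree and both
    contexts exist; trials with fewer than d predecessors count as
    mismatching (an undefined context confers no context-match weight).
    """
    n = len(y)
    E = y[:, None] == y[None, :]
    M = np.ones((depth, n, n))
    for d in range(1, depth + 1):
        if n <= d:
            continue
        ok = np.logical_and.reduce(
            [E[d - k : n - k, d - k : n - k] for k in range(1, d + 1)]
        )
        M[d - 1, d:, d:][ok] = 0.0
    return M


def _precompute(y: np.ndarray, depth: int = 2) -> dict:
    n = len(y)
    idx = np.arange(n)
    delta = idx[:, None] - idx[None, :]
    past = delta > 0  # j strictly before i
    same = (y[:, None] == y[None, :]).astype(float)
    repeat_prev = np.zeros(n, dtype=bool)
    repeat_prev[1:] = y[1:] == y[:-1]
    return {
        "y": y,
        "n": n,
        "delta": np.where(past, delta, 1).astype(float),
        "past": past.astype(float),
        "same": same,
        "M": _context_mismatch(y, depth),
        "repeat_prev": repeat_prev,
    }


def _loglik_pre(pre: dict, tau, cs, alpha, beta) -> float:
    """Exact sequential log-likelihood of the realized trace."""
    with np.errstate(divide="ignore"):
        W = np.exp(-pre["delta"] / tau)
    for d, c in enumerate(cs):
        W = W * np.power(1.0 - c, pre["M"][d])
    W = W * pre["past"]
    S = W.sum(axis=1)  # total past weight per trial
    A = (W * pre["same"]).sum(axis=1)  # past weight on the realized action
    # normalized base measure evaluated at the realized action
    g = np.where(pre["repeat_prev"], beta, 1.0) / (beta + 2.0)
    g[0] = 1.0 / 3.0
    return float(np.sum(np.log(alpha * g + A) - np.log(alpha + S)))


def choice_distribution(history, params: DdcrpParams, i: int | None = None) -> np.ndarray:
    """Predictive distribution over (L, S, R) for the next trial.

    ``history`` holds actions y_1..y_{i-1}; ``i`` defaults to
    ``len(history) + 1`` and is validated if given.  Probabilities are
    explicitly normalized.
    """
    y = _to_int(history)
    n = len(y)
    if i is not None and i != n + 1:
        raise ValueError(f"trial index {i} inconsistent with history length {n}")
    depth = len(params.context_weights)
    if n == 0:
        return np.full(3, 1.0 / 3.0)
    # base measure anchored on the previous action
    g = np.full(3, 1.0 / (params.beta + 2.0))
    g[y[-1]] = params.beta / (params.beta + 2.0)
    weights = params.alpha * g
    ii = n  # 0-based index of the predicted trial
    for j in range(n):
        f = np.exp(-(ii - j) / params.tau)
        for d, c in enumerate(params.context_weights, start=1):
            match = (
                ii >= d
                and j >= d
                and np.array_equal(y[ii - d : ii], y[j - d : j])
            )
            if not match:
                f *= 1.0 - c
        weights[y[j]] += f
    return weights / weights.sum()


def sequence_loglik(trace, params: DdcrpParams) -> float:
    """Log probability of an action sequence under the sequential predictive rule."""
    y = _to_int(trace)
    if len(y) == 0:
        raise ValueError("empty trace")
    pre = _precompute(y, depth=len(params.context_weights))
    return _loglik_pre(pre, params.tau, params.context_weights, params.alpha, params.beta)


def sample_sequence(params: DdcrpParams, n_trials: int, seed, given=()) -> list:
    """Draw an action sequence from the generative process (deterministic per seed).

    ``given`` is an optional already-realized history to condition on; only
    the ``n_trials`` new actions are returned.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hist = list(getattr(given, "actions", given))
    n_given = len(hist)
    for _ in range(n_trials):
        p = choice_distribution(hist, params)
        hist.append(ACTIONS[rng.choice(3, p=p)])
    return hist[n_given:]


# ---------------------------------------------------------------------------
# Bayesian fitting: adaptive random-walk Metropolis in transformed space
# ---------------------------------------------------------------------------

def _unpack(z: np.ndarray, depth: int):
    tau = np.exp(z[0])
    cs = 1.0 / (1.0 + np.exp(-z[1 : 1 + depth]))
    alpha = np.exp(z[1 + depth])
    beta = np.exp(z[2 + depth])
    return tau, cs, alpha, beta


def _log_post(z: np.ndarray, pre: dict, priors: DdcrpPriors, depth: int) -> float:
    """Unnormalized log posterior in transformed coordinates.

    Gamma log-densities are written up to additive constants (they cancel in
    Metropolis ratios); log-Jacobians of the log/logit transforms included.
    """
    tau, cs, alpha, beta = _unpack(z, depth)
    if not np.isfinite(tau) or not np.isfinite(alpha) or not np.isfinite(beta):
        return -np.inf
    lp = _loglik_pre(pre, tau, cs, alpha, beta)
    for x, (shape, scale), zval in (
        (tau, priors.tau, z[0]),
        (alpha, priors.alpha, z[1 + depth]),
        (beta, priors.beta, z[2 + depth]),
    ):
        lp += (shape - 1.0) * np.log(x) - x / scale + zval
    # uniform C prior with logistic-transform Jacobian
    lp += float(np.sum(np.log(cs) + np.log1p(-cs)))
    return lp if np.isfinite(lp) else -np.inf


def _run_chain(pre, priors, depth, n_warmup, n_samples, rng):
    dim = depth + 3
    theta0 = priors.sample_params(rng, depth)
    z = np.empty(dim)
    z[0] = np.log(theta0.tau)
    cs0 = np.clip(np.asarray(theta0.context_weights), 1e-4, 1 - 1e-4)
    z[1 : 1 + depth] = np.log(cs0) - np.log1p(-cs0)
    z[1 + depth] = np.log(theta0.alpha)
    z[2 + depth] = np.log(theta0.beta)
    lp = _log_post(z, pre, priors, depth)
    scale = 0.5
    mean = np.zeros(dim)
    m2 = np.zeros(dim)
    count = 0
    draws = np.empty((n_samples, dim))
    n_acc = 0
    for t in range(n_warmup + n_samples):
        if count > 10:
            step = scale * np.sqrt(m2 / count + 1e-6)
        else:
            step = scale
        prop = z + rng.normal(size=dim) * step
        lp_prop = _log_post(prop, pre, priors, depth)
        accept = np.log(rng.uniform()) < lp_prop - lp
        if accept:
            z, lp = prop, lp_prop
        if t < n_warmup:
            scale *= np.exp((float(accept) - 0.3) / (t + 1) ** 0.6)
            count += 1
            delta = z - mean
            mean += delta / count
            m2 += delta * (z - mean)
        else:
            draws[t - n_warmup] = z
            n_acc += int(accept)
    tau, cs, alpha, beta = _unpack(draws.T, depth)
    out = {"tau": tau, "alpha": alpha, "beta": beta}
    for d in range(depth):
        out[f"C{d + 1}"] = cs[d]
    return out, n_acc / max(n_samples, 1)


@dataclass
class PosteriorFit:
    """MCMC output: pooled draws, convergence diagnostics, point estimate."""

    draws: dict  # param name -> (n_chains, n_samples) array
    n_chains: int
    n_samples: int
    rhat: dict
    point_estimate: DdcrpParams
    seed: int | None = None
    converged: bool = True
    acceptance: tuple = ()

    def to_frame(self) -> pd.DataFrame:
        cols = {}
        for name, arr in self.draws.items():
            cols[name] = arr.reshape(-1)
        df = pd.DataFrame(cols)
        df.insert(0, "chain", np.repeat(np.arange(self.n_chains), self.n_samples))
        df.insert(1, "draw", np.tile(np.arange(self.n_samples), self.n_chains))
        return df

    def summary(self) -> dict:
        return {
            "point_estimate": self.point_estimate.as_dict(),
            "rhat": {k: float(v) for k, v in self.rhat.items()},
            "n_chains": self.n_chains,
            "n_samples": self.n_samples,
            "converged": bool(self.converged),
        }


def posterior_median(fit: PosteriorFit) -> DdcrpParams:
    """Elementwise median of the pooled draws, as a parameter set."""
    if not fit.converged:
        warnings.warn("posterior median taken from a non-converged fit")
    med = {k: float(np.median(v)) for k, v in fit.draws.items()}
    depth = sum(1 for k in med if k.startswith("C"))
    return DdcrpParams(
        tau=med["tau"],
        context_weights=tuple(med[f"C{d}"] for d in range(1, depth + 1)),
        alpha=med["alpha"],
        beta=med["beta"],
    )


def fit_mcmc(
    trace,
    priors: DdcrpPriors | None = None,
    n_chains: int = 4,
    n_samples: int = 1000,
    n_warmup: int = 1000,
    seed: int | None = None,
    context_depth: int = 2,
    rhat_threshold: float = 1.05,
) -> PosteriorFit:
    """Fit the ddCRP to one action sequence by MCMC.

    Runs ``n_chains`` independent adaptive random-walk Metropolis chains of
    ``n_samples`` retained draws each (after ``n_warmup`` adaptation steps),
    computes per-parameter rank-normalized split R-hat, and flags the fit as
    non-converged when any R-hat exceeds ``rhat_threshold``.
    """
    y = _to_int(trace)
    if len(y) < 2:
        raise ValueError("need at least 2 trials to fit")
    priors = priors or DdcrpPriors()
    pre = _precompute(y, depth=context_depth)
    root = np.random.SeedSequence(seed)
    chains = []
    acc = []
    for child in root.spawn(n_chains):
        rng = np.random.default_rng(child)
        draws, a = _run_chain(pre, priors, context_depth, n_warmup, n_samples, rng)
        chains.append(draws)
        acc.append(a)
    names = list(chains[0])
    pooled = {k: np.stack([c[k] for c in chains]) for k in names}
    idata = az.from_dict(posterior=pooled)
    rhat_ds = az.rhat(idata)
    rhat = {k: float(rhat_ds[k].values) for k in names}
    converged = all(np.isfinite(v) and v <= rhat_threshold for v in rhat.values())
    if not converged:
        warnings.warn(
            f"MCMC did not converge: max R-hat = {max(rhat.values()):.3f}"
        )
    med = {k: float(np.median(v)) for k, v in pooled.items()}
    point = DdcrpParams(
        tau=med["tau"],
        context_weights=tuple(med[f"C{d}"] for d in range(1, context_depth + 1)),
        alpha=med["alpha"],
        beta=med["beta"],
    )
    return PosteriorFit(
        draws=pooled,
        n_chains=n_chains,
        n_samples=n_samples,
        rhat=rhat,
        point_estimate=point,
        seed=seed,
        converged=converged,
        acceptance=tuple(acc),
    )


class DistanceDependentCRP(BaseEstimator):
    """sklearn-style estimator wrapper around :func:`fit_mcmc`.

    ``fit(actions)`` estimates the posterior for one animal's action
    sequence; fitted attributes are ``fit_`` (the :class:`PosteriorFit`),
    ``params_`` (posterior-median :class:`DdcrpParams`), ``rhat_`` and
    ``converged_``.  ``score(actions)`` returns the sequence log-likelihood
    at the point estimate and ``predict_proba(history)`` the next-trial
    choice distribution.
    """

    def __init__(
        self,
        priors: DdcrpPriors | None = None,
        n_chains: int = 4,
        n_samples: int = 1000,
        n_warmup: int = 1000,
        context_depth: int = 2,
        rhat_threshold: float = 1.05,
        seed: int | None = None,
    ):
        self.priors = priors
        self.n_chains = n_chains
        self.n_samples = n_samples
        self.n_warmup = n_warmup
        self.context_depth = context_depth
        self.rhat_threshold = rhat_threshold
        self.seed = seed

    def fit(self, X, y=None):
        self.fit_ = fit_mcmc(
            X,
            priors=self.priors,
            n_chains=self.n_chains,
            n_samples=self.n_samples,
            n_warmup=self.n_warmup,
            seed=self.seed,
            context_depth=self.context_depth,
            rhat_threshold=self.rhat_threshold,
        )
        self.params_ = self.fit_.point_estimate
        self.rhat_ = self.fit_.rhat
        self.converged_ = self.fit_.converged
        return self

    def predict_proba(self, history) -> np.ndarray:
        return choice_distribution(history, self.params_)

    def score(self, X, y=None) -> float:
        return sequence_loglik(X, self.params_)

    def sample(self, n_trials: int, seed=None) -> list:
        return sample_sequence(self.params_, n_trials, seed)
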