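"""Action-sequence probability vectors and group-level comparisons.

For each animal the probability of every action sequence of length 1, 2 and
3 over {L, S, R} is estimated from overlapping windows of its action trace,
giving a 39-entry vector (3 + 9 + 27).  Vectors are stacked into an
animals x sequences matrix, visualised as a conditional-probability
dendrogram, embedded by PCA, and compared between experience groups by
pairwise cosine similarity.  The pairwise Wilcoxon rank-sum /
Benjamini-Hochberg utility used throughout the pipeline also lives here.
"""

from __future__ import annotations

import itertools
import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .codec import ActionTrace, UndefinedStatisticError

ACTIONS = ("L", "S", "R")


def all_sequences(max_len: int = 3):
    """All action sequences of length 1..max_len, shortest first."""
    out = []
    for k in range(1, max_len + 1):
        out.extend("".join(p) for p in itertools.product(ACTIONS, repeat=k))
    return out


SEQUENCES_39 = tuple(all_sequences(3))


def sequence_probabilities(trace, max_len: int = 3) -> pd.Series:
    """Window probabilities of every sequence of length 1..max_len.

    The probability of a length-k sequence is its count among all
    overlapping length-k windows divided by the number of such windows.
    Returns a Series indexed by sequence string.
    """
    acts = trace.actions if isinstance(trace, ActionTrace) else list(trace)
    n = len(acts)
    if n < max_len:
        raise UndefinedStatisticError(
            f"trace of length {n} too short; need at least {max_len} actions"
        )
    s = "".join(acts)
    out = {}
    for seq in all_sequences(max_len):
        k = len(seq)
        n_windows = n - k + 1
        count = sum(1 for i in range(n_windows) if s[i : i + k] == seq)
        out[seq] = count / n_windows
    return pd.Series(out, name=getattr(trace, "rat_id", None))


class SequenceProbabilityEncoder(BaseEstimator, TransformerMixin):
    """Encode action traces as sequence-probability row vectors.

    A stateless sklearn-style transformer: ``transform`` maps a list of
    traces (or action lists) to an ``(n_animals, n_sequences)`` array whose
    columns follow :func:`all_sequences`.

    Parameters
    ----------
    max_len : int, default 3
        Longest window length.
    lengths : tuple or None
        Restrict the output to these window lengths (e.g. ``(3,)`` for the
        27 three-trial sequences only).  ``None`` keeps all lengths.
    """

    def __init__(self, max_len: int = 3, lengths=None):
        self.max_len = max_len
        self.lengths = lengths

    def fit(self, X, y=None):
        self.sequences_ = [
            s
            for s in all_sequences(self.max_len)
            if self.lengths is None or len(s) in self.lengths
        ]
        return self

    def transform(self, X):
        if not hasattr(self, "sequences_"):
            self.fit(X)
        rows = [sequence_probabilities(t, self.max_len)[self.sequences_] for t in X]
        return np.asarray(rows, dtype=float)


def dendrogram_edges(vec: pd.Series):
    """Edge list (parent, child, conditional probability) of the sequence tree.

    Root-level edges (parent ``""``) carry the length-1 probabilities; deeper
    edges carry P(child)/P(parent).  Zero-probability parents contribute no
    descendant edges.
    """
    edges = []
    for seq, p in vec.items():
        if len(seq) == 1:
            edges.append(("", seq, float(p)))
        else:
            parent = seq[:-1]
            pp = vec.get(parent, 0.0)
            if pp > 0:
                edges.append((parent, seq, float(p / pp)))
    return edges


def dendrogram_graph(vec: pd.Series) -> nx.DiGraph:
    """The sequence tree as a directed graph (for GraphML export)."""
    g = nx.DiGraph()
    g.add_node("root")
    for parent, child, w in dendrogram_edges(vec):
        g.add_edge(parent or "root", child, probability=w)
    return g


def export_dendrogram(vec: pd.Series, csv_path=None, graphml_path=None):
    edges = dendrogram_edges(vec)
    if csv_path is not None:
        pd.DataFrame(edges, columns=["parent", "child", "probability"]).to_csv(
            csv_path, index=False
        )
    if graphml_path is not None:
        nx.write_graphml(dendrogram_graph(vec), graphml_path)
    return edges


def pca_embed(matrix) -> np.ndarray:
    """Scores of mean-centered rows on all principal components.

    Rows are animals; no variance scaling is applied (entries share units).
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    n_comp = min(X.shape[0], X.shape[1])
    return PCA(n_components=n_comp, svd_solver="full").fit_transform(X)


def cosine_similarity_groups(scores, labels):
    """Pairwise cosine similarities split into within- and across-group sets.

    ``scores`` is the (animals x components) matrix; ``labels`` the group of
    each row.  Both same-group kinds are pooled into ``within``.  Zero
    vectors make cosine undefined; such pairs are dropped with a warning.
    """
    X = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    norms = np.linalg.norm(X, axis=1)
    within, across = [], []
    n_dropped = 0
    for i in range(len(X)):
        for j in range(i + 1, len(X)):
            if norms[i] == 0 or norms[j] == 0:
                n_dropped += 1
                continue
            c = float(X[i] @ X[j] / (norms[i] * norms[j]))
            (within if labels[i] == labels[j] else across).append(c)
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} pairs with zero-norm score vectors")
    return np.asarray(within), np.asarray(across)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    _, adj, _, _ = multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")
    return adj


def pairwise_wilcoxon_bh(groups_by_condition, alpha: float = 0.05) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum tests with Benjamini-Hochberg correction.

    ``groups_by_condition`` maps a condition label (e.g. session) to a pair
    ``(sample_a, sample_b)`` of per-animal values; all conditions form one
    BH family.  Returns a DataFrame with raw and adjusted p-values.
    """
    labels, raw = [], []
    for label, (a, b) in groups_by_condition.items():
        a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"{label}: need at least 2 observations per group")
        raw.append(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        labels.append(label)
    reject, adj, _, _ = multipletests(raw, alpha=alpha, method="fdr_bh")
    return pd.DataFrame(
        {"comparison": labels, "p_raw": raw, "p_adj": adj, "significant": reject}
    )
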