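"""Community structure of the state-transition matrix.

The transition matrix is sparsified by keeping only the strongest
off-diagonal transitions (default: the top 25%), and the resulting
directed weighted graph is partitioned by modularity maximization with
Newman's spectral method — recursive bisection on the leading eigenvector
of the modularity matrix (symmetrized for the eigen step, since transitions
are directed) followed by Kernighan-Lin-style node-moving refinement.

Modularity of a partition C for a directed weighted graph is

    Q = (1/w) * sum_ij [A_ij - s_i^out s_j^in / w] * delta(C_i, C_j)

with w the total edge weight and s^out/s^in the node strengths.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TransitionGraph",
    "CommunityPartition",
    "threshold_transitions",
    "newman_modularity",
    "modularity",
    "label_modules",
]


@dataclass
class TransitionGraph:
    """Thresholded directed transition graph over the K states."""

    weights: np.ndarray  # K x K, zero diagonal, zero where pruned
    kept_fraction: float
    n_kept: int
    n_ties_at_cut: int


@dataclass
class CommunityPartition:
    """Module assignment per state with the achieved modularity Q."""

    module_of: np.ndarray  # length K integer module ids
    Q: float
    module_labels: dict[int, str] | None = None


def threshold_transitions(transition: np.ndarray, kept_fraction: float = 0.25) -> TransitionGraph:
    """Keep the strongest off-diagonal transitions.

    The diagonal (self-persistence) is removed first; the remaining
    K*(K-1) entries are ranked by weight and the top
    ``ceil(kept_fraction * K * (K-1))`` are retained. Entries tied with
    the cutoff value are all retained (a superset is safer than an
    arbitrary drop); ties are logged.
    """
    a = np.asarray(transition, dtype=float)
    k = a.shape[0]
    if a.ndim != 2 or a.shape[1] != k or k < 2:
        raise ValueError("transition must be a square matrix with K >= 2")
    if np.any(a < 0) or np.max(np.abs(a.sum(axis=1) - 1.0)) > 1e-8:
        raise ValueError("transition must be row-stochastic")
    if not (0.0 < kept_fraction <= 1.0):
        raise ValueError(f"kept_fraction must lie in (0, 1], got {kept_fraction}")
    off = a.copy()
    np.fill_diagonal(off, 0.0)
    vals = off[~np.eye(k, dtype=bool)]
    n_target = math.ceil(kept_fraction * k * (k - 1))
    cutoff = np.sort(vals)[::-1][n_target - 1]
    mask = off >= cutoff
    np.fill_diagonal(mask, False)
    n_kept = int(mask.sum())
    n_ties = n_kept - n_target
    if n_ties > 0:
        msg = f"{n_ties} extra edge(s) retained due to ties at the threshold cutoff"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    kept = np.where(mask, off, 0.0)
    return TransitionGraph(weights=kept, kept_fraction=kept_fraction,
                           n_kept=n_kept, n_ties_at_cut=n_ties)


def modularity(weights: np.ndarray, module_of: np.ndarray) -> float:
    """Directed weighted modularity Q of a partition."""
    a = np.asarray(weights, dtype=float)
    w = a.sum()
    if w <= 0:
        raise ValueError("graph has zero total weight")
    s_out = a.sum(axis=1)
    s_in = a.sum(axis=0)
    same = np.asarray(module_of)[:, None] == np.asarray(module_of)[None, :]
    b = a - np.outer(s_out, s_in) / w
    return float(b[same].sum() / w)


def _refine_bisection(bg: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Kernighan-Lin-style single-node flips maximizing s^T Bg s."""
    s = s.copy()
    for _ in range(len(s) * 2):
        gains = -4.0 * s * (bg @ s) + 4.0 * np.diag(bg) * s * s
        i = int(np.argmax(gains))
        if gains[i] <= 1e-14:
            break
        s[i] = -s[i]
    return s


def _split_group(b_sym: np.ndarray, nodes: np.ndarray) -> tuple[np.ndarray, np.ndarray] | None:
    """Attempt a spectral bisection of one group; None if indivisible."""
    bg = b_sym[np.ix_(nodes, nodes)].copy()
    bg[np.diag_indices_from(bg)] -= bg.sum(axis=1)
    vals, vecs = np.linalg.eigh(bg)
    if vals[-1] <= 1e-10:
        return None
    s = np.where(vecs[:, -1] >= 0, 1.0, -1.0)
    s = _refine_bisection(bg, s)
    if np.all(s == s[0]):
        return None
    return nodes[s > 0], nodes[s < 0]


def _kl_partition_refinement(weights: np.ndarray, module_of: np.ndarray) -> np.ndarray:
    """Greedy node moves between existing modules while Q improves."""
    module_of = module_of.copy()
    k = len(module_of)
    improved = True
    q = modularity(weights, module_of)
    while improved:
        improved = False
        for i in range(k):
            best_q, best_m = q, module_of[i]
            for m in np.unique(module_of):
                if m == module_of[i]:
                    continue
                trial = module_of.copy()
                trial[i] = m
                qt = modularity(weights, trial)
                if qt > best_q + 1e-12:
                    best_q, best_m = qt, m
            if best_m != module_of[i]:
                module_of[i] = best_m
                q = best_q
                improved = True
    return module_of


def _merge_refinement(weights: np.ndarray, module_of: np.ndarray) -> np.ndarray:
    """Merge module pairs while Q improves (guards against over-splitting)."""
    module_of = module_of.copy()
    q = modularity(weights, module_of)
    improved = True
    while improved:
        improved = False
        mods = np.unique(module_of)
        for ia in range(len(mods)):
            for ib in range(ia + 1, len(mods)):
                trial = module_of.copy()
                trial[trial == mods[ib]] = mods[ia]
                qt = modularity(weights, trial)
                if qt > q + 1e-12:
                    module_of, q = trial, qt
                    improved = True
                    break
            if improved:
                break
    return module_of


def newman_modularity(graph: TransitionGraph | np.ndarray) -> CommunityPartition:
    """Partition the transition graph by spectral modularity maximization.

    Deterministic given the input: recursive bisection on the leading
    eigenvector of the (symmetrized) modularity matrix, node-flip
    refinement within each bisection, then greedy single-node moves and
    module merges on the full partition.
    """
    a = graph.weights if isinstance(graph, TransitionGraph) else np.asarray(graph, float)
    k = a.shape[0]
    if k < 2:
        raise ValueError("need at least 2 nodes")
    w = a.sum()
    if w <= 0:
        raise ValueError("graph has zero total weight")
    b = a - np.outer(a.sum(axis=1), a.sum(axis=0)) / w
    b_sym = (b + b.T) / 2.0

    module_of = np.zeros(k, dtype=int)
    next_id = 1
    stack = [np.arange(k)]
    while stack:
        nodes = stack.pop()
        if nodes.size < 2:
            continue
        split = _split_group(b_sym, nodes)
        if split is None:
            continue
        left, right = split
        trial = module_of.copy()
        trial[right] = next_id
        if modularity(a, trial) <= modularity(a, module_of) + 1e-12:
            continue
        module_of = trial
        next_id += 1
        stack.append(left)
        stack.append(right)

    module_of = _kl_partition_refinement(a, module_of)
    module_of = _merge_refinement(a, module_of)
    # relabel in order of first appearance
    _, module_of = np.unique(module_of, return_inverse=True)
    order = {}
    for m in module_of:
        order.setdefault(int(m), len(order))
    module_of = np.array([order[int(m)] for m in module_of])
    return CommunityPartition(module_of=module_of, Q=modularity(a, module_of))


def label_modules(partition: CommunityPartition, group_results: pd.DataFrame,
                  metric: str = "fractional_occupancy",
                  covariate_set: str | None = None) -> CommunityPartition:
    """Label each module by the group-difference profile of its states.

    Within a module, states with a significant case-increased metric
    (t > 0) are tallied against states with a significant case-decreased
    metric; whichever direction outnumbers the other (with at least one
    significant state) gives the label ``case-related`` or
    ``control-related``, otherwise ``mixed``.
    """
    res = group_results[group_results["metric"] == metric]
    if covariate_set is None and "covariate_set" in res.columns:
        covariate_set = res["covariate_set"].iloc[0]
    if covariate_set is not None:
        res = res[res["covariate_set"] == covariate_set]
    sig_up = set(res[(res["significant"]) & (res["t"] > 0)]["state"])
    sig_down = set(res[(res["significant"]) & (res["t"] < 0)]["state"])
    labels: dict[int, str] = {}
    for m in np.unique(partition.module_of):
        states = set(np.flatnonzero(partition.module_of == m).tolist())
        up = len(states & sig_up)
        down = len(states & sig_down)
        if up > down and up >= 1:
            labels[int(m)] = "case-related"
        elif down > up and down >= 1:
            labels[int(m)] = "control-related"
        else:
            labels[int(m)] = "mixed"
    return replace(partition, module_labels=labels)


def graph_edge_list(graph: TransitionGraph) -> pd.DataFrame:
    """Kept edges as a tidy (source_state, target_state, weight) table."""
    src, dst = np.nonzero(graph.weights)
    return pd.DataFrame({
        "source_state": src,
        "target_state": dst,
        "weight": graph.weights[src, dst],
    })
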