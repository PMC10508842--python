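"""Correlation pruning, mRMR feature selection, and rank-sum screening."""

from __future__ import annotations

from typing import Dict, List, Sequence

import numpy as np
from scipy import stats


def prune_correlated(X: np.ndarray, names: Sequence[str],
                     threshold: float = 0.90) -> List[str]:
    """Greedy Pearson-correlation pruning in canonical name order.

    Scanning the columns in order, a feature is dropped iff its absolute
    correlation with any already-retained feature reaches ``threshold``.
    Constant features (undefined correlation) are dropped first.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.size == 0:
        raise ValueError("empty feature matrix")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples to compute correlations")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    names = list(names)
    if len(names) != X.shape[1]:
        raise ValueError("names do not match matrix columns")

    sd = X.std(axis=0)
    variable = sd > 0
    Z = np.zeros_like(X)
    Z[:, variable] = (X[:, variable] - X[:, variable].mean(axis=0)) / sd[variable]
    n = X.shape[0]

    retained_idx: List[int] = []
    for j in range(X.shape[1]):
        if not variable[j]:
            continue
        if retained_idx:
            r = Z[:, retained_idx].T @ Z[:, j] / n
            if np.max(np.abs(r)) >= threshold - 1e-12:
                continue
        retained_idx.append(j)
    return [names[j] for j in retained_idx]


def discretize_three_state(X: np.ndarray,
                           mean: np.ndarray | None = None,
                           sd: np.ndarray | None = None) -> np.ndarray:
    """Classic mRMR discretization: 3 states split at mean +/- sd.

    ``mean``/``sd`` default to column statistics of ``X`` itself; pass the
    training-fold statistics when transforming held-out data.
    """
    X = np.asarray(X, dtype=np.float64)
    if mean is None:
        mean = X.mean(axis=0)
    if sd is None:
        sd = X.std(axis=0)
    lo = mean - sd
    hi = mean + sd
    return ((X > lo).astype(np.int64) + (X > hi).astype(np.int64))


def _mi_against(D: np.ndarray, z: np.ndarray, n_states: int = 3) -> np.ndarray:
    """Mutual information (bits) of every column of ``D`` with ``z``.

    ``D`` holds small non-negative integer states; ``z`` is any discrete
    vector (mapped to dense codes internally).
    """
    n, p = D.shape
    _, zi = np.unique(z, return_inverse=True)
    nz_states = zi.max() + 1
    joint = np.zeros((n_states, nz_states, p))
    for s in range(n_states):
        Ds = D == s
        for c in range(nz_states):
            joint[s, c] = (Ds & (zi == c)[:, None]).sum(axis=0)
    pj = joint / n
    px = pj.sum(axis=1, keepdims=True)
    pz = pj.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(pj > 0, pj / np.maximum(px * pz, 1e-300), 1.0)
        terms = np.where(pj > 0, pj * np.log2(ratio), 0.0)
    return terms.sum(axis=(0, 1))


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Mutual information (bits) between two discrete variables."""
    x = np.asarray(x)
    y = np.asarray(y)
    xv, xi = np.unique(x, return_inverse=True)
    yv, yi = np.unique(y, return_inverse=True)
    joint = np.zeros((xv.size, yv.size))
    np.add.at(joint, (xi, yi), 1.0)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float((p[nz] * np.log2(p[nz] / (px @ py)[nz])).sum())


def mrmr_select(X: np.ndarray, y: np.ndarray, names: Sequence[str],
                k: int, redundancy_weight: float = 1.0) -> List[str]:
    """Greedy mRMR (MID criterion) on three-state discretized features.

    First picks the feature with maximal mutual information with the label,
    then repeatedly the maximizer of ``I(f; y) - w * mean_s I(f; s)`` over the
    already-selected set ``s``. Ties break toward canonical (column) order.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("labels must contain both classes")
    names = list(names)
    D = discretize_three_state(X)
    p = D.shape[1]
    k = min(k, p)

    relevance = _mi_against(D, y)
    selected: List[int] = []
    redundancy_sum = np.zeros(p)
    remaining = list(range(p))
    for _ in range(k):
        if selected:
            score = relevance - redundancy_weight * redundancy_sum / len(selected)
        else:
            score = relevance.copy()
        best = max(remaining, key=lambda j: (score[j], -j))
        selected.append(best)
        remaining.remove(best)
        if remaining:
            redundancy_sum += _mi_against(D, D[:, best])
    return [names[j] for j in selected]


def wilcoxon_rank_sum(group_a: Sequence[float],
                      group_b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Uses the exact null distribution when the pooled sample is small
    (n_a + n_b <= 12) and tie-free, and the normal approximation with tie and
    continuity corrections otherwise.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if a.size + b.size <= 12 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.pvalue)


def screen_significant(X: np.ndarray, y: np.ndarray, names: Sequence[str],
                       alpha: float = 0.05) -> Dict[str, float]:
    """Per-feature rank-sum p-values for features separating the two arms.

    Returns the mapping name -> p for features with p < alpha.
    """
    y = np.asarray(y).astype(int)
    out: Dict[str, float] = {}
    for j, name in enumerate(names):
        p = wilcoxon_rank_sum(X[y == 1, j], X[y == 0, j])
        if p < alpha:
            out[name] = p
    return out
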