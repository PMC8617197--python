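"""Independent brute-force oracles used only by the test suite.

Each function re-derives a quantity from first principles (enumeration,
double loops, direct formula evaluation) without touching the package's
implementation paths.
"""
from __future__ import annotations

import itertools
import math
from typing import List, Tuple

import numpy as np


def clr_direct(counts: np.ndarray) -> np.ndarray:
    """Direct CLR: ln((x+1)/geomean_over_cells(x_f+1)), scalar loops."""
    counts = np.asarray(counts, dtype=float)
    out = np.zeros_like(counts)
    n_cells = counts.shape[1]
    for f in range(counts.shape[0]):
        gm = math.exp(sum(math.log(counts[f, c] + 1) for c in range(n_cells)) / n_cells)
        for c in range(n_cells):
            out[f, c] = math.log((counts[f, c] + 1) / gm)
    return out


def ranksum_exact_p(x, y) -> float:
    """Two-sided exact rank-sum p by full enumeration over C(n+m, n) splits
    (tie-free data only): p = min(1, 2*min(P(W<=w), P(W>=w)))."""
    pooled = sorted(list(x) + list(y))
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    n = len(x)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    w_obs = sum(ranks[v] for v in x)
    ws = [sum(c) for c in itertools.combinations(range(1, len(pooled) + 1), n)]
    total = len(ws)
    p_le = sum(1 for w in ws if w <= w_obs) / total
    p_ge = sum(1 for w in ws if w >= w_obs) / total
    return min(1.0, 2 * min(p_le, p_ge))


def morans_i_direct(weights: np.ndarray, x: np.ndarray) -> float:
    """Moran's I by explicit double sum."""
    w = np.asarray(weights, dtype=float)
    x = np.asarray(x, dtype=float)
    n = len(x)
    xbar = x.mean()
    num = 0.0
    W = 0.0
    for i in range(n):
        for j in range(n):
            num += w[i, j] * (x[i] - xbar) * (x[j] - xbar)
            W += w[i, j]
    den = sum((xi - xbar) ** 2 for xi in x)
    return (n / W) * num / den


def log2_cpm_direct(counts: np.ndarray) -> np.ndarray:
    counts = np.asarray(counts, dtype=float)
    out = np.zeros_like(counts)
    for i in range(counts.shape[0]):
        total = counts[i].sum()
        for j in range(counts.shape[1]):
            out[i, j] = math.log2(1 + counts[i, j] / total * 1e6)
    return out


def complete_linkage_direct(data: np.ndarray) -> List[Tuple[frozenset, frozenset, float]]:
    """O(n^3) agglomeration with complete linkage / Euclidean distance.

    Returns the merge list as (cluster_a, cluster_b, height) with clusters
    as frozensets of original indices; ties broken by smallest members.
    """
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    dist = np.sqrt(((data[:, None, :] - data[None, :, :]) ** 2).sum(-1))
    clusters = [frozenset([i]) for i in range(n)]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = max(dist[i, j] for i in clusters[a] for j in clusters[b])
            key = (d, tuple(sorted(clusters[a] | clusters[b])))
            if best is None or key < best[0]:
                best = (key, a, b)
        (d, _), a, b = best
        merges.append((clusters[a], clusters[b], d))
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return merges


def knn_sets_direct(points: np.ndarray, k: int) -> List[set]:
    """Per point, the k nearest others by an all-pairs scan (ties by index)."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    out = []
    for i in range(n):
        d = [(np.linalg.norm(pts[i] - pts[j]), j) for j in range(n) if j != i]
        d.sort()
        out.append({j for _, j in d[:k]})
    return out


def bh_qvalues_direct(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up by hand."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        val = min(prev, p[idx] * m / rank)
        q[idx] = val
        prev = val
    return q
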