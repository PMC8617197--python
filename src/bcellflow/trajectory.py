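"""Trajectory analysis: cell-cycle regression, graph-geodesic pseudotime,
Moran's-I selection of trajectory-variable genes, and gene modules.

Pseudotime is the shortest-path distance along the cell kNN graph (Euclidean
edge lengths) from the medoid of a user-designated root cluster — a
deterministic geodesic ordering standing in for principal-graph trajectory
learning. Genes varying smoothly over the graph are selected by Moran's I
with a one-sided normal-theory p-value and Benjamini–Hochberg correction,
then grouped into modules by community detection over their cluster-averaged
profiles.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Set, Tuple

import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from scipy.sparse.csgraph import dijkstra
from statsmodels.stats.multitest import multipletests

from .preprocess import CellGraph, _igraph_from


@dataclass
class PseudotimeResult:
    pseudotime: np.ndarray
    root_cell: str
    unreachable: Set[str] = field(default_factory=set)


@dataclass
class GeneModuleSet:
    modules: Dict[int, List[str]]
    gene_stats: pd.DataFrame  # gene, morans_i, p, q
    module_cluster_matrix: pd.DataFrame  # modules x clusters


def regress_cycle(matrix: np.ndarray, s_score: np.ndarray, g2m_score: np.ndarray) -> np.ndarray:
    """Per-gene OLS residuals against intercept + S score + G2M score.

    Collinear scores (|r| ~ 1) drop the G2M covariate with a warning.
    """
    s = np.asarray(s_score, dtype=float)
    g = np.asarray(g2m_score, dtype=float)
    if not (np.all(np.isfinite(s)) and np.all(np.isfinite(g))):
        raise ValueError("non-finite cell-cycle scores")
    cols = [np.ones_like(s), s, g]
    sc, gc = s - s.mean(), g - g.mean()
    denom = np.linalg.norm(sc) * np.linalg.norm(gc)
    if denom == 0 or abs(sc @ gc) / denom > 1 - 1e-12:
        warnings.warn("S and G2M scores are collinear; dropping the G2M covariate")
        cols = [np.ones_like(s), s] if np.linalg.norm(sc) > 0 else [np.ones_like(s)]
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, np.asarray(matrix, dtype=float).T, rcond=None)
    return matrix - (X @ beta).T


def geodesic_pseudotime(
    graph: CellGraph,
    labels: Sequence,
    root_cluster,
    barcodes: Sequence[str],
    embedding: np.ndarray,
) -> PseudotimeResult:
    """Shortest-path pseudotime from the root cluster's medoid cell."""
    labels = np.asarray(labels)
    root_idx = np.flatnonzero(labels == root_cluster)
    if root_idx.size == 0:
        raise ValueError(f"root cluster {root_cluster!r} has no cells")
    pts = np.asarray(embedding)[root_idx]
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1) ** 0.5
    medoid = int(root_idx[np.argmin(d2.sum(axis=1))])
    dist = dijkstra(graph.distances, directed=False, indices=medoid)
    unreachable = {barcodes[i] for i in np.flatnonzero(~np.isfinite(dist))}
    return PseudotimeResult(pseudotime=dist, root_cell=barcodes[medoid], unreachable=unreachable)


def _moran_constants(w: sp.spmatrix) -> Tuple[float, float, float]:
    w = sp.csr_matrix(w)
    W = w.sum()
    wt = w + w.T
    s1 = 0.5 * (wt.multiply(wt)).sum()
    row = np.asarray(w.sum(axis=1)).ravel()
    col = np.asarray(w.sum(axis=0)).ravel()
    s2 = ((row + col) ** 2).sum()
    return float(W), float(s1), float(s2)


def _moran_stats(I: np.ndarray, n: int, W: float, s1: float, s2: float) -> Tuple[np.ndarray, np.ndarray]:
    """z and one-sided (greater) p under the normality assumption."""
    e_i = -1.0 / (n - 1)
    var = (n * n * s1 - n * s2 + 3 * W * W) / (W * W * (n * n - 1)) - e_i ** 2
    if var <= 0:
        # degenerate weights (e.g. a complete graph): I is constant at E[I]
        return np.zeros_like(I), np.full_like(I, 0.5)
    z = (I - e_i) / np.sqrt(var)
    p = scipy.stats.norm.sf(z)
    return z, p


def morans_i(graph: CellGraph | sp.spmatrix, x: np.ndarray) -> Tuple[float, float, float]:
    """Moran's I over the graph's connectivity weights, with analytic z and
    one-sided p for positive autocorrelation."""
    w = graph.connectivity if isinstance(graph, CellGraph) else sp.csr_matrix(graph)
    x = np.asarray(x, dtype=float)
    n = len(x)
    if w.nnz == 0:
        raise ValueError("graph has no edges")
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0:
        raise ValueError("constant x; Moran's I undefined")
    W, s1, s2 = _moran_constants(w)
    I = (n / W) * float(xc @ (w @ xc)) / denom
    z, p = _moran_stats(np.asarray([I]), n, W, s1, s2)
    return I, float(z[0]), float(p[0])


def autocorrelated_genes(
    graph: CellGraph,
    norm: np.ndarray,
    gene_names: Sequence[str],
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-gene Moran's I with BH q-values; returns the tested genes with a
    ``significant`` flag (q < q_threshold). Constant genes are skipped and
    reported with NaN statistics."""
    w = sp.csr_matrix(graph.connectivity)
    X = np.asarray(norm, dtype=float)
    n = X.shape[1]
    xc = X - X.mean(axis=1, keepdims=True)
    denom = (xc * xc).sum(axis=1)
    tested = denom > 0
    W, s1, s2 = _moran_constants(w)
    num = (xc[tested] * (w @ xc[tested].T).T).sum(axis=1)
    I = (n / W) * num / denom[tested]
    z, p = _moran_stats(I, n, W, s1, s2)
    q = multipletests(p, method="fdr_bh")[1]
    df = pd.DataFrame({"gene": list(gene_names), "morans_i": np.nan, "z": np.nan, "p": np.nan, "q": np.nan})
    df.loc[tested, ["morans_i", "z", "p", "q"]] = np.column_stack([I, z, p, q])
    df["tested"] = tested
    df["significant"] = df["q"] < q_threshold
    return df


def gene_modules(
    norm: np.ndarray,
    gene_names: Sequence[str],
    genes: Sequence[str],
    labels: Sequence,
    knn_k: int = 10,
    resolution: float = 1.0,
    seed: int = 0,
) -> GeneModuleSet:
    """Group genes into modules by their cluster-averaged profiles.

    Each gene's expression is averaged per cell cluster and z-scored; genes
    are joined to their ``knn_k`` nearest neighbours under correlation
    distance and partitioned by Leiden community detection. The module×cluster
    matrix holds the mean of member genes' z-scored aggregates.
    """
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError("need at least two genes to build modules")
    name_index = {g: i for i, g in enumerate(gene_names)}
    missing = [g for g in genes if g not in name_index]
    if missing:
        raise ValueError(f"genes absent from the matrix: {missing[:10]}")
    labels = np.asarray(labels)
    clusters = sorted(pd.unique(labels).tolist())
    prof = np.stack(
        [np.asarray(norm)[[name_index[g] for g in genes]][:, labels == cl].mean(axis=1) for cl in clusters],
        axis=1,
    )  # genes x clusters
    mu = prof.mean(axis=1, keepdims=True)
    sd = prof.std(axis=1, ddof=1, keepdims=True)
    zprof = np.divide(prof - mu, sd, out=np.zeros_like(prof), where=sd > 0)

    k = min(knn_k, len(genes) - 1)
    if k < knn_k:
        warnings.warn(f"fewer genes than knn_k+1; reducing k to {k}")
    # correlation distance between z-scored profiles
    zn = zprof - zprof.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(zn, axis=1)
    norms[norms == 0] = 1.0
    corr = (zn / norms[:, None]) @ (zn / norms[:, None]).T
    dist = 1 - corr
    np.fill_diagonal(dist, np.inf)
    rows, cols = [], []
    for i in range(len(genes)):
        nn = np.argsort(dist[i], kind="stable")[:k]
        rows.extend([i] * k)
        cols.extend(nn.tolist())
    conn = sp.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(len(genes), len(genes)))
    conn = ((conn + conn.T) > 0).astype(float)
    g = _igraph_from(sp.csr_matrix(conn))
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    membership = np.asarray(part.membership)
    modules: Dict[int, List[str]] = {}
    for m in sorted(set(membership.tolist())):
        modules[m] = [genes[i] for i in np.flatnonzero(membership == m)]
    mat = pd.DataFrame(
        np.stack([zprof[membership == m].mean(axis=0) for m in modules]),
        index=[f"module_{m}" for m in modules],
        columns=[str(c) for c in clusters],
    )
    stats = pd.DataFrame({"gene": genes, "module": membership})
    return GeneModuleSet(modules=modules, gene_stats=stats, module_cluster_matrix=mat)
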