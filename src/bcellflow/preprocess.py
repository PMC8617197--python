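"""Cell/gene filtering, normalisation, embedding, clustering, and the
DE-count-guided cluster-merging rule.

Filtering keeps cells detecting more than ``min_genes`` genes, then genes
detected in more than ``min_cells`` cells, then removes the cells whose
mitochondrial fraction falls in the top ``mito_top_frac`` quantile. Two
normalisations are provided: median-scaled log counts and a Pearson-residual
variance stabilisation with fixed dispersion (optionally followed by
regressing out per-cell covariates such as the mitochondrial percentage).
Clusters come from Leiden community detection on a kNN graph of the top
principal components; pairs of clusters separated by fewer than ``min_de``
significant genes are merged iteratively, fewest-DE pair first.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, NamedTuple, Optional, Tuple

import igraph
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .markers import pairwise_de_genes
from .simulate import CountsBundle


@dataclass
class FilterReport:
    n_cells_in: int
    n_cells_out: int
    n_genes_in: int
    n_genes_out: int
    removed_low_genes: List[str]
    removed_for_mito: List[str]
    min_genes: int
    min_cells: int
    mito_top_frac: float
    mito_cutoff: float


@dataclass
class ClusterLabels:
    labels: np.ndarray
    merge_log: List[Tuple[Tuple[int, int], int]] = field(default_factory=list)


class CellGraph(NamedTuple):
    """Undirected kNN graph: 0/1 connectivity plus Euclidean edge lengths."""

    connectivity: sp.csr_matrix
    distances: sp.csr_matrix


def filter_cells_genes(
    bundle: CountsBundle,
    min_genes: int = 300,
    min_cells: int = 3,
    mito_top_frac: float = 0.005,
) -> Tuple[CountsBundle, FilterReport]:
    """Apply the fixed-order cell/gene filters.

    Order: cells detecting > min_genes genes; genes detected in > min_cells
    cells; cells whose mitochondrial fraction lies in the top mito_top_frac
    quantile (ties at the cutoff all removed).
    """
    rna = sp.csr_matrix(bundle.rna)
    n_cells_in, n_genes_in = rna.shape[1], rna.shape[0]

    genes_per_cell = (rna > 0).sum(axis=0).A1
    keep_cells = genes_per_cell > min_genes
    low = [bc for bc, k in zip(bundle.cell_barcodes, keep_cells) if not k]
    out = bundle.subset_cells(keep_cells)

    cells_per_gene = (out.rna > 0).sum(axis=1).A1
    out = out.subset_genes(cells_per_gene > min_cells)

    mito_cutoff = np.inf
    removed_mito: List[str] = []
    if mito_top_frac > 0 and out.mito_mask.any():
        totals = np.asarray(out.rna.sum(axis=0)).ravel()
        mito = np.asarray(out.rna[out.mito_mask].sum(axis=0)).ravel()
        frac = np.divide(mito, totals, out=np.zeros_like(mito, dtype=float), where=totals > 0)
        mito_cutoff = float(np.quantile(frac, 1 - mito_top_frac))
        keep = frac < mito_cutoff
        removed_mito = [bc for bc, k in zip(out.cell_barcodes, keep) if not k]
        out = out.subset_cells(keep)

    if out.n_cells == 0:
        raise ValueError("filtering removed all cells")
    report = FilterReport(
        n_cells_in=n_cells_in,
        n_cells_out=out.n_cells,
        n_genes_in=n_genes_in,
        n_genes_out=out.rna.shape[0],
        removed_low_genes=low,
        removed_for_mito=removed_mito,
        min_genes=min_genes,
        min_cells=min_cells,
        mito_top_frac=mito_top_frac,
        mito_cutoff=mito_cutoff,
    )
    return out, report


def _ols_residualise(matrix: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Replace each gene row by its OLS residuals on covariates + intercept."""
    X = np.column_stack([np.ones(matrix.shape[1]), np.atleast_2d(covariates).reshape(matrix.shape[1], -1)])
    beta, *_ = np.linalg.lstsq(X, matrix.T, rcond=None)
    return matrix - (X @ beta).T


def normalize(
    counts: sp.spmatrix | np.ndarray,
    method: str = "pearson_residual",
    covariates: Optional[np.ndarray] = None,
    theta: float = 100.0,
) -> np.ndarray:
    """Normalise a genes×cells count matrix.

    ``log_cpm_median``: ln(1 + count / cell_total × median cell total).
    ``pearson_residual``: (x − μ)/sqrt(μ + μ²/θ) with μ = gene share × cell
    depth share of the grand total and fixed θ, clipped at ±sqrt(n_cells);
    all-zero gene rows get residual 0 by convention. This variance-stabilised
    residual plays the role the regularised-NB transforms play in standard
    single-cell pipelines. If ``covariates`` are given, each gene row is then
    replaced by its least-squares residuals on the covariates plus intercept.
    """
    counts = np.asarray(counts.todense() if sp.issparse(counts) else counts, dtype=float)
    cell_totals = counts.sum(axis=0)
    if np.any(cell_totals == 0):
        raise ValueError("zero-total cell encountered; filter cells first")
    if method == "log_cpm_median":
        med = np.median(cell_totals)
        out = np.log1p(counts / cell_totals[None, :] * med)
    elif method == "pearson_residual":
        gene_totals = counts.sum(axis=1)
        grand = counts.sum()
        mu = np.outer(gene_totals, cell_totals) / grand
        denom = np.sqrt(mu + mu ** 2 / theta)
        out = np.divide(counts - mu, denom, out=np.zeros_like(counts), where=denom > 0)
        clip = np.sqrt(counts.shape[1])
        out = np.clip(out, -clip, clip)
    else:
        raise ValueError(f"unknown normalisation method: {method}")
    if covariates is not None:
        out = _ols_residualise(out, np.asarray(covariates, dtype=float))
    return out


def run_pca(
    norm: np.ndarray,
    n_components: int = 30,
    center: bool = True,
    scale: bool = True,
) -> np.ndarray:
    """PCA of cells over genes; returns cells×components scores.

    Gene rows are centred (and unit-scaled unless a gene is constant); each
    component's sign is fixed so that the largest-|loading| entry is positive.
    """
    norm = np.asarray(norm, dtype=float)
    n_genes, n_cells = norm.shape
    if n_components > min(n_genes, n_cells):
        raise ValueError(f"n_components={n_components} exceeds min(n_genes, n_cells)")
    X = norm.copy()
    if center:
        X -= X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=0)
    if np.all(sd == 0):
        raise ValueError("constant matrix; PCA undefined")
    if scale:
        X /= np.where(sd > 0, sd, 1.0)[:, None]
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X.T)
    loadings = pca.components_  # components x genes
    signs = np.sign(loadings[np.arange(n_components), np.abs(loadings).argmax(axis=1)])
    signs[signs == 0] = 1.0
    return scores * signs[None, :]


def knn_graph(embedding: np.ndarray, k: int = 20) -> CellGraph:
    """k nearest Euclidean neighbours per cell, symmetrised by union.

    Connectivity weights are 1; Euclidean distances are kept alongside.
    Ties and duplicate points are broken by index.
    """
    embedding = np.asarray(embedding, dtype=float)
    n = embedding.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be < n_cells={n}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding)
    dist, idx = nn.kneighbors(embedding)
    rows, cols, vals = [], [], []
    for i in range(n):
        for d, j in zip(dist[i], idx[i]):
            if j == i:
                continue
            rows.append(i)
            cols.append(j)
            vals.append(d)
    d_mat = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    d_sym = d_mat.maximum(d_mat.T)  # union of edges; distances are symmetric anyway
    # connectivity from edge presence, not distance value, so duplicate points
    # (zero-length edges) still connect
    ones = d_mat.copy()
    ones.data = np.ones_like(ones.data)
    conn = ((ones + ones.T) > 0).astype(float)
    return CellGraph(connectivity=sp.csr_matrix(conn), distances=sp.csr_matrix(d_sym))


def _igraph_from(conn: sp.csr_matrix) -> igraph.Graph:
    coo = sp.triu(conn, k=1).tocoo()
    g = igraph.Graph(n=conn.shape[0], edges=list(zip(coo.row.tolist(), coo.col.tolist())))
    return g


def community_cluster(graph: CellGraph, resolution: float = 0.4, seed: int = 0) -> ClusterLabels:
    """Leiden (RB-configuration) community detection on the connectivity
    graph; labels are relabelled by decreasing cluster size."""
    if graph.connectivity.shape[0] == 0:
        raise ValueError("empty graph")
    g = _igraph_from(graph.connectivity)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    raw = np.asarray(part.membership)
    order = pd.Series(raw).value_counts(sort=True).index.tolist()
    remap = {old: new for new, old in enumerate(order)}
    return ClusterLabels(labels=np.asarray([remap[r] for r in raw]))


def merge_by_de(
    norm: np.ndarray,
    labels: ClusterLabels | np.ndarray,
    min_de: int = 5,
    lfc_threshold: float = 0.25,
    alpha: float = 0.01,
) -> ClusterLabels:
    """Iteratively merge cluster pairs separated by fewer than ``min_de``
    significant genes (rank-sum, Bonferroni over genes tested per pair,
    |log2FC| >= lfc_threshold, adjusted p <= alpha).

    Each iteration merges the single pair with the fewest significant genes
    (ties: smaller combined cell count, then lexicographic labels), relabels,
    and restarts; terminates when every pair has at least ``min_de``.
    """
    lab = np.asarray(labels.labels if isinstance(labels, ClusterLabels) else labels).copy()
    merge_log: List[Tuple[Tuple[int, int], int]] = []
    if min_de <= 0:
        return ClusterLabels(labels=lab, merge_log=merge_log)
    # cache pair DE counts; only pairs touching a merged cluster change
    cache: Dict[Tuple, int] = {}
    while True:
        clusters = sorted(pd.unique(lab).tolist())
        if len(clusters) < 2:
            break
        best = None  # (n_de, combined_size, (a, b))
        for i, a in enumerate(clusters):
            for b in clusters[i + 1:]:
                if (a, b) not in cache:
                    cache[(a, b)] = len(
                        pairwise_de_genes(norm, lab, a, b, lfc_threshold=lfc_threshold, alpha=alpha)
                    )
                n_de = cache[(a, b)]
                if n_de < min_de:
                    size = int(np.sum(lab == a) + np.sum(lab == b))
                    key = (n_de, size, (a, b))
                    if best is None or key < best:
                        best = key
        if best is None:
            break
        n_de, _, (a, b) = best
        lab[lab == b] = a
        merge_log.append(((a, b), n_de))
        cache = {pair: v for pair, v in cache.items() if a not in pair and b not in pair}
    # relabel contiguously by decreasing size
    order = pd.Series(lab).value_counts(sort=True).index.tolist()
    remap = {old: new for new, old in enumerate(order)}
    return ClusterLabels(labels=np.asarray([remap[v] for v in lab]), merge_log=merge_log)
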