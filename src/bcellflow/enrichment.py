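"""Signature enrichment of bulk subtype transcriptomes with Monte-Carlo
significance of the hierarchical clustering.

Replicates are summed per subtype, converted to log2 counts-per-million,
z-scored per gene across subtypes, and each developmental-cluster signature
is scored as the mean z of its genes in each subtype. Both axes of the
resulting grid are clustered (Euclidean distance, complete linkage) and each
dendrogram node is tested against a single-Gaussian null: null data sets of
the node's shape are drawn with the node's covariance eigenvalues (floored
at the median per-feature variance), clustered identically, and compared on
the scale-free statistic root-linkage-height / mean-pairwise-distance.
Genuine two-cluster structure pulls that ratio down toward 2 — about half
of all leaf pairs sit near the maximum distance — whereas a single
(possibly elongated) Gaussian puts only its extreme pair there, so small
observed ratios are the rejection direction. Family-wise error is
controlled by testing each node at alpha*(n_node-1)/(N-1) and descending
only into the children of rejected nodes.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist

from .markers import SignatureSet


@dataclass
class Dendrogram:
    linkage: np.ndarray  # scipy linkage matrix
    leaf_labels: List[str]


@dataclass
class EnrichmentGrid:
    scores: pd.DataFrame  # signatures x subtypes
    genes_used: Dict[str, int]
    row_dendrogram: Optional[Dendrogram] = None
    col_dendrogram: Optional[Dendrogram] = None


@dataclass
class SHCReport:
    table: pd.DataFrame  # node, n_leaves, leaves, statistic, p, threshold, decision
    alpha: float
    n_sim: int
    seed: int


def aggregate_replicates(counts: pd.DataFrame, sample_to_subtype: Mapping[str, str] | pd.Series) -> pd.DataFrame:
    """Sum a sample×gene count table over biological replicates per subtype."""
    mapping = pd.Series(dict(sample_to_subtype)) if not isinstance(sample_to_subtype, pd.Series) else sample_to_subtype
    unmapped = [s for s in counts.index if s not in mapping.index]
    if unmapped:
        raise ValueError(f"unmapped samples: {unmapped}")
    return counts.groupby(mapping.loc[counts.index].values).sum().rename_axis("subtype")


def log2_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """log2(1 + count / subtype_total × 1e6) per subtype row."""
    totals = counts.sum(axis=1)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"zero-total subtypes: {bad}")
    return np.log2(1 + counts.div(totals, axis=0) * 1e6)


def gene_zscores(log2cpm: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z across subtypes (sample SD, n−1); zero-variance genes get
    an all-zero column with a warning."""
    if log2cpm.shape[0] < 2:
        raise ValueError("at least two subtypes required for z-scores")
    mu = log2cpm.mean(axis=0)
    sd = log2cpm.std(axis=0, ddof=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} zero-variance genes set to zero z-scores")
    z = (log2cpm - mu).div(sd.where(~degenerate, 1.0), axis=1)
    z.loc[:, degenerate] = 0.0
    return z


def signature_scores(
    z: pd.DataFrame,
    signatures: SignatureSet | Mapping[str, Sequence[str]],
    min_genes: int = 3,
) -> EnrichmentGrid:
    """Average z over each signature's present genes, per subtype.

    Signatures with fewer than ``min_genes`` genes present in the bulk gene
    universe are dropped with a warning; an error is raised if none survive.
    """
    sets = dict(signatures.sets) if isinstance(signatures, SignatureSet) else dict(signatures)
    if not sets:
        raise ValueError("empty signature set")
    rows = {}
    genes_used = {}
    universe = set(z.columns)
    for name, genes in sets.items():
        present = [g for g in dict.fromkeys(genes) if g in universe]
        if len(present) < min_genes:
            warnings.warn(f"signature '{name}' has {len(present)} genes in the bulk universe; dropped")
            continue
        rows[name] = z[present].mean(axis=1)
        genes_used[name] = len(present)
    if not rows:
        raise ValueError("all signatures dropped (too few genes present)")
    scores = pd.DataFrame(rows).T  # signatures x subtypes
    scores = scores[z.index]  # fix column order to subtype order
    return EnrichmentGrid(scores=scores, genes_used=genes_used)


def hclust(matrix: pd.DataFrame | np.ndarray, axis: int = 0, metric: str = "euclidean", linkage: str = "complete") -> Dendrogram:
    """Agglomerative clustering of the rows (axis=0) or columns (axis=1)."""
    if isinstance(matrix, pd.DataFrame):
        labels = list(matrix.index if axis == 0 else matrix.columns)
        data = matrix.values
    else:
        data = np.asarray(matrix)
        labels = [str(i) for i in range(data.shape[0] if axis == 0 else data.shape[1])]
    if axis == 1:
        data = data.T
    if data.shape[0] < 2:
        raise ValueError("at least two items required")
    if not np.all(np.isfinite(data)):
        raise ValueError("non-finite values in the matrix")
    Z = sch.linkage(data, method=linkage, metric=metric)
    return Dendrogram(linkage=Z, leaf_labels=labels)


def _root_statistic(data: np.ndarray, linkage_method: str = "complete") -> float:
    """Scale-free statistic: root linkage height / mean pairwise distance."""
    d = pdist(data)
    mean_d = d.mean()
    if mean_d == 0:
        return np.nan
    Z = sch.linkage(data, method=linkage_method)
    return float(Z[-1, 2] / mean_d)


def _node_leaves(Z: np.ndarray, node: int, n: int) -> List[int]:
    if node < n:
        return [node]
    left, right = int(Z[node - n, 0]), int(Z[node - n, 1])
    return _node_leaves(Z, left, n) + _node_leaves(Z, right, n)


def shc_test(
    matrix: pd.DataFrame | np.ndarray,
    axis: int = 0,
    alpha: float = 0.05,
    n_sim: int = 100,
    min_n: int = 3,
    seed: int = 0,
    linkage: str = "complete",
) -> SHCReport:
    """Monte-Carlo significance of each dendrogram node, top-down with FWER
    control.

    Nodes with at least 2*min_n leaves are testable; the root is tested at
    alpha*(n_root−1)/(N−1) = alpha, and each child of a rejected node at
    alpha*(n_child−1)/(N−1). The Monte-Carlo p is
    (1 + #{null statistic <= observed}) / (n_sim + 1); see the module
    docstring for the direction argument.
    """
    if n_sim < 20:
        raise ValueError("n_sim < 20 gives too coarse a p-value resolution")
    if isinstance(matrix, pd.DataFrame):
        data = matrix.values
        labels = list(matrix.index if axis == 0 else matrix.columns)
    else:
        data = np.asarray(matrix, dtype=float)
        labels = [str(i) for i in range(data.shape[0] if axis == 0 else data.shape[1])]
    if axis == 1:
        data = data.T
    n_items = data.shape[0]
    if n_items < 2 * min_n:
        raise ValueError(f"need at least {2 * min_n} items (got {n_items})")
    Z = sch.linkage(data, method=linkage)
    rng = np.random.default_rng(seed)

    rows = []

    def leaves_of(node_id: int) -> List[int]:
        return _node_leaves(Z, node_id, n_items)

    def test_node(node_id: int, height: float) -> Tuple[float, float]:
        idx = leaves_of(node_id)
        sub = data[idx]
        d = pdist(sub)
        obs = height / d.mean() if d.mean() > 0 else np.nan
        if not np.isfinite(obs):
            return np.nan, 1.0  # degenerate node: zero variance
        centered = sub - sub.mean(axis=0)
        cov = centered.T @ centered / (len(idx) - 1)
        ev = np.linalg.eigvalsh(cov)
        floor = float(np.median(centered.var(axis=0, ddof=1)))
        ev = np.maximum(ev, max(floor, 1e-12))
        scale = np.sqrt(ev)
        count = 0
        for _ in range(n_sim):
            null = rng.standard_normal((len(idx), data.shape[1])) * scale
            stat = _root_statistic(null, linkage)
            if np.isfinite(stat) and stat <= obs:
                count += 1
        return obs, (1 + count) / (n_sim + 1)

    # top-down: (node_id in scipy's 0..2n-2 numbering)
    root = 2 * n_items - 2
    stack = [root]
    while stack:
        node = stack.pop()
        idx = leaves_of(node)
        n_d = len(idx)
        if n_d < 2 * min_n:
            rows.append(
                {
                    "node": node,
                    "n_leaves": n_d,
                    "leaves": ";".join(labels[i] for i in idx),
                    "statistic": np.nan,
                    "p": np.nan,
                    "threshold": np.nan,
                    "decision": "too small",
                }
            )
            continue
        height = float(Z[node - n_items, 2])
        obs, p = test_node(node, height)
        threshold = alpha * (n_d - 1) / (n_items - 1)
        rejected = p <= threshold
        rows.append(
            {
                "node": node,
                "n_leaves": n_d,
                "leaves": ";".join(labels[i] for i in idx),
                "statistic": obs,
                "p": p,
                "threshold": threshold,
                "decision": "rejected" if rejected else "not rejected",
            }
        )
        if rejected:
            for child in (int(Z[node - n_items, 0]), int(Z[node - n_items, 1])):
                if child >= n_items:
                    stack.append(child)
    table = pd.DataFrame(rows).sort_values("n_leaves", ascending=False).reset_index(drop=True)
    return SHCReport(table=table, alpha=alpha, n_sim=n_sim, seed=seed)


def build_enrichment_grid(
    bulk_counts: pd.DataFrame,
    sample_to_subtype: Mapping[str, str] | pd.Series,
    signatures: SignatureSet | Mapping[str, Sequence[str]],
    min_genes: int = 3,
    alpha: float = 0.05,
    n_sim: int = 100,
    min_n: int = 3,
    seed: int = 0,
) -> Tuple[EnrichmentGrid, SHCReport, SHCReport]:
    """Chain the full enrichment analysis: aggregate → log2cpm → z-scores →
    signature scores → hierarchical clustering and Monte-Carlo tests on both
    axes. Returns (grid, row report, column report)."""
    agg = aggregate_replicates(bulk_counts, sample_to_subtype)
    z = gene_zscores(log2_cpm(agg))
    grid = signature_scores(z, signatures, min_genes=min_genes)
    grid.row_dendrogram = hclust(grid.scores, axis=0)
    grid.col_dendrogram = hclust(grid.scores, axis=1)
    row_report = shc_test(grid.scores, axis=0, alpha=alpha, n_sim=n_sim, min_n=min_n, seed=seed)
    col_report = shc_test(grid.scores, axis=1, alpha=alpha, n_sim=n_sim, min_n=min_n, seed=seed + 1)
    return grid, row_report, col_report
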