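"""Marker-gene discovery, consensus signatures, and homolog mapping.

Two independent rankings feed the consensus: a one-vs-rest Wilcoxon
rank-sum table with Bonferroni correction and log2-fold-change filtering,
and a specificity score (fraction of in-cluster cells expressing × the
cluster's share of the gene's mean expression). Cluster signatures are the
per-correspondence-group intersection of the two rankings, then translated
through a strictly one-to-one homolog map.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.stats

LOG2FC_EPS = 1e-9


@dataclass
class SignatureSet:
    """Named gene sets with a provenance tag."""

    sets: Dict[str, List[str]]
    provenance: str = ""
    flagged_empty: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sets = {k: list(dict.fromkeys(v)) for k, v in self.sets.items()}

    def __iter__(self):
        return iter(self.sets.items())

    def __getitem__(self, key: str) -> List[str]:
        return self.sets[key]


def wilcoxon_de(x: Sequence[float], y: Sequence[float], exact_max_n: int = 8) -> Tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Exact p by enumeration when both samples have at most ``exact_max_n``
    observations and there are no ties; otherwise the normal approximation
    with tie and continuity corrections. Returns (rank-sum statistic of x,
    two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(x) <= exact_max_n and len(y) <= exact_max_n and not has_ties) else "asymptotic"
    res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    ranks = scipy.stats.rankdata(pooled)
    w = float(ranks[: len(x)].sum())
    return w, float(res.pvalue)


def _ranksum_pvalues(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorised two-sided rank-sum p per column (normal approximation with
    tie and continuity corrections), for (n1, G) vs (n2, G) arrays."""
    res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic", axis=0)
    return np.asarray(res.pvalue)


def log2_fold_change(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """log2 fold change for ln(1+·)-normalised data, per gene column."""
    mx = np.expm1(np.asarray(x, dtype=float)).mean(axis=0)
    my = np.expm1(np.asarray(y, dtype=float)).mean(axis=0)
    return np.log2((mx + LOG2FC_EPS) / (my + LOG2FC_EPS))


def pairwise_de_genes(
    norm: np.ndarray,
    labels: np.ndarray,
    a,
    b,
    lfc_threshold: float = 0.25,
    alpha: float = 0.01,
) -> np.ndarray:
    """Indices of genes significantly DE between clusters a and b.

    Genes detected in neither group are not tested; Bonferroni correction
    spans the genes tested in this comparison. A gene passes when
    |log2FC| >= lfc_threshold and adjusted p <= alpha.
    """
    labels = np.asarray(labels)
    xa = norm[:, labels == a].T  # cells x genes
    xb = norm[:, labels == b].T
    if xa.shape[0] == 0 or xb.shape[0] == 0:
        raise ValueError(f"empty cluster in comparison {a} vs {b}")
    tested = np.flatnonzero((xa != 0).any(axis=0) | (xb != 0).any(axis=0))
    if tested.size == 0:
        return tested
    pvals = _ranksum_pvalues(xa[:, tested], xb[:, tested])
    adj = np.minimum(pvals * tested.size, 1.0)
    lfc = log2_fold_change(xa[:, tested], xb[:, tested])
    return tested[(np.abs(lfc) >= lfc_threshold) & (adj <= alpha)]


def rank_markers_ovr(
    norm: np.ndarray,
    gene_names: Sequence[str],
    labels: Sequence,
    lfc_threshold: float = 0.25,
    alpha: float = 0.01,
    positive_only: bool = True,
) -> pd.DataFrame:
    """One-vs-rest marker table over all clusters.

    Each gene is tested cluster-vs-rest with the rank-sum test; genes kept
    when |log2FC| >= lfc_threshold and Bonferroni-adjusted p <= alpha
    (negative-fold-change records dropped when ``positive_only``). Records
    are ranked within cluster by adjusted p, then |log2FC|.
    """
    labels = np.asarray(labels)
    clusters = sorted(pd.unique(labels).tolist(), key=str)
    if len(clusters) < 2:
        raise ValueError("at least two clusters required")
    gene_names = list(gene_names)
    records = []
    for cl in clusters:
        in_mask = labels == cl
        xin = norm[:, in_mask].T
        xout = norm[:, ~in_mask].T
        tested = np.flatnonzero((xin != 0).any(axis=0) | (xout != 0).any(axis=0))
        pvals = _ranksum_pvalues(xin[:, tested], xout[:, tested])
        adj = np.minimum(pvals * tested.size, 1.0)
        lfc = log2_fold_change(xin[:, tested], xout[:, tested])
        frac_in = (xin[:, tested] > 0).mean(axis=0)
        frac_out = (xout[:, tested] > 0).mean(axis=0)
        keep = (np.abs(lfc) >= lfc_threshold) & (adj <= alpha)
        if positive_only:
            keep &= lfc > 0
        for j in np.flatnonzero(keep):
            records.append(
                {
                    "cluster": cl,
                    "gene": gene_names[tested[j]],
                    "log2fc": lfc[j],
                    "p_value": pvals[j],
                    "adj_p": adj[j],
                    "frac_expr_in": frac_in[j],
                    "frac_expr_out": frac_out[j],
                }
            )
    table = pd.DataFrame(
        records,
        columns=["cluster", "gene", "log2fc", "p_value", "adj_p", "frac_expr_in", "frac_expr_out"],
    )
    if len(table):
        table["_abs"] = table["log2fc"].abs()
        table = table.sort_values(["cluster", "adj_p", "_abs"], ascending=[True, True, False], kind="stable")
        table["rank"] = table.groupby("cluster").cumcount() + 1
        table = table.drop(columns="_abs").reset_index(drop=True)
    else:
        table["rank"] = pd.Series(dtype=int)
    return table


def rank_markers_specificity(
    norm: np.ndarray,
    gene_names: Sequence[str],
    labels: Sequence,
    top_n: int = 25,
) -> pd.DataFrame:
    """Specificity-ranked markers: per cluster, score each gene by
    (fraction of in-cluster cells expressing) × (in-cluster mean expression
    share across clusters) and return the ``top_n`` genes."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    labels = np.asarray(labels)
    clusters = sorted(pd.unique(labels).tolist(), key=str)
    if len(clusters) < 2:
        raise ValueError("at least two clusters required")
    gene_names = list(gene_names)
    means = np.stack([norm[:, labels == cl].mean(axis=1) for cl in clusters])  # K x G
    fracs = np.stack([(norm[:, labels == cl] > 0).mean(axis=1) for cl in clusters])
    total = means.sum(axis=0)
    share = np.divide(means, total[None, :], out=np.zeros_like(means), where=total[None, :] > 0)
    records = []
    for i, cl in enumerate(clusters):
        score = fracs[i] * share[i]
        order = sorted(range(len(gene_names)), key=lambda g: (-score[g], gene_names[g]))[:top_n]
        for rank, g in enumerate(order, start=1):
            records.append(
                {
                    "cluster": cl,
                    "gene": gene_names[g],
                    "specificity": score[g],
                    "expr_share": share[i, g],
                    "frac_expr_in": fracs[i, g],
                    "rank": rank,
                }
            )
    return pd.DataFrame(records)


def consensus_signatures(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    cluster_map: Sequence[Mapping[str, Sequence]],
) -> SignatureSet:
    """Intersect two marker rankings per correspondence group.

    ``cluster_map`` is a list of groups ``{"name": ..., "a": [...], "b": [...]}``
    covering every cluster of both tables; within a group each method's
    member lists are unioned before the cross-method intersection, which
    handles non-1:1 cluster correspondences.
    """
    clusters_a = set(table_a["cluster"].unique())
    clusters_b = set(table_b["cluster"].unique())
    mapped_a = set()
    mapped_b = set()
    for grp in cluster_map:
        mapped_a.update(grp["a"])
        mapped_b.update(grp["b"])
    for side, have, mapped in (("a", clusters_a, mapped_a), ("b", clusters_b, mapped_b)):
        missing = have - mapped
        if missing:
            raise ValueError(f"clusters of table {side} not covered by cluster_map: {sorted(map(str, missing))}")
    sets: Dict[str, List[str]] = {}
    flagged = []
    for grp in cluster_map:
        name = str(grp.get("name", "+".join(map(str, grp["a"]))))
        genes_a = set(table_a.loc[table_a["cluster"].isin(grp["a"]), "gene"])
        genes_b = set(table_b.loc[table_b["cluster"].isin(grp["b"]), "gene"])
        inter = sorted(genes_a & genes_b)
        sets[name] = inter
        if not inter:
            flagged.append(name)
            warnings.warn(f"consensus signature '{name}' is empty")
    return SignatureSet(sets=sets, provenance="consensus", flagged_empty=flagged)


def one_to_one_pairs(pairs: Sequence[Tuple[str, str]]) -> Dict[str, str]:
    """Filter a homolog pair list down to the strictly one-to-one core."""
    src_targets: Dict[str, set] = {}
    tgt_sources: Dict[str, set] = {}
    for s, t in pairs:
        src_targets.setdefault(s, set()).add(t)
        tgt_sources.setdefault(t, set()).add(s)
    return {
        s: next(iter(ts))
        for s, ts in src_targets.items()
        if len(ts) == 1 and len(tgt_sources[next(iter(ts))]) == 1
    }


def map_homologs(
    signatures: SignatureSet,
    homolog_pairs: Sequence[Tuple[str, str]],
) -> Tuple[SignatureSet, Dict[str, List[str]]]:
    """Translate signatures through a homolog map, keeping only genes whose
    mapping is one-to-one in both directions. Returns the mapped set and a
    per-signature report of dropped genes."""
    if not homolog_pairs:
        raise ValueError("empty homolog map")
    translate = one_to_one_pairs(homolog_pairs)
    mapped: Dict[str, List[str]] = {}
    dropped: Dict[str, List[str]] = {}
    for name, genes in signatures:
        kept = [translate[g] for g in genes if g in translate]
        mapped[name] = kept
        dropped[name] = [g for g in genes if g not in translate]
    return SignatureSet(sets=mapped, provenance=signatures.provenance + "+homolog-mapped"), dropped


def median_split(values: Sequence[float]) -> np.ndarray:
    """Binary high/low labels by strict comparison to the median; values
    equal to the median go to "low"."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least two values")
    med = np.median(values)
    if np.all(values == values[0]):
        raise ValueError("all values identical; median split undefined")
    return np.where(values > med, "high", "low")
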