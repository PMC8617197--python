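"""Hashtag-oligo (HTO) demultiplexing: singlet / doublet / negative calls.

The classifier follows the standard hashing logic: CLR-normalise the HTO
counts, k-means-cluster cells in CLR space, take every cell outside the
cluster with the highest mean CLR for a hashtag as that hashtag's
background, fit a negative binomial to the background raw counts by the
method of moments, and call a cell positive for the hashtag when its raw
count exceeds the background's q-quantile. Cells positive for exactly one
hashtag are singlets, for two or more doublets, for none negatives.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.cluster import KMeans


@dataclass
class DemuxResult:
    clr: np.ndarray  # hashtags x cells
    call: List[str]  # singlet / doublet / negative
    assigned_sample: List[Optional[str]]
    positive_set: List[frozenset]
    thresholds: np.ndarray  # per hashtag
    hashtag_names: List[str]

    def to_frame(self, barcodes: Sequence[str] | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"call": self.call, "sample": [s or "" for s in self.assigned_sample]})
        for i, h in enumerate(self.hashtag_names):
            df[f"clr_{h}"] = self.clr[i]
        if barcodes is not None:
            df.insert(0, "barcode", list(barcodes))
        return df


def clr_normalize(counts: np.ndarray) -> np.ndarray:
    """Centered log-ratio per feature across cells.

    out[f, c] = ln((x[f, c] + 1) / geometric_mean_c(x[f, ·] + 1))
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0:
        raise ValueError("empty count matrix")
    if counts.min() < 0:
        raise ValueError("counts must be non-negative")
    logs = np.log1p(counts)
    return logs - logs.mean(axis=1, keepdims=True)


def _nb_quantile_mom(x: np.ndarray, q: float) -> float:
    """q-quantile of a method-of-moments NB fit; Poisson fallback when
    the sample variance does not exceed the mean; 0 for all-zero data."""
    x = np.asarray(x, dtype=float)
    m = x.mean()
    if m == 0:
        warnings.warn("degenerate background (all zeros); threshold set to 0")
        return 0.0
    v = x.var(ddof=1) if len(x) > 1 else m
    if v <= m:
        return float(scipy.stats.poisson.ppf(q, m))
    # NB parameterised by (n, p): mean = n(1-p)/p, var = n(1-p)/p^2
    p = m / v
    n = m * p / (1 - p)
    return float(scipy.stats.nbinom.ppf(q, n, p))


def classify_hashtags(
    counts: np.ndarray,
    hashtag_names: Sequence[str],
    k: int | None = None,
    q: float = 0.99,
    seed: int = 0,
    n_init: int = 10,
) -> DemuxResult:
    """Classify each cell as singlet, doublet, or negative from HTO counts.

    ``k`` defaults to n_hashtags + 1 (one cluster per hashtag plus one for
    negatives/doublets); the background quantile ``q`` must lie in (0.5, 1).
    """
    counts = np.asarray(counts)
    n_hto, n_cells = counts.shape
    if k is None:
        k = n_hto + 1
    if k <= n_hto:
        raise ValueError(f"k={k} must exceed the number of hashtags ({n_hto})")
    if not (0.5 < q < 1):
        raise ValueError("q must be in (0.5, 1)")

    clr = clr_normalize(counts)
    km = KMeans(n_clusters=k, random_state=seed, n_init=n_init).fit(clr.T)
    labels = km.labels_

    # Background per hashtag: the cells of the cluster with the LOWEST mean
    # CLR for that hashtag. Taking everything outside the highest cluster
    # instead would leave cross-sample doublets (signal-level counts) in the
    # background and wreck the moment fit.
    thresholds = np.zeros(n_hto)
    positive = np.zeros((n_hto, n_cells), dtype=bool)
    for h in range(n_hto):
        cluster_means = [clr[h, labels == c].mean() if np.any(labels == c) else np.inf for c in range(k)]
        bottom = int(np.argmin(cluster_means))
        background = counts[h, labels == bottom]
        thresholds[h] = _nb_quantile_mom(background, q)
        positive[h] = counts[h] > thresholds[h]

    n_pos = positive.sum(axis=0)
    call = np.where(n_pos == 0, "negative", np.where(n_pos == 1, "singlet", "doublet")).tolist()
    assigned: List[Optional[str]] = []
    pos_sets: List[frozenset] = []
    names = list(hashtag_names)
    for c in range(n_cells):
        pos = frozenset(names[h] for h in range(n_hto) if positive[h, c])
        pos_sets.append(pos)
        assigned.append(next(iter(pos)) if len(pos) == 1 else None)
    return DemuxResult(
        clr=clr,
        call=call,
        assigned_sample=assigned,
        positive_set=pos_sets,
        thresholds=thresholds,
        hashtag_names=names,
    )


def k_scan(
    counts: np.ndarray,
    hashtag_names: Sequence[str],
    k_values: Sequence[int],
    q: float = 0.99,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the classifier across a range of k and report, per k, the fraction
    of cells classified as singlets/doublets/negatives. The choice among k
    values is left to the user."""
    rows = []
    for k in k_values:
        res = classify_hashtags(counts, hashtag_names, k=k, q=q, seed=seed)
        calls = pd.Series(res.call)
        rows.append(
            {
                "k": k,
                "frac_singlet": (calls == "singlet").mean(),
                "frac_doublet": (calls == "doublet").mean(),
                "frac_negative": (calls == "negative").mean(),
            }
        )
    return pd.DataFrame(rows)


def cross_tabulate(calls_a: Sequence[str], calls_b: Sequence[str]) -> pd.DataFrame:
    """Contingency table between two per-cell call vectors (same cell axis)."""
    if len(calls_a) != len(calls_b):
        raise ValueError(f"mismatched cell axes: {len(calls_a)} vs {len(calls_b)}")
    return pd.crosstab(pd.Series(calls_a, name="a"), pd.Series(calls_b, name="b"))
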