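"""Cell-cycle phase scoring and classification.

Each cell is scored against three programs — S, G2M, and the post-mitotic G1
(G1PM) set of rapid cyclers that retain G2/M transcripts (Birc5, Myc, Mki67,
Foxm1, Aurkb, Plk1) — and labelled by the maximal score; a cell whose three
scores are all negative defaults to G0/G1.

Scores use the bin-matched control scheme standard for single-cell module
scoring: the mean expression of the set genes minus the mean of control
genes drawn from the same average-expression bins, so that sequencing depth
and baseline expression do not masquerade as phase signal.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as bio

PHASE_ORDER = ("S", "G2M", "G1PM")  # tie-break priority, highest first

G1PM_CORE_GENES = ("Birc5", "Myc", "Mki67", "Foxm1", "Aurkb", "Plk1")


def default_phase_gene_sets() -> Dict[str, List[str]]:
    """Packaged canonical S/G2M phase lists plus the six-gene G1PM core."""
    with resources.as_file(resources.files("bcellflow").joinpath("genesets/cell_cycle_mouse.gmt")) as p:
        sets = bio.read_gmt(str(p))
    return {k: sets[k] for k in ("S", "G2M", "G1PM")}


@dataclass
class PhaseScores:
    s_score: np.ndarray
    g2m_score: np.ndarray
    g1pm_score: np.ndarray
    phase: List[str] | None = None

    def to_frame(self, barcodes: Sequence[str] | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {"S.Score": self.s_score, "G2M.Score": self.g2m_score, "G1PM.Score": self.g1pm_score}
        )
        if self.phase is not None:
            df["Phase"] = self.phase
        if barcodes is not None:
            df.insert(0, "barcode", list(barcodes))
        return df


def module_score(
    norm_expr: np.ndarray,
    gene_names: Sequence[str],
    gene_set: Sequence[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
    raw_mean: bool = False,
) -> np.ndarray:
    """Per-cell module score for one gene set on a genes×cells matrix.

    Controls are drawn without replacement, ``n_ctrl`` per set gene, from the
    set gene's average-expression bin (``n_bins`` equal-frequency bins over
    all genes); the score is mean(set genes) − mean(pooled control genes).
    With ``raw_mean=True`` the control subtraction is skipped.
    """
    norm_expr = np.asarray(norm_expr, dtype=float)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    name_index = {g: i for i, g in enumerate(gene_names)}
    present = [g for g in gene_set if g in name_index]
    missing = [g for g in gene_set if g not in name_index]
    if len(present) < 0.5 * len(gene_set):
        raise ValueError(
            f"only {len(present)}/{len(gene_set)} gene-set genes present; missing: {missing}"
        )
    set_idx = np.array(sorted(name_index[g] for g in present))
    set_mean = norm_expr[set_idx].mean(axis=0)
    if raw_mean:
        return set_mean

    avg = norm_expr.mean(axis=1)
    # equal-frequency bins over average expression; rank-based to be robust
    order = np.argsort(avg, kind="stable")
    bins = np.empty(len(avg), dtype=int)
    bins[order] = np.minimum((np.arange(len(avg)) * n_bins) // len(avg), n_bins - 1)

    rng = np.random.default_rng(seed)
    in_set = np.zeros(len(avg), dtype=bool)
    in_set[set_idx] = True
    ctrl: set[int] = set()
    for gi in set_idx:
        # control pool excludes the set itself, so a uniform shift of the
        # set genes moves the score by exactly that shift
        pool = np.flatnonzero((bins == bins[gi]) & ~in_set)
        take = min(n_ctrl, len(pool))
        ctrl.update(rng.choice(pool, size=take, replace=False).tolist())
    if not ctrl:
        raise ValueError("no control genes available outside the gene set")
    ctrl_idx = np.array(sorted(ctrl))
    ctrl_mean = norm_expr[ctrl_idx].mean(axis=0)
    return set_mean - ctrl_mean


def score_phases(
    norm_expr: np.ndarray,
    gene_names: Sequence[str],
    gene_sets: Mapping[str, Sequence[str]] | None = None,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
    raw_mean: bool = False,
) -> PhaseScores:
    """Score all three phase programs (without classifying)."""
    sets = dict(gene_sets) if gene_sets is not None else default_phase_gene_sets()
    kw = dict(n_bins=n_bins, n_ctrl=n_ctrl, raw_mean=raw_mean)
    return PhaseScores(
        s_score=module_score(norm_expr, gene_names, sets["S"], seed=seed, **kw),
        g2m_score=module_score(norm_expr, gene_names, sets["G2M"], seed=seed + 1, **kw),
        g1pm_score=module_score(norm_expr, gene_names, sets["G1PM"], seed=seed + 2, **kw),
    )


def classify_phase(scores: PhaseScores) -> PhaseScores:
    """Assign a discrete phase per cell.

    Highest score wins; exact ties broken by the fixed priority S > G2M >
    G1PM; a cell with all three scores negative defaults to G0/G1.
    """
    mat = np.vstack([scores.s_score, scores.g2m_score, scores.g1pm_score])
    bad = ~np.isfinite(mat)
    if bad.any():
        cells = np.flatnonzero(bad.any(axis=0))
        raise ValueError(f"non-finite phase scores for cells at positions {cells[:10].tolist()}")
    labels: List[str] = []
    for c in range(mat.shape[1]):
        col = mat[:, c]
        if np.all(col < 0):
            labels.append("G0G1")
        else:
            labels.append(PHASE_ORDER[int(np.argmax(col))])  # argmax takes first on ties
    return PhaseScores(scores.s_score, scores.g2m_score, scores.g1pm_score, phase=labels)
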