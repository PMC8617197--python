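"""Synthetic multimodal (CITE-seq-like) and bulk-subtype data with ground truth.

The generator emulates the structure of a two-mouse hashed bone-marrow
experiment: a gene×cell RNA count matrix with stage-specific programs laid
out along a latent developmental ordering, overlaid cell-cycle programs
(S, G2M, and the six-gene post-mitotic G1 "G1PM" program plus padding),
mitochondrial genes, hashtag-oligo counts with cross-sample doublets, and
six antibody-derived-tag (ADT) surface markers with stage-dependent means.
Counts are negative binomial (gamma–Poisson) with a gene-shared dispersion
and a log-normal per-cell depth factor.

Every cell's stage, phase, sample of origin, and doublet status — and every
gene's program membership — are recorded in a GroundTruth object so that
downstream stages can be tested without any external data.
"""
from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import io as bio
from .cellcycle import default_phase_gene_sets

PHASES = ("G0G1", "S", "G2M", "G1PM")

# Canonical surface-marker panel; means below emulate stage-restricted
# expression across six developmental stages (pre-pro-B ... mature B).
DEFAULT_ADT_NAMES = ("B220", "CD19", "CD93", "CD25", "IgM", "CD43")
_ADT_MEANS_6x6 = np.array(
    [
        # preproB proB  preBCRd preBCRi smallpre mature
        [200, 300, 300, 300, 400, 800],  # B220
        [10, 200, 300, 300, 300, 400],  # CD19
        [300, 300, 300, 300, 200, 30],  # CD93
        [5, 10, 30, 200, 100, 10],  # CD25
        [5, 5, 5, 5, 300, 600],  # IgM
        [400, 400, 300, 150, 30, 20],  # CD43
    ],
    dtype=float,
)

_MITO_BASENAMES = [
    "mt-Nd1", "mt-Nd2", "mt-Co1", "mt-Co2", "mt-Atp8", "mt-Atp6", "mt-Co3",
    "mt-Nd3", "mt-Nd4l", "mt-Nd4", "mt-Nd5", "mt-Nd6", "mt-Cytb",
]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


def _check_simplex(w: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(w, dtype=float)
    if arr.ndim != 1 or np.any(arr < 0) or abs(arr.sum() - 1.0) > 1e-9:
        raise ConfigError(f"{name} must be non-negative and sum to 1 (got {list(arr)})")
    return arr


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the CITE-seq-like simulation.

    ``stage_lfc`` and ``phase_lfc`` are log2 effect sizes of the planted
    programs; ``nb_dispersion`` is the negative-binomial theta
    (var = mu + mu^2/theta); ``depth_lognorm_params`` are (mu, sigma) of the
    log-normal per-cell depth factor; ``stage_bump_width`` is the width (in
    units of the [0,1) latent time) of each stage program's Gaussian bump,
    so programs ramp up and down smoothly across neighbouring stages.
    """

    n_cells: int = 2000
    n_genes: int = 1500
    n_stages: int = 6
    stage_props: Optional[Sequence[float]] = None
    phase_props: Mapping[str, float] = field(
        default_factory=lambda: {"G0G1": 0.55, "S": 0.20, "G2M": 0.15, "G1PM": 0.10}
    )
    n_hashtags: int = 2
    doublet_rate: float = 0.10
    n_adt: int = 6
    prog_genes_per_stage: int = 40
    n_gradient_genes: int = 30
    stage_lfc: float = 2.0
    phase_lfc: float = 2.0
    nb_dispersion: float = 10.0
    depth_lognorm_params: Tuple[float, float] = (0.0, 0.35)
    mito_gene_frac: float = 0.01
    mito_expr_frac: float = 0.05
    g1pm_padding: int = 14
    stage_bump_width: Optional[float] = None
    continuous: bool = True
    mean_depth: float = 3000.0
    hto_signal_mean: float = 300.0
    hto_background_mean: float = 15.0
    seed: int = 0

    def validate(self) -> "SimConfig":
        for attr in ("n_cells", "n_genes", "n_stages", "n_hashtags", "n_adt", "prog_genes_per_stage"):
            if getattr(self, attr) <= 0:
                raise ConfigError(f"{attr} must be positive")
        if not (0 <= self.doublet_rate < 1):
            raise ConfigError("doublet_rate must be in [0, 1)")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be positive")
        props = self.stage_props if self.stage_props is not None else [1.0 / self.n_stages] * self.n_stages
        sp_arr = _check_simplex(props, "stage_props")
        if len(sp_arr) != self.n_stages:
            raise ConfigError("stage_props length must equal n_stages")
        ph = [self.phase_props.get(p, 0.0) for p in PHASES]
        _check_simplex(ph, "phase_props")
        return self

    @property
    def stage_props_array(self) -> np.ndarray:
        if self.stage_props is None:
            return np.full(self.n_stages, 1.0 / self.n_stages)
        return np.asarray(self.stage_props, dtype=float)

    @property
    def phase_props_array(self) -> np.ndarray:
        return np.asarray([self.phase_props.get(p, 0.0) for p in PHASES], dtype=float)


@dataclass
class CountsBundle:
    """RNA / HTO / ADT count matrices sharing one cell axis."""

    rna: sp.csr_matrix  # genes x cells
    hto: np.ndarray  # hashtags x cells
    adt: np.ndarray  # markers x cells
    gene_names: List[str]
    cell_barcodes: List[str]
    hashtag_names: List[str]
    adt_names: List[str]
    mito_mask: np.ndarray  # bool per gene

    def __post_init__(self) -> None:
        n = len(self.cell_barcodes)
        for name, mat in (("rna", self.rna), ("hto", self.hto), ("adt", self.adt)):
            if mat.shape[1] != n:
                raise ValueError(f"{name} has {mat.shape[1]} cells; expected {n}")
        for name, ids in (
            ("gene_names", self.gene_names),
            ("cell_barcodes", self.cell_barcodes),
            ("hashtag_names", self.hashtag_names),
            ("adt_names", self.adt_names),
        ):
            if len(set(ids)) != len(ids):
                raise ValueError(f"{name} contains duplicates")

    @property
    def n_cells(self) -> int:
        return len(self.cell_barcodes)

    def subset_cells(self, mask: np.ndarray) -> "CountsBundle":
        idx = np.flatnonzero(np.asarray(mask))
        return CountsBundle(
            rna=self.rna[:, idx],
            hto=self.hto[:, idx],
            adt=self.adt[:, idx],
            gene_names=list(self.gene_names),
            cell_barcodes=[self.cell_barcodes[i] for i in idx],
            hashtag_names=list(self.hashtag_names),
            adt_names=list(self.adt_names),
            mito_mask=self.mito_mask.copy(),
        )

    def subset_genes(self, mask: np.ndarray) -> "CountsBundle":
        idx = np.flatnonzero(np.asarray(mask))
        return CountsBundle(
            rna=self.rna[idx, :],
            hto=self.hto,
            adt=self.adt,
            gene_names=[self.gene_names[i] for i in idx],
            cell_barcodes=list(self.cell_barcodes),
            hashtag_names=list(self.hashtag_names),
            adt_names=list(self.adt_names),
            mito_mask=self.mito_mask[idx],
        )

    def write_10x(self, outdir: str, gzipped: bool = False) -> None:
        """Write RNA+HTO+ADT as one 10x-style triplet; HTO/ADT rows are
        typed "Antibody Capture" in the features file."""
        matrix = sp.vstack([sp.csr_matrix(self.rna), sp.csr_matrix(self.hto), sp.csr_matrix(self.adt)])
        names = list(self.gene_names) + list(self.hashtag_names) + list(self.adt_names)
        types = [bio.GENE_EXPRESSION] * len(self.gene_names) + [bio.ANTIBODY_CAPTURE] * (
            len(self.hashtag_names) + len(self.adt_names)
        )
        bio.write_10x(outdir, matrix, names, self.cell_barcodes, types, gzipped=gzipped)


@dataclass
class GroundTruth:
    """Per-cell and per-gene truth emitted by the simulator."""

    cell_stage: List[str]
    cell_phase: List[str]
    cell_sample: List[str]  # "HTO-a+HTO-b" for doublets
    is_doublet: np.ndarray
    gene_program: Dict[str, str]
    latent_time: np.ndarray
    doublet_sources: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]]
    planted_bulk_enrichment: Dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": self.cell_stage,
                "phase": self.cell_phase,
                "sample": self.cell_sample,
                "is_doublet": self.is_doublet.astype(int),
                "latent_time": self.latent_time,
            }
        )

    def write_tsv(self, path: str, barcodes: Sequence[str]) -> None:
        df = self.to_frame()
        df.insert(0, "barcode", list(barcodes))
        df.to_csv(path, sep="\t", index=False)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, theta: float) -> np.ndarray:
    """Gamma–Poisson draw: var = mu + mu^2/theta."""
    mean = np.asarray(mean, dtype=float)
    lam = np.zeros_like(mean)
    pos = mean > 0
    lam[pos] = rng.gamma(shape=theta, scale=mean[pos] / theta)
    return rng.poisson(lam)


def _build_gene_universe(config: SimConfig) -> Tuple[List[str], Dict[str, str], np.ndarray, Dict[str, List[str]]]:
    """Assemble gene names, program membership, mito mask, and phase sets."""
    phase_sets = default_phase_gene_sets()
    g1pm_pad = [f"G1pmPad{i + 1}" for i in range(config.g1pm_padding)]
    g1pm_program = list(phase_sets["G1PM"]) + g1pm_pad

    n_mito = max(1, int(round(config.mito_gene_frac * config.n_genes)))
    mito = list(_MITO_BASENAMES[:n_mito])
    mito += [f"mt-G{i + 1}" for i in range(n_mito - len(mito))]

    stage_prog: Dict[int, List[str]] = {
        s: [f"Stg{s}Gene{j + 1}" for j in range(config.prog_genes_per_stage)]
        for s in range(config.n_stages)
    }
    # monotone developmental ramps (half rising, half falling with latent
    # time), emulating genes like Ebf1/Vpreb1 whose expression trends across
    # the whole trajectory rather than marking one stage
    n_up = config.n_gradient_genes // 2
    grad_up = [f"GradUp{j + 1}" for j in range(n_up)]
    grad_dn = [f"GradDn{j + 1}" for j in range(config.n_gradient_genes - n_up)]

    names: List[str] = []
    program: Dict[str, str] = {}
    for g in phase_sets["S"]:
        names.append(g)
        program[g] = "S"
    for g in phase_sets["G2M"]:
        if g not in program:
            names.append(g)
            program[g] = "G2M"
    for g in g1pm_program:
        if g not in program:
            names.append(g)
        program[g] = "G1PM"  # carry-over genes relabelled to the G1PM program
    for g in mito:
        names.append(g)
        program[g] = "mito"
    for s, genes in stage_prog.items():
        for g in genes:
            names.append(g)
            program[g] = f"stage_{s}"
    for g in grad_up:
        names.append(g)
        program[g] = "gradient_up"
    for g in grad_dn:
        names.append(g)
        program[g] = "gradient_down"
    n_filler = config.n_genes - len(names)
    if n_filler < 0:
        raise ConfigError(
            f"n_genes={config.n_genes} too small for programs ({len(names)} genes needed)"
        )
    names += [f"Gene{i + 1:05d}" for i in range(n_filler)]
    mito_mask = np.array([g.startswith("mt-") for g in names])
    sets = {"S": list(phase_sets["S"]), "G2M": list(phase_sets["G2M"]), "G1PM": g1pm_program}
    return names, program, mito_mask, sets


def simulate_cite(config: SimConfig) -> Tuple[CountsBundle, GroundTruth]:
    """Simulate an RNA+HTO+ADT bundle with ground truth.

    RNA means factorise as baseline × stage effect × phase effect × depth.
    Stage programs are Gaussian bumps over a latent developmental time, so
    expression ramps smoothly between neighbouring stages (a continuous
    trajectory rather than disconnected islands). Doublets are formed by
    summing the RNA/HTO/ADT columns of two singlets from different hashtags.
    """
    config = config.validate()
    rng = np.random.default_rng(config.seed)
    n_out = config.n_cells
    n_doub = int(round(config.doublet_rate * n_out))
    if n_doub > 0 and config.n_hashtags < 2:
        raise ConfigError("doublets require at least two hashtags")
    n_singlet_out = n_out - n_doub
    n_src = n_singlet_out + 2 * n_doub  # singlets drawn before pairing

    gene_names, gene_program, mito_mask, sets = _build_gene_universe(config)
    G = len(gene_names)

    # Baseline means: log-normal, scaled so that expected depth matches
    # mean_depth, with mito genes pinned to a fixed share of it.
    base = rng.lognormal(mean=0.0, sigma=1.2, size=G)
    base[mito_mask] = 0.0
    base *= (1 - config.mito_expr_frac) * config.mean_depth / base.sum()
    n_mito = int(mito_mask.sum())
    base[mito_mask] = config.mito_expr_frac * config.mean_depth / n_mito

    # Per-cell latent structure.
    stages = rng.choice(config.n_stages, size=n_src, p=config.stage_props_array)
    # continuous: cells spread over their stage's latent-time interval,
    # giving a connected trajectory; discrete: all cells sit at the stage
    # centre, making cells within a stage exchangeable
    jitter = rng.uniform(size=n_src) if config.continuous else np.full(n_src, 0.5)
    latent = (stages + jitter) / config.n_stages
    phases = np.array(PHASES)[rng.choice(4, size=n_src, p=config.phase_props_array)]
    depth = rng.lognormal(*config.depth_lognorm_params, size=n_src)
    hashtags = rng.integers(config.n_hashtags, size=n_src)

    # Stage-program multipliers: Gaussian bump over latent time.
    width = config.stage_bump_width if config.stage_bump_width is not None else 0.5 / config.n_stages
    centers = (np.arange(config.n_stages) + 0.5) / config.n_stages
    log2_mult = np.zeros((G, n_src))
    name_index = {g: i for i, g in enumerate(gene_names)}
    for s in range(config.n_stages):
        gidx = [name_index[g] for g, p in gene_program.items() if p == f"stage_{s}"]
        bump = np.exp(-0.5 * ((latent - centers[s]) / width) ** 2)
        log2_mult[np.array(gidx)[:, None], :] += config.stage_lfc * bump[None, :]
    up_idx = [name_index[g] for g, p in gene_program.items() if p == "gradient_up"]
    dn_idx = [name_index[g] for g, p in gene_program.items() if p == "gradient_down"]
    if up_idx:
        log2_mult[np.array(up_idx)[:, None], :] += config.stage_lfc * latent[None, :]
    if dn_idx:
        log2_mult[np.array(dn_idx)[:, None], :] += config.stage_lfc * (1 - latent)[None, :]

    # Phase-program multipliers. Genes shared between the canonical G2M
    # list and the G1PM program are elevated in both phases (carry-over).
    phase_member = {
        p: np.array([name_index[g] for g in sets[p] if g in name_index]) for p in ("S", "G2M", "G1PM")
    }
    g2m_carryover = np.array([name_index[g] for g in sets["G1PM"] if g in set(sets["G2M"])])
    for p in ("S", "G2M", "G1PM"):
        cells = np.flatnonzero(phases == p)
        if cells.size:
            log2_mult[phase_member[p][:, None], cells[None, :]] += config.phase_lfc
    g2m_cells = np.flatnonzero(phases == "G2M")
    if g2m_cells.size and g2m_carryover.size:
        # already counted once via G2M membership; no double count needed
        pass

    mean = base[:, None] * (2.0 ** log2_mult) * depth[None, :]
    rna_src = _nb_draw(rng, mean, config.nb_dispersion)

    # HTO counts: own hashtag at signal mean, others at background.
    hto_mean = np.full((config.n_hashtags, n_src), config.hto_background_mean)
    hto_mean[hashtags, np.arange(n_src)] = config.hto_signal_mean
    hto_src = _nb_draw(rng, hto_mean, config.nb_dispersion)

    # ADT counts: per-marker stage-dependent means (log2 bump profile).
    adt_names = list(DEFAULT_ADT_NAMES[: config.n_adt]) + [
        f"ADT{i + 1}" for i in range(max(0, config.n_adt - len(DEFAULT_ADT_NAMES)))
    ]
    if config.n_adt == 6 and config.n_stages == 6:
        adt_stage_means = _ADT_MEANS_6x6
    else:
        s_grid = np.arange(config.n_stages)
        adt_stage_means = np.array(
            [
                30.0 * 4.0 ** np.exp(-0.5 * ((s_grid - m * (config.n_stages - 1) / max(1, config.n_adt - 1)) / 1.2) ** 2)
                for m in range(config.n_adt)
            ]
        )
    adt_mean = adt_stage_means[:, stages]
    adt_src = _nb_draw(rng, adt_mean, config.nb_dispersion)

    # Doublet formation: pair singlets from different hashtags, sum columns.
    src_order = rng.permutation(n_src)
    singlet_idx: List[int] = []
    pool_by_tag: Dict[int, List[int]] = {t: [] for t in range(config.n_hashtags)}
    for i in src_order:
        pool_by_tag[hashtags[i]].append(i)
    pairs: List[Tuple[int, int]] = []
    for _ in range(n_doub):
        # take from the two largest pools to guarantee differing hashtags
        tags = sorted(pool_by_tag, key=lambda t: len(pool_by_tag[t]), reverse=True)
        a, b = pool_by_tag[tags[0]].pop(), pool_by_tag[tags[1]].pop()
        pairs.append((a, b))
    for t in pool_by_tag:
        singlet_idx.extend(pool_by_tag[t])
    singlet_idx = sorted(singlet_idx)[:n_singlet_out]

    cols_rna: List[np.ndarray] = []
    cols_hto: List[np.ndarray] = []
    cols_adt: List[np.ndarray] = []
    cell_stage: List[str] = []
    cell_phase: List[str] = []
    cell_sample: List[str] = []
    lat_out: List[float] = []
    is_doublet = np.zeros(n_out, dtype=bool)
    hashtag_names = [f"HTO-{i + 1}" for i in range(config.n_hashtags)]
    doublet_sources: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
    barcodes = [f"CELL{i + 1:06d}" for i in range(n_out)]

    for i in singlet_idx:
        cols_rna.append(rna_src[:, i])
        cols_hto.append(hto_src[:, i])
        cols_adt.append(adt_src[:, i])
        cell_stage.append(f"stage_{stages[i]}")
        cell_phase.append(str(phases[i]))
        cell_sample.append(hashtag_names[hashtags[i]])
        lat_out.append(latent[i])
    for j, (a, b) in enumerate(pairs):
        pos = n_singlet_out + j
        cols_rna.append(rna_src[:, a] + rna_src[:, b])
        cols_hto.append(hto_src[:, a] + hto_src[:, b])
        cols_adt.append(adt_src[:, a] + adt_src[:, b])
        cell_stage.append(f"stage_{stages[a]}")
        cell_phase.append(str(phases[a]))
        cell_sample.append("+".join(sorted([hashtag_names[hashtags[a]], hashtag_names[hashtags[b]]])))
        lat_out.append(float(latent[a]))
        is_doublet[pos] = True
        doublet_sources[barcodes[pos]] = (
            rna_src[:, a].copy(),
            rna_src[:, b].copy(),
            hto_src[:, a].copy(),
            hto_src[:, b].copy(),
        )

    bundle = CountsBundle(
        rna=sp.csr_matrix(np.column_stack(cols_rna)),
        hto=np.column_stack(cols_hto),
        adt=np.column_stack(cols_adt),
        gene_names=gene_names,
        cell_barcodes=barcodes,
        hashtag_names=hashtag_names,
        adt_names=adt_names,
        mito_mask=mito_mask,
    )
    truth = GroundTruth(
        cell_stage=cell_stage,
        cell_phase=cell_phase,
        cell_sample=cell_sample,
        is_doublet=is_doublet,
        gene_program=gene_program,
        latent_time=np.asarray(lat_out),
        doublet_sources=doublet_sources,
    )
    return bundle, truth


@dataclass(frozen=True)
class BulkSimConfig:
    """Parameters of the bulk "B-ALL subtype" simulation."""

    n_subtypes: int = 4
    replicates_per_subtype: int = 3
    n_genes: int = 2000
    planted_lfc: float = 2.0
    nb_dispersion: float = 20.0
    depth: float = 1e6
    seed: int = 0

    def validate(self) -> "BulkSimConfig":
        if self.replicates_per_subtype < 1:
            raise ConfigError("replicates_per_subtype must be >= 1")
        if self.n_subtypes < 1 or self.n_genes < 1:
            raise ConfigError("n_subtypes and n_genes must be positive")
        if self.planted_lfc < 0:
            raise ConfigError("planted_lfc must be >= 0")
        return self


def simulate_bulk_subtypes(
    config: BulkSimConfig,
    signatures: Mapping[str, Sequence[str]],
    gene_names: Optional[Sequence[str]] = None,
) -> Tuple[pd.DataFrame, pd.Series, GroundTruth]:
    """Simulate a sample×gene bulk count table with planted signature enrichment.

    Each subtype is assigned one signature (round-robin when there are fewer
    signatures than subtypes); that signature's genes get their mean
    multiplied by 2**planted_lfc in the subtype's replicates. Returns
    (counts, sample→subtype map, GroundTruth with the planting recorded).
    """
    config = config.validate()
    if not signatures:
        raise ConfigError("at least one signature required")
    sig_names = list(signatures)
    sig_genes = {k: list(dict.fromkeys(v)) for k, v in signatures.items()}
    all_sig_genes = [g for genes in sig_genes.values() for g in genes]
    if gene_names is None:
        universe = list(dict.fromkeys(all_sig_genes))
        n_filler = config.n_genes - len(universe)
        if n_filler < 0:
            raise ConfigError("n_genes smaller than the signature gene universe")
        universe += [f"BulkGene{i + 1:05d}" for i in range(n_filler)]
    else:
        universe = list(gene_names)
        missing = sorted(set(all_sig_genes) - set(universe))
        if missing:
            raise ConfigError(f"signatures reference unknown genes: {missing}")
    gidx = {g: i for i, g in enumerate(universe)}
    G = len(universe)

    rng = np.random.default_rng(config.seed)
    base = rng.lognormal(mean=0.0, sigma=1.0, size=G)
    base *= config.depth / base.sum()

    subtypes = [f"subtype_{i + 1}" for i in range(config.n_subtypes)]
    planted = {st: sig_names[i % len(sig_names)] for i, st in enumerate(subtypes)}

    samples: List[str] = []
    sample_subtype: List[str] = []
    rows: List[np.ndarray] = []
    for st in subtypes:
        mean = base.copy()
        idx = [gidx[g] for g in sig_genes[planted[st]]]
        mean[idx] *= 2.0 ** config.planted_lfc
        for r in range(config.replicates_per_subtype):
            samples.append(f"{st}_rep{r + 1}")
            sample_subtype.append(st)
            rows.append(_nb_draw(rng, mean, config.nb_dispersion))
    counts = pd.DataFrame(np.vstack(rows), index=samples, columns=universe)
    sample_map = pd.Series(sample_subtype, index=samples, name="subtype")
    truth = GroundTruth(
        cell_stage=[],
        cell_phase=[],
        cell_sample=[],
        is_doublet=np.zeros(0, dtype=bool),
        gene_program={},
        latent_time=np.zeros(0),
        doublet_sources={},
        planted_bulk_enrichment=planted,
    )
    return counts, sample_map, truth
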