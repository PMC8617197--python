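"""Stage orchestration: simulate → demux → cell cycle → cluster/merge →
markers → trajectory → enrichment, with a fixed output layout.

Outputs land under the configured directory: ``counts/`` (10x triplet),
``tables/`` (TSV), ``genesets/`` (GMT), ``reports/`` (TSV + log). Every TSV
carries a header comment with the package version, stage seed, and config
hash; reruns with the same config are bit-identical. Completed stages are
skipped unless ``force`` is set.
"""
from __future__ import annotations

import logging
import os
import time
from dataclasses import dataclass, field
from typing import Dict, List

import numpy as np
import pandas as pd

from . import __version__
from . import io as bio
from .cellcycle import classify_phase, score_phases
from .config import RunConfig
from .demux import classify_hashtags, k_scan
from .enrichment import build_enrichment_grid
from .markers import (
    consensus_signatures,
    map_homologs,
    rank_markers_ovr,
    rank_markers_specificity,
)
from .preprocess import (
    community_cluster,
    filter_cells_genes,
    knn_graph,
    merge_by_de,
    normalize,
    run_pca,
)
from .simulate import BulkSimConfig, SimConfig, simulate_bulk_subtypes, simulate_cite
from .trajectory import autocorrelated_genes, gene_modules, geodesic_pseudotime, regress_cycle

log = logging.getLogger("bcellflow")


@dataclass
class RunReport:
    stages_run: List[str] = field(default_factory=list)
    stages_skipped: List[str] = field(default_factory=list)
    shapes: Dict[str, str] = field(default_factory=dict)
    wall_time: Dict[str, float] = field(default_factory=dict)
    warnings: List[str] = field(default_factory=list)


def _header(config: RunConfig, stage: str) -> str:
    return (
        f"# bcellflow {__version__} seed={config.stage_seed(stage)} "
        f"config_hash={config.config_hash()}\n"
    )


def _write_tsv(df: pd.DataFrame, path: str, config: RunConfig, stage: str, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config, stage))
        df.to_csv(fh, sep="\t", index=index)


def _read_tsv(path: str, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kw)


def _dirs(config: RunConfig) -> Dict[str, str]:
    out = config.outdir
    d = {k: os.path.join(out, k) for k in ("counts", "tables", "genesets", "reports")}
    for p in d.values():
        os.makedirs(p, exist_ok=True)
    return d


def run_pipeline(config: RunConfig, force: bool = False) -> RunReport:
    """Execute the configured stages in order.

    A stage whose outputs already exist is skipped unless ``force``; a stage
    toggled off whose outputs are missing raises when a later stage needs
    them. Fails fast with the failing stage named.
    """
    report = RunReport()
    d = _dirs(config)
    ann_path = os.path.join(d["tables"], "cell_annotations.tsv")

    def _stage(name: str, outputs: List[str]):
        def decorator(fn):
            def runner():
                if not getattr(config.stages, name):
                    report.stages_skipped.append(name)
                    return
                if not force and outputs and all(os.path.exists(p) for p in outputs):
                    report.stages_skipped.append(name)
                    return
                t0 = time.time()
                try:
                    fn()
                except Exception as exc:
                    raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
                report.wall_time[name] = time.time() - t0
                report.stages_run.append(name)
                log.info("stage %s done in %.1fs", name, report.wall_time[name])

            return runner

        return decorator

    # ------------------------------------------------------------------ simulate
    @_stage("simulate", [os.path.join(d["counts"], "matrix.mtx"), os.path.join(d["tables"], "ground_truth.tsv")])
    def stage_simulate():
        sim_cfg = SimConfig(**config.sim.model_dump(), seed=config.stage_seed("simulate"))
        bundle, truth = simulate_cite(sim_cfg)
        bundle.write_10x(d["counts"])
        truth.write_tsv(os.path.join(d["tables"], "ground_truth.tsv"), bundle.cell_barcodes)
        report.shapes["simulate"] = f"rna {bundle.rna.shape}, hto {bundle.hto.shape}, adt {bundle.adt.shape}"

    # ------------------------------------------------------------------ demux
    @_stage("demux", [os.path.join(d["tables"], "demux.tsv")])
    def stage_demux():
        bundle = _load_bundle(d["counts"])
        res = classify_hashtags(
            bundle.hto, bundle.hashtag_names, k=config.demux.k, q=config.demux.q,
            seed=config.stage_seed("demux"),
        )
        _write_tsv(res.to_frame(bundle.cell_barcodes), os.path.join(d["tables"], "demux.tsv"), config, "demux")
        if config.demux.k_scan:
            scan = k_scan(bundle.hto, bundle.hashtag_names, config.demux.k_scan, q=config.demux.q,
                          seed=config.stage_seed("demux"))
            _write_tsv(scan, os.path.join(d["reports"], "k_scan.tsv"), config, "demux")
        report.shapes["demux"] = f"{len(res.call)} cells"

    # ------------------------------------------------------------------ cellcycle
    @_stage("cellcycle", [ann_path])
    def stage_cellcycle():
        bundle = _load_bundle(d["counts"])
        demux_df = _read_tsv(os.path.join(d["tables"], "demux.tsv"))
        singlet = (demux_df["call"] == "singlet").to_numpy()
        bundle = bundle.subset_cells(singlet)
        samples = demux_df.loc[singlet, "sample"].to_numpy()
        filtered, frep = filter_cells_genes(
            bundle, config.filter.min_genes, config.filter.min_cells, config.filter.mito_top_frac
        )
        keep = set(filtered.cell_barcodes)
        samples = samples[[bc in keep for bc in bundle.cell_barcodes]]
        _write_tsv(
            pd.DataFrame(
                {
                    "metric": ["n_cells_in", "n_cells_out", "n_genes_in", "n_genes_out",
                               "n_removed_low_genes", "n_removed_mito"],
                    "value": [frep.n_cells_in, frep.n_cells_out, frep.n_genes_in, frep.n_genes_out,
                              len(frep.removed_low_genes), len(frep.removed_for_mito)],
                }
            ),
            os.path.join(d["reports"], "filter_report.tsv"), config, "cellcycle",
        )
        filtered.write_10x(os.path.join(d["counts"], "filtered"))
        # phase scores are computed on the variance-stabilised normalisation,
        # which separates baseline from induced expression far better than
        # log counts for the bimodal cycle programs
        vst = normalize(filtered.rna, config.normalize.method, theta=config.normalize.theta)
        scores = classify_phase(
            score_phases(
                vst, filtered.gene_names,
                n_bins=config.cellcycle.n_bins, n_ctrl=config.cellcycle.n_ctrl,
                raw_mean=config.cellcycle.raw_mean, seed=config.stage_seed("cellcycle"),
            )
        )
        ann = scores.to_frame(filtered.cell_barcodes)
        ann.insert(1, "sample", samples)
        _write_tsv(ann, ann_path, config, "cellcycle")
        report.shapes["cellcycle"] = f"{filtered.n_cells} singlet cells after filtering"

    # ------------------------------------------------------------------ cluster
    @_stage("cluster", [os.path.join(d["tables"], "clusters.tsv")])
    def stage_cluster():
        filtered = _load_bundle(os.path.join(d["counts"], "filtered"))
        covar = _pct_mito(filtered) if config.normalize.regress_mito else None
        norm = normalize(filtered.rna, config.normalize.method, covariates=covar, theta=config.normalize.theta)
        pca = run_pca(norm, config.cluster.n_pcs, scale=config.cluster.scale_pca)
        graph = knn_graph(pca, config.cluster.knn_k)
        labels = community_cluster(graph, config.cluster.resolution, seed=config.stage_seed("cluster"))
        merged = merge_by_de(
            normalize(filtered.rna, "log_cpm_median"), labels,
            min_de=config.cluster.min_de, lfc_threshold=config.cluster.lfc, alpha=config.cluster.alpha,
        )
        _write_tsv(
            pd.DataFrame({"barcode": filtered.cell_barcodes, "cluster": merged.labels}),
            os.path.join(d["tables"], "clusters.tsv"), config, "cluster",
        )
        _write_tsv(
            pd.DataFrame(
                [{"merged_a": a, "merged_b": b, "n_de": n} for (a, b), n in merged.merge_log]
            ),
            os.path.join(d["reports"], "merge_log.tsv"), config, "cluster",
        )
        _write_tsv(
            pd.DataFrame(pca, index=filtered.cell_barcodes).rename_axis("barcode"),
            os.path.join(d["tables"], "pca.tsv"), config, "cluster", index=True,
        )
        report.shapes["cluster"] = f"{merged.labels.max() + 1} clusters ({len(merged.merge_log)} merges)"

    # ------------------------------------------------------------------ markers
    @_stage("markers", [os.path.join(d["genesets"], "signatures_human.gmt")])
    def stage_markers():
        filtered = _load_bundle(os.path.join(d["counts"], "filtered"))
        labels = _read_tsv(os.path.join(d["tables"], "clusters.tsv"))["cluster"].to_numpy()
        logn = normalize(filtered.rna, "log_cpm_median")
        ovr = rank_markers_ovr(
            logn, filtered.gene_names, labels,
            lfc_threshold=config.markers.lfc, alpha=config.markers.alpha,
            positive_only=config.markers.positive_only,
        )
        spec_tab = rank_markers_specificity(logn, filtered.gene_names, labels, top_n=config.markers.top_n)
        _write_tsv(ovr, os.path.join(d["tables"], "markers_ovr.tsv"), config, "markers")
        _write_tsv(spec_tab, os.path.join(d["tables"], "markers_specificity.tsv"), config, "markers")
        clusters = sorted(set(labels.tolist()))
        cmap = [{"name": f"cluster_{c}", "a": [c], "b": [c]} for c in clusters]
        cons = consensus_signatures(ovr, spec_tab, cmap)
        bio.write_gmt(os.path.join(d["genesets"], "signatures.gmt"), cons.sets)
        # mouse→human style translation (uppercase symbols) for the bulk stage
        pairs = [(g, g.upper()) for g in filtered.gene_names]
        mapped, dropped = map_homologs(cons, pairs)
        bio.write_gmt(os.path.join(d["genesets"], "signatures_human.gmt"), mapped.sets)
        _write_tsv(
            pd.DataFrame(
                [{"signature": k, "dropped_gene": g} for k, gs in dropped.items() for g in gs]
            ),
            os.path.join(d["reports"], "homolog_drop_report.tsv"), config, "markers",
        )
        report.shapes["markers"] = f"{len(ovr)} OvR records, {len(cons.sets)} signatures"

    # ------------------------------------------------------------------ trajectory
    @_stage("trajectory", [os.path.join(d["tables"], "module_cluster_matrix.tsv")])
    def stage_trajectory():
        filtered = _load_bundle(os.path.join(d["counts"], "filtered"))
        ann = _read_tsv(ann_path)
        labels = _read_tsv(os.path.join(d["tables"], "clusters.tsv"))["cluster"].to_numpy()
        covar = _pct_mito(filtered) if config.normalize.regress_mito else None
        norm = normalize(filtered.rna, config.normalize.method, covariates=covar, theta=config.normalize.theta)
        resid = regress_cycle(norm, ann["S.Score"].to_numpy(), ann["G2M.Score"].to_numpy())
        pca = run_pca(resid, config.cluster.n_pcs, scale=config.trajectory.scale_pca)
        graph = knn_graph(pca, config.cluster.knn_k)
        pt = geodesic_pseudotime(graph, labels, config.trajectory.root_cluster, filtered.cell_barcodes, pca)
        ann["pseudotime"] = pt.pseudotime
        ann["cluster"] = labels
        _write_tsv(ann, ann_path, config, "trajectory")
        ac = autocorrelated_genes(graph, resid, filtered.gene_names, q_threshold=config.trajectory.q_threshold)
        _write_tsv(ac, os.path.join(d["tables"], "autocorrelation.tsv"), config, "trajectory")
        sig_genes = ac.loc[ac["significant"], "gene"].tolist()
        gm = gene_modules(
            resid, filtered.gene_names, sig_genes, labels,
            knn_k=config.trajectory.module_knn_k, resolution=config.trajectory.module_resolution,
            seed=config.stage_seed("trajectory"),
        )
        bio.write_gmt(
            os.path.join(d["genesets"], "gene_modules.gmt"),
            {f"module_{m}": genes for m, genes in gm.modules.items()},
        )
        _write_tsv(gm.module_cluster_matrix.rename_axis("module"),
                   os.path.join(d["tables"], "module_cluster_matrix.tsv"), config, "trajectory", index=True)
        report.shapes["trajectory"] = f"{len(sig_genes)} autocorrelated genes, {len(gm.modules)} modules"

    # ------------------------------------------------------------------ enrich
    @_stage("enrich", [os.path.join(d["tables"], "enrichment_grid.tsv")])
    def stage_enrich():
        signatures = bio.read_gmt(os.path.join(d["genesets"], "signatures_human.gmt"))
        usable = {k: v for k, v in signatures.items() if len(v) >= config.enrich.min_genes}
        bulk_cfg = BulkSimConfig(
            n_subtypes=config.enrich.n_subtypes,
            replicates_per_subtype=config.enrich.replicates_per_subtype,
            n_genes=config.enrich.n_genes,
            planted_lfc=config.enrich.planted_lfc,
            seed=config.stage_seed("enrich"),
        )
        counts, sample_map, truth = simulate_bulk_subtypes(bulk_cfg, usable)
        counts.rename_axis("sample").to_csv(os.path.join(d["tables"], "bulk_counts.tsv"), sep="\t")
        sample_map.rename_axis("sample").to_frame().to_csv(
            os.path.join(d["tables"], "bulk_sample_map.tsv"), sep="\t"
        )
        grid, row_rep, col_rep = build_enrichment_grid(
            counts, sample_map, usable,
            min_genes=config.enrich.min_genes, alpha=config.enrich.alpha,
            n_sim=config.enrich.n_sim, min_n=config.enrich.min_n,
            seed=config.stage_seed("enrich"),
        )
        _write_tsv(grid.scores.rename_axis("signature"),
                   os.path.join(d["tables"], "enrichment_grid.tsv"), config, "enrich", index=True)
        _write_tsv(row_rep.table, os.path.join(d["reports"], "shc_rows.tsv"), config, "enrich")
        _write_tsv(col_rep.table, os.path.join(d["reports"], "shc_cols.tsv"), config, "enrich")
        _write_tsv(
            pd.DataFrame(
                {"subtype": list(truth.planted_bulk_enrichment),
                 "planted_signature": list(truth.planted_bulk_enrichment.values())}
            ),
            os.path.join(d["reports"], "bulk_planting.tsv"), config, "enrich",
        )
        report.shapes["enrich"] = f"grid {grid.scores.shape}"

    for runner in (stage_simulate, stage_demux, stage_cellcycle, stage_cluster,
                   stage_markers, stage_trajectory, stage_enrich):
        runner()

    # persisted run report (deterministic: no timings)
    _write_tsv(
        pd.DataFrame(
            [{"stage": s, "shape": report.shapes.get(s, "")} for s in report.stages_run]
        ),
        os.path.join(d["reports"], "run_report.tsv"), config, "enrich",
    )
    config.to_yaml(os.path.join(d["reports"], "config_used.yaml"))
    return report


def _load_bundle(counts_dir: str):
    from .simulate import CountsBundle

    matrix, features, barcodes = bio.read_10x(counts_dir)
    is_gene = (features["type"] == bio.GENE_EXPRESSION).to_numpy()
    names = features["name"].tolist()
    gene_names = [n for n, g in zip(names, is_gene) if g]
    ab_names = [n for n, g in zip(names, is_gene) if not g]
    hto_names = [n for n in ab_names if n.startswith("HTO")]
    adt_names = [n for n in ab_names if not n.startswith("HTO")]
    name_row = {n: i for i, n in enumerate(names)}
    dense_ab = np.asarray(matrix[[name_row[n] for n in hto_names + adt_names]].todense())
    return CountsBundle(
        rna=matrix[is_gene],
        hto=dense_ab[: len(hto_names)],
        adt=dense_ab[len(hto_names):],
        gene_names=gene_names,
        cell_barcodes=barcodes,
        hashtag_names=hto_names,
        adt_names=adt_names,
        mito_mask=np.array([g.startswith("mt-") for g in gene_names]),
    )


def _pct_mito(bundle) -> np.ndarray:
    totals = np.asarray(bundle.rna.sum(axis=0)).ravel()
    mito = np.asarray(bundle.rna[bundle.mito_mask].sum(axis=0)).ravel()
    return np.divide(mito, totals, out=np.zeros_like(mito, dtype=float), where=totals > 0)
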