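# bcellflow

Multimodal single-cell analysis of B-cell development in mouse bone marrow,
packaged as a tested, reusable pipeline. It covers the full arc of a
CITE-seq-style study of developing B cells: demultiplexing hashed samples,
staging the cell cycle with the post-mitotic-G1 (G1PM) signature, clustering
with a differential-expression-guided merge rule, building consensus marker
signatures per developmental stage, ordering cells along a pseudotime
trajectory with Moran's-I gene modules, and asking which human B-ALL
(B-cell acute lymphoblastic leukemia) subtypes resemble which developmental
stage — with Monte-Carlo significance for the resulting hierarchical
clustering.

Every stage is exercised end-to-end on the package's own synthetic-data
generator, which plants known stages, cycle phases, doublets, and bulk
subtype enrichments, so the whole pipeline is testable without any external
download.

## Who this is for

Computational biologists who want the individual building blocks
(`clr_normalize`, `classify_hashtags`, `module_score`, `merge_by_de`,
`morans_i`, `shc_test`, ...) as documented, tested functions, and anyone who
wants to run the full pipeline on simulated or real 10x-style inputs.

## The core methods

- **Hashtag demultiplexing.** HTO counts are CLR-normalised
  (`ln((x+1)/geometric mean)`), cells are k-means-clustered in CLR space
  (k = n_hashtags + 1 by default; a k-scan is available), each hashtag's
  background negative-binomial distribution is fitted by the method of
  moments on its lowest-mean cluster, and a cell is positive for a hashtag
  when its raw count exceeds the background's 0.99 quantile. Exactly one
  positive → singlet; two or more → doublet; none → negative.
- **Cell-cycle staging.** Per-cell scores for the S, G2M, and G1PM programs
  (G1PM core: *Birc5, Myc, Mki67, Foxm1, Aurkb, Plk1* — G1 cells of rapid
  cyclers that retain G2/M transcripts) using bin-matched control
  subtraction; the maximal score labels the phase unless all three are
  negative, which defaults to G0/G1.
- **Cluster merging.** Leiden communities on a kNN graph of the top 30 PCs;
  any pair of clusters separated by fewer than 5 significant genes
  (two-sided rank-sum, |log2FC| ≥ 0.25, Bonferroni-adjusted p ≤ 0.01) is
  merged — fewest-DE pair first, iterating to convergence.
- **Consensus signatures.** The intersection of a one-vs-rest Wilcoxon
  marker table and an independent specificity ranking, then translated
  through a strictly one-to-one homolog map.
- **Trajectory.** Expression is regressed on the S and G2M scores
  (`~ S.Score + G2M.Score`), pseudotime is the graph-geodesic distance from
  the root cluster's medoid, trajectory-variable genes are selected by
  Moran's I (BH q < 0.05) and grouped into modules by community detection on
  their cluster-averaged profiles.
- **B-ALL enrichment.** Bulk replicates are summed per subtype,
  log2-CPM-transformed and z-scored per gene across subtypes; each
  signature's score per subtype is its genes' mean z. Both axes are
  clustered (Euclidean, complete linkage) and every dendrogram node is
  tested against a single-Gaussian Monte-Carlo null with family-wise error
  control.

See `docs/methods.md` for the model details, parameter defaults, and design
choices.

## Worked example

```bash
bcellflow all --outdir demo --seed 7
```

runs the whole pipeline on the bundled simulation (2000 cells × 1500 genes,
two hashtags, 10% doublets) and prints:

```
[done] simulate: rna (1500, 2000), hto (2, 2000), adt (6, 2000)
[done] demux: 2000 cells
[done] cellcycle: 1774 singlet cells after filtering
[done] cluster: 7 clusters (0 merges)
[done] markers: 526 OvR records, 7 signatures
[done] trajectory: 483 autocorrelated genes, 9 modules
[done] enrich: grid (7, 4)
```

Reading the output: of 2000 simulated droplets, 1774 pass demultiplexing
(HTO singlets only) and quality filtering; Leiden clustering at resolution
0.4 yields 7 clusters, none of which the DE-merge rule collapses; marker
discovery produces 7 cluster signatures which, scored against 4 simulated
bulk subtypes, give the enrichment grid in
`demo/tables/enrichment_grid.tsv`, e.g.

```
signature   subtype_1  subtype_2  subtype_3  subtype_4
cluster_0       1.48      -0.47      -0.55      -0.46
cluster_1      -0.53       1.48      -0.47      -0.48
...
```

— each planted signature scores highest (average z ≈ 1.5) in exactly the
subtype where it was planted. `demo/reports/shc_rows.tsv` and
`shc_cols.tsv` record the Monte-Carlo p-value for every dendrogram split.
Rerunning with the same seed reproduces every output byte-for-byte.

Each stage is also available as its own subcommand (`simulate`, `demux`,
`cellcycle`, `cluster`, `markers`, `trajectory`, `enrich`) over a shared
YAML config; completed stages are skipped unless `--force` is given.

## Real data

The pipeline reads standard 10x-style triplets (`matrix.mtx`,
`features.tsv` with an Antibody Capture type column, `barcodes.tsv`), GMT
gene sets, and TSV homolog maps, so deposited datasets can be substituted
for the simulation by placing them in the run directory's `counts/` folder
and toggling the `simulate` stage off.
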