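# Methods

This note documents the models, defaults, and design choices behind
bcellflow, and what the synthetic-data generator does and does not emulate.

## The synthetic CITE-seq generator

RNA counts are gamma–Poisson (negative binomial) with
`var = mu + mu^2/theta` and a gene-shared dispersion `theta = 10`. The mean
of gene *g* in cell *c* factorises as

```
mu_gc = baseline_g × 2^(stage effect) × 2^(phase effect) × depth_c
```

- **Baselines** are log-normal (sigma = 1.2), rescaled so the expected
  library size is 3000 counts — a typical 10x v3 median for primary mouse
  bone marrow. Mitochondrial genes (`mt-` prefix, 1% of genes) are pinned
  to 5% of the expected library.
- **Developmental structure.** Each cell carries a latent time
  `t ∈ [0, 1)`: its stage index plus, in the default *continuous* mode, a
  uniform within-stage jitter. Each of the 6 stages owns 40 program genes
  whose log2 effect is a Gaussian bump in latent time (height 2, width half
  a stage), so programs ramp up and down smoothly across neighbouring
  stages. Thirty additional *gradient* genes ramp monotonically (half up,
  half down) across the whole trajectory, emulating genes such as *Ebf1*
  or *Vpreb1* whose expression trends over development; they give the
  trajectory a global ordering axis. In *discrete* mode (`continuous:
  false`) all cells of a stage sit at the stage centre, making cells within
  a stage exchangeable — the right regime for testing the cluster-merge
  rule, where over-splitting must produce statistically identical halves.
- **Cell cycle.** Phases are drawn per cell (G0/G1 55%, S 20%, G2M 15%,
  G1PM 10%). S and G2M cells up-shift the packaged canonical phase lists by
  `phase_lfc = 2` (4-fold — cycle genes are among the most strongly
  modulated genes in real data); G1PM cells up-shift the six core G1PM
  genes plus 14 padding genes. Genes shared between the G2M list and the
  G1PM program (*Birc5*, *Mki67*, *Aurkb*) are elevated in both phases —
  exactly the carry-over that defines the post-mitotic G1 state. A 6-gene
  signature alone scores too noisily at this depth, hence the padding.
- **Hashtags and doublets.** A cell's own hashtag is NB with mean 300,
  the others mean 15. Doublets (10% of output cells) are formed by summing
  the RNA, HTO, and ADT columns of two singlets from *different* hashtags;
  same-hashtag doublets are not simulated because no truth-based HTO test
  could detect them. The two source columns are retained in the ground
  truth so the summation is testable exactly.
- **ADT.** Six surface markers (B220, CD19, CD93, CD25, IgM, CD43) with a
  stage×marker mean lookup that mimics their developmental windows (e.g.
  CD43 high early, IgM late); NB noise, no explicit antibody background
  beyond the low means themselves.

The bulk generator plants one signature per subtype (round-robin): the
signature's genes get `2^planted_lfc` (default 4-fold) higher means in that
subtype's replicates, on an otherwise shared log-normal baseline with an
expected depth of 10^6.

**What is not emulated:** ambient RNA, empty droplets, UMI collisions,
batch or chemistry effects, transcriptional bursting beyond NB noise,
same-hashtag doublets, read-level data. Passing tests therefore demonstrate
that each algorithm recovers the structure it targets under a clean NB
world; they do not certify performance against real-data artefacts like
ambient contamination.

## Demultiplexing

CLR normalisation is per hashtag across cells. Classification k-means
clusters cells in CLR space with `k = n_hashtags + 1` by default (a k-scan
over any range, e.g. 7–26, is available; the "best" k is left to the user
because cleanliness of a classification has no single criterion). The
background for each hashtag is the cluster with the *lowest* mean CLR for
it: the background must estimate ambient/non-expressing noise, and any
rule that pools "everything outside the top cluster" would sweep
cross-sample doublets — which carry signal-level counts for *both*
hashtags — into every background and inflate the moment fit beyond use.
The NB fit is method-of-moments with a Poisson fallback when the sample
variance does not exceed the mean; the positivity threshold is the fitted
0.99 quantile. Raising `q` can only shrink positive sets (monotone).

## Cell-cycle scoring

`module_score` subtracts bin-matched controls: genes are cut into 24
equal-frequency bins by average expression, and 100 controls per set gene
are drawn (seeded, without replacement) from the gene's bin, excluding the
set itself — exclusion makes the score respond exactly one-to-one to a
uniform shift of the set genes. A `raw_mean` flag disables control
subtraction for sensitivity analysis. Scores are computed on the
variance-stabilised (Pearson-residual) normalisation, which separates
baseline from induced expression far better than log counts for bimodal
cycle programs. Classification takes the maximal score, with exact ties
broken S > G2M > G1PM (fixed, documented; ties are measure-zero on real
data) and the all-negative default G0/G1.

## Filtering and normalisation

Filter order is fixed: cells detecting more than 300 genes → genes detected
in more than 3 cells → cells in the top 0.5% of mitochondrial fraction
(ties at the cutoff all removed). Two normalisations are provided:
`log_cpm_median` (`ln(1 + count/total × median total)`) and
`pearson_residual` — `(x − mu)/sqrt(mu + mu^2/theta)` with
`mu = gene share × cell share` of the grand total, fixed `theta = 100`,
clipped at ±sqrt(n_cells), with all-zero genes mapped to zero residuals.
The Pearson residual plays the variance-stabilising role of
regularised-NB transforms; it deliberately does not refit a per-gene
dispersion, which is the package's largest simplification relative to full
regularised-NB pipelines. The mitochondrial percentage can be regressed
out of the residuals (OLS per gene), mirroring its use as a nuisance
covariate.

## Embedding, clustering, merging

PCA centres (and optionally unit-scales) genes; component signs are fixed
so each loading's largest-magnitude entry is positive. For clustering the
genes are unit-scaled (the conventional choice); for the trajectory
embedding they are not, because Pearson residuals already carry calibrated
variances and unit scaling lets the hundreds of structureless genes drown
the trajectory signal, creating shortcut edges in the kNN graph that break
geodesic distances. The kNN graph (k = 20, Euclidean, union-symmetrised,
distances retained as edge attributes) feeds Leiden community detection
(RB-configuration, resolution 0.4, seeded, relabelled by decreasing size).

`merge_by_de` merges one pair per iteration — the pair with the fewest
significant genes (ties: smaller combined size, then lexicographic) — and
restarts until every pair has at least 5 significant genes. Sequential
merging makes the merge log a total order and avoids order-dependent
chained merges that simultaneous merging would permit. Significance is the
two-sided rank-sum test with Bonferroni correction over the genes tested
*within that comparison* (genes detected in at least one of the two
groups), |log2FC| ≥ 0.25 and adjusted p ≤ 0.01. Fold changes are
`log2((mean expm1 + 1e-9)/(mean expm1 + 1e-9))` on log-normalised data.

## Markers, consensus, homologs

The one-vs-rest table uses the same test and thresholds, keeps positive
fold changes by default, and ranks by adjusted p then |log2FC|. The second,
deliberately different ranking scores specificity — (fraction of in-cluster
cells expressing) × (the cluster's share of the gene's mean across
clusters) — and returns the top 25 per cluster. Consensus signatures union
each method's lists within a correspondence group (handling non-1:1 cluster
matches) and intersect across methods. Homolog translation keeps only
pairs that are one-to-one in both directions; everything else is dropped
and reported. `median_split` assigns values equal to the median to "low".

## Trajectory

Cycle regression is OLS per gene on intercept + S score + G2M score;
collinear scores drop the G2M covariate with a warning. Pseudotime is the
Dijkstra distance along the kNN graph (Euclidean edge lengths) from the
medoid of an explicitly chosen root cluster — a deterministic geodesic
stand-in for principal-graph trajectory ordering; the tested property is
that the ordering matches the planted trajectory, not the geometry of any
particular principal graph. Residual cycle signal in heavily cycling cells
can still create rare graph shortcuts; the clean-recovery benchmark is
therefore a quiescent simulation, and that limitation is inherited by any
real dataset dominated by cycling cells. Moran's I uses the analytic
normal-theory mean −1/(N−1) and variance with a one-sided (greater)
p-value — only positive autocorrelation means "varies along the
trajectory"; degenerate weight matrices (e.g. complete graphs, where I is
constant) return z = 0, p = 0.5. Gene selection applies Benjamini–Hochberg
at q < 0.05; constant genes are skipped and reported. Modules cluster
genes by their cluster-averaged, z-scored profiles (kNN under correlation
distance + Leiden), which is deterministic and testable, instead of a
2-D embedding of genes whose stochasticity would be untestable.

## Enrichment and clustering significance

The enrichment chain is: sum replicates per subtype → log2(1 + CPM) →
per-gene z across subtypes (sample SD; zero-variance genes zeroed with a
note) → per-signature mean z over the genes present (signatures with fewer
than 3 present genes are dropped). Z-scoring after aggregation treats each
subtype as one averaged sample; a flag could equally z-score across all
samples first, but the post-aggregation reading matches "an average sample
per subtype". Hierarchical clustering is Euclidean/complete on both axes.

The Monte-Carlo test statistic at a dendrogram node is its linkage height
divided by the mean pairwise distance of its leaves. Under a genuine
two-cluster split roughly half of all leaf pairs sit near the maximum
distance, pulling the ratio down toward 2; a single Gaussian — even a
strongly elongated one, which is exactly what the eigenvalue-preserving
null produces when the data are split — puts only its extreme pair near
the maximum, giving larger ratios. Small observed ratios are therefore the
rejection direction: `p = (1 + #{null ≤ observed})/(n_sim + 1)`. Null data
sets have the node's shape and a diagonal covariance equal to the node's
covariance eigenvalues, each floored at the median per-feature variance
(the floor stops near-zero sample eigenvalues from fabricating structure).
Family-wise error is controlled top-down: a node with `n_d` leaves is
tested at `alpha × (n_d − 1)/(N − 1)` and only the children of rejected
nodes are examined; nodes with fewer than `2 × min_n` leaves are reported
as "too small". `n_sim = 100` by default (p resolution 1/101; fewer than
20 simulations is rejected as too coarse). On 200 simulated 12×6 Gaussian
nulls the any-rejection rate sits inside the exact 95% binomial band
around the nominal 5%, and power over a 2/5/10-SD separation sweep is
monotone — those calibration checks are recomputed by the test suite and
the acceptance script, not quoted from anywhere.

## Pipeline and reproducibility

One global seed derives per-stage seeds as
`(seed × 1000003 + stage index) mod 2^31`, so stages rerun in isolation
reproducibly. Every output TSV carries a header comment with the package
version, stage seed, and a hash of the analysis parameters (the output
path is excluded from the hash). Reruns with the same configuration are
byte-identical; completed stages are skipped unless forced. Timing is
logged, never written into result files.

## Problem sizes

The bundled simulation is 2000 cells × 1500 genes (6 stages, 2 hashtags,
10% doublets); merge-restoration benchmarks use 1200 cells × 4 discrete
stages; the bulk benchmark is 4 subtypes × 3 replicates × 2000 genes; SHC
calibration uses 200 null 12×6 matrices at 99 simulations each. These
sizes make every property measurable at desk scale while keeping the full
suite fast; all recovery margins are wide at these sizes (F1 and ARI near
1), so scaling further up changes nothing qualitative.

## Known limitations

- The Pearson-residual normalisation fixes one dispersion for all genes
  rather than fitting regularised per-gene dispersions.
- Geodesic pseudotime has no branch detection and is sensitive to rare
  shortcut edges in heavily cycling populations.
- The SHC null estimates covariance eigenvalues from the node's own data;
  at very small nodes (4–6 leaves) the p-values are correspondingly noisy.
- The homolog mapper is deliberately conservative (strict 1:1), which
  discards genuinely informative many-to-one orthologs.
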