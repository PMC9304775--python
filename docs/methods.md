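# Methods

This note documents the statistical models, defaults, and design choices
behind `scmntb`, and what the synthetic-data tests do and do not demonstrate.

## Data model and containers

The root object is a sparse genes × cells integer `CountMatrix` with boolean
gene flags (`mito`, `reporter`) and per-cell metadata (including manual
exclusion annotations from capture-site imaging). Normalized values live in a
dense `ExpressionMatrix` of log2 CPM aligned to the filtered matrix. Gene
identifiers are case-sensitive strings; symbol↔ID mapping is the caller's
responsibility.

## Cell and gene quality control

Cell QC uses two metrics: number of genes detected (count > 0) and
mitochondrial read proportion. A cell is removed when its genes-detected
value deviates from the median by more than `n_mads` (default 3) MADs on
either side, or when its mitochondrial proportion exceeds the median by more
than `n_mads` MADs (upper tail only — a *low* mitochondrial fraction is not
pathological). The MAD is scaled by 1.4826 so it estimates σ for Gaussian
data; raw MAD is available via `QCThresholds(scaled_mad=False)`. When a
metric's MAD is zero (constant metric) no cell is an outlier by that metric;
this avoids emptying a dataset over a degenerate metric. Cells flagged
`excluded_manually` are always dropped.

Gene filtering drops all-zero genes and keeps genes with ≥ `min_count`
(default 10) counts in ≥ `min_cells` (default 3) cells. The fourth-quartile
filter (keep the top 25% of surviving genes by mean expression) is
implemented but off by default: the detection rule and the quartile rule are
two different published readings of the same step, so both are exposed and
chained only when `quartile_filter=True`. Filters operate on raw counts,
before any normalization.

## Size factors by pooling and deconvolution

Per-cell median-of-ratios estimators collapse at single-cell depths because
most gene-wise ratios hit zeros. The pooling estimator sidesteps this: cells
are placed on a ring ordered by library-size rank; for each pool size k
(default {20, 40, 60, 80, 100}, capped at n/2) and each window of k
consecutive cells, the pooled count vector is compared with the average
pseudo-cell (per-gene mean over all cells) by the median of gene-wise ratios
over genes whose pseudo-cell mean is ≥ `min_mean` (default 1 count). Each
window contributes the equation Σ_{c∈window} θ_c = pooled factor, and θ is
recovered by least squares.

The ring equations alone are rank-deficient (windows constrain only sums), so
the system is augmented with low-weight (0.1) per-cell rows tying θ_c to the
cell's plain library-size factor — the same device the pooling literature
uses. In the DE-free case these rows are exactly consistent with the pool
equations, so the noise-free scalar-multiple case is recovered to machine
precision; under differential expression their low weight leaves the pooled
median-ratio information dominant. Non-positive solutions are clipped to the
smallest positive estimate with a warning; factors are rescaled to unit mean.

CPM uses the effective library size θ_c × mean(total counts), which keeps the
factors and CPM mutually consistent and the values on the familiar
per-million scale. log2 CPM adds a pseudocount of 1 so zero counts map to 0.

## Variable-gene selection

Per-gene variance of log2 CPM is regressed on mean log2 CPM by LOESS
(local-linear, tricube weights; span 0.3 by default — the span is a free
parameter and configurable). The trend is floored at 1e-8 and acts as the
technical-noise estimate. The deviation test treats
(n−1)·variance/trend as χ²(n−1) (one-sided upper tail) — the standard
scaled-chi-square model for variance ratios; genes pass at ratio > 2 and
BH FDR < 5%. Constant genes get ratio 0 and p = 1.

The correlation filter computes Spearman ρ (mid-ranks for ties) for all
candidate pairs and compares against a pooled permutation null: one
distribution of |ρ| between `n_perm` (default 10,000) random rankings and a
fixed ranking, shared by all pairs; p = (1 + #{null ≥ |ρ|}) / (n_perm + 1),
BH-adjusted across pairs. A gene is kept iff it participates in at least one
pair with FDR ≤ 0.001 and |ρ| > 0.4. Fewer than 100 permutations is refused
(the null would be too coarse for the 0.001 gate). Note the granularity
interaction: with P pairs the smallest achievable adjusted p is roughly
P/(k·(n_perm+1)) for k tied significant pairs, so very small candidate sets
or low `n_perm` can make the 0.001 gate unreachable even for perfect
correlations.

The reporter transcript is excluded before variance fitting and never enters
the clustering feature set (it is retained in the matrix for validation).

## Clustering and iterative refinement

Cells are clustered on median-centered log2 CPM (each gene's median across
cells subtracted — the quantity a clustering heatmap displays) with Ward
linkage on Euclidean distances. For the tree cut, the constraint is a
minimum cluster size of 5. Among all cut levels k whose clusters each hold at
least 5 cells, the package selects the k with the widest merge-height
interval — the level at which the dendrogram most clearly separates. An
alternative rule, "the largest k satisfying the size constraint", was
implemented first and rejected: noise sub-splits of ≥ 5 cells essentially
always exist, so that rule returns the most granular admissible partition
rather than the natural one, and feeding its splinters into DE-driven
refinement amplified noise instead of converging. An explicit `n_clusters`
override remains available for reproduction runs. With fewer than
2 × min_cluster_size cells a single cluster is returned with a warning.

Refinement alternates: (1) Ward clustering on the current gene set; (2)
NB contrasts between every pair of clusters at the standard gates (≥ 2-fold
in either direction, FDR ≤ 0.05, detection rule); (3) the union of
significant genes becomes the next feature set. Iteration stops when the
partition repeats exactly (label-permutation-invariant comparison) or after
`max_iter` (default 10) rounds. If no gene distinguishes any pair of
clusters, the partition is considered unsupported and all cells collapse to
one cluster — this is what happens on single-population data. Manual
exclusion lists are applied before clustering; doublets are never inferred
automatically.

## Differential expression

The NB model has variance μ + αμ². Dispersions are method-of-moments
estimates, α̂ = (s² − m̄)/m̄², computed within groups on depth-normalized
counts, combined across groups by df-weighted average, clipped at zero, and
shrunk (weight 0.7) toward a LOESS trend over log mean expression; degenerate
genes take the trend value. This estimator is deliberately explicit and
self-contained — it is this package's own testing machinery, calibrated by
simulation (null type-I error ≈ 5% at n = 50/group, α = 0.1), not a
re-implementation of any external tool.

Contrasts test equality of group means with a likelihood-ratio test: group
means are fitted by per-gene Newton iterations on the log scale with
log effective-library-size offsets, and 2·(ll_alt − ll_null) is referred to
χ²(1). BH FDR is applied within each contrast (per-contrast FDR is also how
the results are reported downstream). The reported fold change is the ratio
of average CPM between the groups — not the GLM coefficient — with its log2;
a zero denominator gets a continuity constant of 0.5 CPM and a flag.
A significance call requires fold ≥ 2, FDR ≤ 0.05, and detection at ≥ 5 CPM
in ≥ 20% of cells of at least one compared group. One-vs-rest tables are
produced after merging clusters that annotate to the same type (the two
neuronal clusters in practice) and are sorted by FDR.

## Annotation, reporter validation, ligand-receptor edges

Cluster–type scores are the mean, over a type's marker genes, of cluster-mean
log2 CPM minus grand-mean log2 CPM; assignment is argmax with ties (within
1e-9) flagged ambiguous rather than silently broken. Missing marker genes are
skipped with a warning; a type with no resolvable markers is reported
unassignable.

Reporter validation runs a one-sided Wilcoxon rank-sum test of reporter
expression in each neuronal cluster against the pooled non-neuronal cells
(exact enumeration up to 8 per group without ties, normal approximation with
tie correction otherwise), BH-adjusts across neuronal clusters, and passes
iff every adjusted p ≤ 0.005.

Ligand–receptor edges are **descriptive**, not significance statements about
signaling: an edge S→R is emitted when the ligand passes the enrichment rule
in S (fold ≥ 2 and FDR ≤ 0.05 in its one-vs-rest table; or, in
"expressed-only" mode, detection at ≥ 5 CPM in ≥ 20% of cells) and the
receptor passes it in R. The default pair table covers the VEGF, TGFβ,
Delta-Notch and FGF inventories relevant to this tissue. Unresolvable gene
identifiers are reported, not silently dropped. Output order is
deterministic (pathway, sender, receiver, ligand, receptor).

## Imaging quantification

`percent_positive_area` estimates background with a rolling-ball of the given
radius (default 25), subtracts it (clipped at 0), and reports
100 × suprathreshold pixels / ROI pixels. Pixel-exact parity with any
particular GUI tool is a non-goal; the contract is the idempotent background
model. Whether thresholds apply to raw or background-subtracted intensities
is ambiguous in practice, so the background step can be disabled
(radius ≤ 0) and both settings are recorded by the caller. `volume_fraction`
is 100 × true voxels / ROI voxels; voxel dimensions cancel and are accepted
only for interface clarity. Families of Welch t tests (group SDs differ in
this kind of data) are controlled by the two-stage adaptive
Benjamini–Krieger–Yekutieli procedure at q = 1%: stage 1 runs BH at
q′ = q/(1+q) and estimates m0 as the non-rejections; stage 2 reruns BH at
q′·m/m0. The canonical definition (q′ in both stages) is used; it matches
statsmodels' `fdr_tsbky` and the literal-definition oracle in the tests.
Standard tests (Welch t, two-way ANOVA workflows) are called from scipy, not
re-derived.

## Synthetic data: what it emulates, what it does not

The generator draws NB counts with mean depth_c × rate_g, where each cell
type's rate vector is a shared log-normal baseline with its marker panel
multiplied by `marker_fold`, normalized to sum 1 so a cell's expected total
equals its depth. Defaults define the study conditions: five types — two
neuronal (60 + 45 cells) sharing a pan-neuronal panel (including *Fgf9*) with
small private panels, astrocytes (50, including *Fgfr3*), oligodendrocytes
(45), VACs (40) — 2000 genes, 8-fold marker enrichment, scalar dispersion
α = 0.1, log-normal depths (log-sd 0.3, median 50k counts), 13 mitochondrial
genes at ~4% of a healthy library, and a reporter transcript (~2% of a
neuron's library) restricted to neuronal profiles with zero leakage by
default (leakage is configurable because trace leakage occurs in real
microfluidic captures). Depth and dispersion of the real tissue are not
published at this granularity; the defaults are chosen so QC summaries look
like deep plate-based libraries while keeping the default matrix small
enough that the whole pipeline runs in seconds.

Artifacts: low-quality cells are existing cells binomially thinned to 20% of
their total with counts re-allocated (multinomial redraw) so the
mitochondrial fraction reaches ≥ 0.5 — totals stay interpretable; doublets
are exact element-wise sums of two distinct parents, appended with both
parent types recorded.

What passing tests show: the pipeline's inference is correct when the data
match its assumptions (NB counts, strong discrete types, markers that
co-vary). What they do not show: robustness to continuous trajectories,
batch effects across capture plates, ambient RNA, UMI-free amplification
noise beyond NB, or marker panels that overlap between types. Real-tissue
cluster counts and DE lists therefore still require the usual judgment.

## Numerical choices

- Variance-trend and dispersion-trend floors: 1e-8 and 0 respectively;
  LOESS outputs clipped to be nonnegative.
- Newton fits for group means: 50 iterations max, step clipped to ±5 on the
  log scale, convergence at 1e-10; α < 1e-8 switches to the Poisson
  log-likelihood.
- Ward cut ties: the smallest qualifying k wins only through the strict
  `>` gap comparison (first-found maximum); cluster labels are renumbered in
  order of first appearance so results are deterministic for a given input
  order, and partition comparisons are order-insensitive.
- All randomness (simulation, permutation null, artifact injection) flows
  from explicit integer seeds; the pipeline reuses its single config seed.

## Known limitations

- The NB testing machinery is a stand-in with its own calibration; it does
  not reproduce any external tool's output byte-for-byte.
- The pooled permutation null assumes exchangeable cells; strong depth
  gradients surviving normalization could distort it.
- The widest-gap tree cut assumes the dendrogram has one dominant scale of
  separation; hierarchically nested types at very different scales may need
  the explicit `n_clusters` override.
- Percent-area parity with GUI imaging tools is approximate by design.
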