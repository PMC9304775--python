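# scmntb

Single-cell transcriptomic analysis of the developing auditory brainstem —
specifically the medial nucleus of the trapezoid body (MNTB), a nucleus whose
nearly homogeneous principal neurons, compressed maturation timeline, and
giant calyx of Held synapse make it a standard model for neural circuit
formation. The package is aimed at researchers analyzing plate-based (e.g.
Fluidigm C1) scRNA-seq of such tissue: a few hundred deeply sequenced cells
spanning neurons, astrocytes, oligodendrocytes, and vascular-associated cells
(VACs), plus the imaging quantification statistics used to validate the
transcriptomic predictions at the protein level.

## What it does

Starting from a genes × cells integer count matrix, the pipeline runs:

1. **Cell QC** — outlier removal on genes-detected (two-sided) and
   mitochondrial read proportion (upper tail), at 3 median absolute
   deviations (MAD, scaled by 1.4826); manual doublet/dead-cell exclusions.
2. **Gene filtering** — drop all-zero genes; keep genes with ≥ 10 counts in
   ≥ 3 cells (optional fourth-quartile mean-expression filter).
3. **Normalization** — pooled-deconvolution size factors θ_c: cells on a ring
   ordered by library size, each window's pooled profile compared with the
   average pseudo-cell by the median of gene-wise ratios, the linear system
   Σ_{c∈pool} θ_c = pooled factor solved by least squares; expression as
   log2(CPM + 1) with CPM on the effective library size θ_c · mean(N).
4. **Variable genes** — LOESS fit of per-gene variance on mean log2 CPM;
   genes with variance/trend > 2 at FDR < 5% (χ² test,
   (n−1)·var/trend ~ χ²(n−1)); then a Spearman correlation filter
   (|ρ| > 0.4, FDR ≤ 0.001 with a pooled permutation null) keeps genes that
   co-vary across cells. The neuronal reporter transcript (tdTomato) is
   removed before this stage.
5. **Clustering** — Ward-linkage hierarchical clustering of cells on
   median-centered log2 CPM; the dendrogram is cut at its widest
   merge-height interval subject to a minimum cluster size of 5; then
   iterative refinement: all-pairs negative-binomial contrasts
   (≥ 2-fold, FDR ≤ 0.05, detected at ≥ 5 CPM in ≥ 20% of a cluster) define
   a new gene set, the cells are re-clustered, and iteration stops when the
   partition repeats.
6. **Differential expression** — NB likelihood-ratio contrasts (pairwise and
   one-vs-rest, with the two neuronal clusters merged) using trended,
   shrunken method-of-moments dispersions; fold changes are ratios of
   average CPM.
7. **Annotation & validation** — clusters scored against marker panels
   (neurons: *Calb1/Gabra5/Grin2a*; astrocytes: *Aldh1l1/Slc1a2/Slc1a3*;
   oligodendrocytes: *Cnp/Mbp/Sox10*; VACs: *Cldn5/Flt1/Pdgfrb*); a
   one-sided Wilcoxon rank-sum test checks that neuronal clusters carry the
   reporter transcript (adjusted p ≤ 0.005).
8. **Ligand–receptor directionality** — descriptive sender→receiver edges
   for VEGF, TGFβ, Delta-Notch and FGF pairs, emitted when the ligand is
   enriched in the sender cluster and the receptor in the receiver.
9. **Imaging statistics** — percent-positive area after rolling-ball
   background subtraction, volume fractions of label masks, and families of
   Welch t tests under the two-stage adaptive Benjamini–Krieger–Yekutieli
   FDR at q = 1%.

A synthetic-data module (`scmntb.simulate`) generates count matrices with
this exact structure — five cell types with planted markers, a
neuron-restricted reporter, mitochondrial genes, log-normal depths,
low-quality libraries and doublets — so every stage is tested against known
ground truth without downloading anything.

## Worked example

```bash
python examples/03_cluster_annotate_pipeline.py
```

prints, for the default 240-cell five-type synthetic sample:

```
cells kept: 236/240, genes kept: 1888/2000
clustering genes: 52 (from 56 HVGs)
clusters: {0: 59, 1: 44, 2: 50, 3: 44, 4: 39} (2 refinement rounds, converged=True)
adjusted Rand index vs ground truth: 1.000
  cluster 0: neuron (n=59)
  cluster 1: neuron (n=44)
  cluster 2: astrocyte (n=50)
  cluster 3: oligodendrocyte (n=44)
  cluster 4: VAC (n=39)
reporter (tdTomato) validation: passed=True, max adjusted p = 1.98e-39
FGF-pathway edges (sender -> receiver):
  neuron -> astrocyte: Fgf9/Fgfr3 (ligand fold 8.4, receptor fold 8.0)
```

The five recovered clusters match the planted types exactly (ARI 1.0), the
refinement loop converges in two rounds, both neuronal clusters pass the
reporter check, and the planted neuron→astrocyte Fgf9/Fgfr3 signaling
direction is recovered. The other scripts in `examples/` walk through QC
(`01`), normalization and variable-gene selection (`02`), the one-vs-rest
marker tables (`04`), and the imaging statistics (`05`).

Programmatic entry points: `scmntb.run_pipeline(counts, PipelineConfig(...))`
for the whole analysis, or the per-stage functions in `scmntb.qc`,
`scmntb.normalize`, `scmntb.hvg`, `scmntb.cluster`, `scmntb.de`,
`scmntb.annotate`, and `scmntb.quant`. Matrices read and write as Matrix
Market + TSV sidecars via `scmntb.io`.

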