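"""Ward hierarchical clustering of cells with iterative DE-driven refinement.

Cells are clustered on median-centered log2 CPM of the selected gene set using
Ward linkage on Euclidean distances. The tree is cut at the largest number of
clusters such that every cluster keeps at least ``min_cluster_size`` members.
Refinement alternates clustering with all-pairs differential expression: the
union of DE genes becomes the next feature set, and iteration stops when the
cell partition no longer changes (compared permutation-invariantly).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch

from .de import DEThresholds, estimate_dispersion, nb_contrast
from .matrix import CountMatrix, ExpressionMatrix, SizeFactors, ValidationError

__all__ = [
    "CenteredMatrix",
    "ClusteringResult",
    "median_center",
    "ward_cluster",
    "iterative_refine",
    "same_partition",
]


@dataclass
class CenteredMatrix:
    """Genes x cells log2 CPM with the per-gene median subtracted."""

    values: np.ndarray
    gene_ids: pd.Index
    cell_ids: pd.Index


@dataclass
class ClusteringResult:
    labels: np.ndarray  # per-cell integer cluster ids, 0-based
    cell_ids: pd.Index
    linkage: np.ndarray | None
    genes_used: list
    min_cluster_size: int
    iterations: list = field(default_factory=list)  # (gene list, labels) per round
    converged: bool = True

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))

    def cluster_sizes(self) -> dict:
        labs, counts = np.unique(self.labels, return_counts=True)
        return {int(l): int(c) for l, c in zip(labs, counts)}


def median_center(e: ExpressionMatrix, genes=None) -> CenteredMatrix:
    """Subtract each gene's median across cells (the heatmap quantity)."""
    sub = e if genes is None else e.subset_genes(list(genes))
    if sub.values.shape[0] == 0:
        raise ValidationError("empty gene set")
    med = np.median(sub.values, axis=1, keepdims=True)
    return CenteredMatrix(
        values=sub.values - med, gene_ids=sub.gene_ids, cell_ids=sub.cell_ids
    )


def _canonical_labels(raw: np.ndarray) -> np.ndarray:
    """Relabel clusters 0..k-1 in order of first appearance (deterministic)."""
    mapping, out = {}, np.empty_like(raw)
    nxt = 0
    for i, lab in enumerate(raw):
        if lab not in mapping:
            mapping[lab] = nxt
            nxt += 1
        out[i] = mapping[lab]
    return out


def ward_cluster(
    cm: CenteredMatrix,
    min_cluster_size: int = 5,
    n_clusters: int | None = None,
) -> ClusteringResult:
    """Ward-linkage clustering cut at the most granular admissible partition.

    With ``n_clusters`` unset, the tree is cut at the number of clusters whose
    merge-height interval is widest (the dendrogram's clearest separation),
    considering only cuts where every cluster keeps at least
    ``min_cluster_size`` members. If no such cut exists, all cells form one
    cluster.
    """
    X = cm.values.T  # cells x genes
    n = X.shape[0]
    if n < 2 * min_cluster_size and n_clusters is None:
        warnings.warn(
            f"only {n} cells (< 2 x min_cluster_size); returning a single cluster"
        )
        labels = np.zeros(n, dtype=int)
        return ClusteringResult(
            labels=labels, cell_ids=cm.cell_ids, linkage=None,
            genes_used=list(cm.gene_ids), min_cluster_size=min_cluster_size,
            iterations=[(list(cm.gene_ids), labels)],
        )
    Z = sch.linkage(X, method="ward")
    if n_clusters is not None:
        raw = sch.fcluster(Z, t=n_clusters, criterion="maxclust")
        labels = _canonical_labels(raw)
    else:
        heights = Z[:, 2]
        best_k, best_gap = None, -np.inf
        for k in range(2, n // min_cluster_size + 1):
            raw = sch.fcluster(Z, t=k, criterion="maxclust")
            labs, counts = np.unique(raw, return_counts=True)
            if len(labs) != k or counts.min() < min_cluster_size:
                continue
            # width of the threshold interval that yields exactly k clusters
            gap = heights[n - k] - heights[n - k - 1]
            if gap > best_gap:
                best_k, best_gap = k, gap
        if best_k is None:
            labels = np.zeros(n, dtype=int)
        else:
            labels = _canonical_labels(
                sch.fcluster(Z, t=best_k, criterion="maxclust")
            )
    return ClusteringResult(
        labels=labels, cell_ids=cm.cell_ids, linkage=Z,
        genes_used=list(cm.gene_ids), min_cluster_size=min_cluster_size,
        iterations=[(list(cm.gene_ids), labels)],
    )


def same_partition(a: np.ndarray, b: np.ndarray) -> bool:
    """Label-permutation-invariant partition equality (set-of-sets)."""
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        return False
    blocks_a = {frozenset(np.flatnonzero(a == lab)) for lab in np.unique(a)}
    blocks_b = {frozenset(np.flatnonzero(b == lab)) for lab in np.unique(b)}
    return blocks_a == blocks_b


def iterative_refine(
    m: CountMatrix,
    sf: SizeFactors,
    e: ExpressionMatrix,
    initial_genes,
    de_thresholds: DEThresholds | None = None,
    min_cluster_size: int = 5,
    max_iter: int = 10,
    exclude_cells=None,
) -> ClusteringResult:
    """Cluster, rerun all-pairs DE, recluster on the DE genes, to convergence.

    Each round: (1) Ward clustering on the current gene set; (2) pairwise NB
    contrasts between all current clusters at the configured gates (>= 2-fold,
    FDR <= 0.05, with the 5 CPM / 20% detection rule); (3) the union of
    significant genes (reporter excluded upstream) becomes the next gene set.
    Stops when the partition repeats or after ``max_iter`` rounds. Manual
    exclusions (``exclude_cells`` ids) are dropped before the first round.
    """
    de_thresholds = de_thresholds or DEThresholds(direction="both")
    if exclude_cells:
        keep = ~e.cell_ids.isin(list(exclude_cells))
        m = m.subset_cells(keep.to_numpy() if hasattr(keep, "to_numpy") else keep)
        e = ExpressionMatrix(e.values[:, np.asarray(keep)], e.gene_ids,
                             e.cell_ids[np.asarray(keep)], e.pseudocount)
        sf_vals = sf.factor[np.asarray(keep)]
        from .matrix import SizeFactors as _SF
        sf = _SF(sf_vals / sf_vals.mean(), m.cell_ids, sf.pool_sizes_used)

    genes = list(initial_genes)
    history = []
    prev_labels = None
    converged = False
    result = None
    for _ in range(max_iter):
        result = ward_cluster(median_center(e, genes), min_cluster_size)
        labels = result.labels
        history.append((list(genes), labels.copy()))
        if prev_labels is not None and same_partition(labels, prev_labels):
            converged = True
            break
        prev_labels = labels
        if result.n_clusters < 2:
            converged = True
            break
        disp = estimate_dispersion(m, sf, labels)
        de_genes: set = set()
        labs = np.unique(labels)
        for i, la in enumerate(labs):
            for lb in labs[i + 1:]:
                tab = nb_contrast(m, sf, labels, la, lb, disp, de_thresholds)
                de_genes |= set(tab.significant_genes())
        # the reporter transcript never enters the clustering feature set
        reporter = set(m.gene_ids[m.gene_flags["reporter"].to_numpy()])
        de_genes -= reporter
        if not de_genes:
            # no expression differences back any split: the cells are one group
            warnings.warn(
                "pairwise DE produced no genes; collapsing to a single cluster"
            )
            labels = np.zeros(len(result.labels), dtype=int)
            history.append((list(genes), labels))
            result = ClusteringResult(
                labels=labels, cell_ids=result.cell_ids, linkage=result.linkage,
                genes_used=list(genes), min_cluster_size=min_cluster_size,
            )
            converged = True
            break
        genes = [g for g in m.gene_ids if g in de_genes]
    return ClusteringResult(
        labels=result.labels,
        cell_ids=result.cell_ids,
        linkage=result.linkage,
        genes_used=history[-1][0],
        min_cluster_size=min_cluster_size,
        iterations=history,
        converged=converged,
    )
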