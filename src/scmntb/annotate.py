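"""Cluster annotation from marker genes, reporter validation, and directional
ligand-receptor summaries.

Clusters are scored against marker panels (mean marker log2 CPM above the
grand mean), validated with the neuron-restricted reporter transcript by a
one-sided Wilcoxon rank-sum test, and linked by descriptive sender->receiver
edges when a ligand passes an enrichment (or expression) rule in the sender
cluster and its receptor passes it in the receiver.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st

from .matrix import ExpressionMatrix, ValidationError
from .stats import bh_fdr

__all__ = [
    "MarkerSet",
    "DEFAULT_MARKER_SETS",
    "DEFAULT_LR_PAIRS",
    "AnnotationReport",
    "assign_cluster_types",
    "ReporterReport",
    "reporter_validation",
    "wilcoxon_rank_sum",
    "DirectedEdge",
    "ligand_receptor_directionality",
]


@dataclass
class MarkerSet:
    cell_type: str
    genes: tuple

    def __post_init__(self):
        if not self.genes:
            raise ValidationError(f"empty marker set for {self.cell_type!r}")
        self.genes = tuple(self.genes)


#: canonical brainstem marker panels used for cluster identification
DEFAULT_MARKER_SETS = [
    MarkerSet("neuron", ("Calb1", "Gabra5", "Grin2a")),
    MarkerSet("astrocyte", ("Aldh1l1", "Slc1a2", "Slc1a3")),
    MarkerSet("oligodendrocyte", ("Cnp", "Mbp", "Sox10")),
    MarkerSet("VAC", ("Cldn5", "Flt1", "Pdgfrb")),
]

#: ligand, receptor, pathway — the angiogenic/FGF inventories of this system
DEFAULT_LR_PAIRS = pd.DataFrame(
    [
        ("Vegfa", "Flt1", "VEGF"), ("Vegfa", "Kdr", "VEGF"),
        ("Vegfb", "Flt1", "VEGF"), ("Vegfc", "Flt4", "VEGF"),
        ("Tgfb2", "Tgfbr2", "TGFb"), ("Tgfb2", "Acvrl1", "TGFb"),
        ("Tgfb3", "Tgfbr2", "TGFb"), ("Gdf11", "Tgfbr1", "TGFb"),
        ("Dll1", "Notch1", "Notch"), ("Dll1", "Notch2", "Notch"),
        ("Dll4", "Notch1", "Notch"), ("Dll4", "Notch4", "Notch"),
        ("Jag1", "Notch1", "Notch"), ("Jag1", "Notch2", "Notch"),
        ("Jag1", "Notch3", "Notch"),
        ("Fgf9", "Fgfr3", "FGF"), ("Fgf9", "Fgfr2", "FGF"),
        ("Fgf1", "Fgfr1", "FGF"), ("Fgf2", "Fgfr1", "FGF"),
        ("Fgf10", "Fgfr2", "FGF"), ("Fgf18", "Fgfr3", "FGF"),
    ],
    columns=["ligand", "receptor", "pathway"],
)


@dataclass
class AnnotationReport:
    assignments: dict           # cluster -> cell type (argmax score)
    scores: pd.DataFrame        # clusters x types score matrix
    ambiguous: dict             # cluster -> list of tied types
    missing_genes: dict         # type -> genes absent from the matrix
    unassignable_types: list


def assign_cluster_types(
    e: ExpressionMatrix, labels, marker_sets=None, tie_tol: float = 1e-9
) -> AnnotationReport:
    """Score clusters against marker panels and assign by argmax.

    ``score(cluster, type)`` is the mean over the type's (present) marker genes
    of the cluster-mean log2 CPM minus the grand-mean log2 CPM. Ties within
    ``tie_tol`` are flagged ambiguous rather than silently broken.
    """
    marker_sets = marker_sets if marker_sets is not None else DEFAULT_MARKER_SETS
    labels = np.asarray(labels)
    clusters = list(pd.unique(labels))
    gene_set = set(e.gene_ids)
    missing, unassignable, usable = {}, [], {}
    for ms in marker_sets:
        absent = [g for g in ms.genes if g not in gene_set]
        present = [g for g in ms.genes if g in gene_set]
        if absent:
            missing[ms.cell_type] = absent
        if present:
            usable[ms.cell_type] = present
        else:
            unassignable.append(ms.cell_type)

    grand = e.values.mean(axis=1)
    scores = pd.DataFrame(index=pd.Index(clusters, name="cluster"),
                          columns=list(usable), dtype=float)
    for ct, genes in usable.items():
        idx = [e.gene_ids.get_loc(g) for g in genes]
        delta = e.values[idx, :] - grand[idx, None]
        for cl in clusters:
            scores.loc[cl, ct] = delta[:, labels == cl].mean()

    assignments, ambiguous = {}, {}
    for cl in clusters:
        row = scores.loc[cl]
        best = row.max()
        tied = list(row.index[row >= best - tie_tol])
        assignments[cl] = tied[0]
        if len(tied) > 1:
            ambiguous[cl] = tied
    return AnnotationReport(
        assignments=assignments, scores=scores, ambiguous=ambiguous,
        missing_genes=missing, unassignable_types=unassignable,
    )


def wilcoxon_rank_sum(x, y, alternative: str = "greater",
                      exact_max_n: int = 8) -> float:
    """One-sided Wilcoxon rank-sum p-value.

    Exact enumeration below ``exact_max_n`` per group (no ties), normal
    approximation with tie correction otherwise.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if len(x) <= exact_max_n and len(y) <= exact_max_n and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(st.mannwhitneyu(x, y, alternative=alternative, method=method).pvalue)


@dataclass
class ReporterReport:
    p_values: dict      # neuron cluster -> raw p
    adjusted: dict      # neuron cluster -> BH-adjusted p
    alpha: float
    passed: bool


def reporter_validation(
    e: ExpressionMatrix, labels, reporter_gene: str, neuron_clusters,
    alpha: float = 0.005,
) -> ReporterReport:
    """Wilcoxon validation that neuron clusters carry the reporter transcript.

    Each neuron cluster is tested one-sided (greater) against the pooled
    non-neuron cells; p-values are BH-adjusted across the neuron clusters and
    the check passes iff every adjusted p <= alpha.
    """
    if reporter_gene not in set(e.gene_ids):
        raise ValidationError(f"reporter gene {reporter_gene!r} absent")
    labels = np.asarray(labels)
    neuron_clusters = list(neuron_clusters)
    expr = e.loc(reporter_gene)
    non_neuron = ~np.isin(labels, neuron_clusters)
    if non_neuron.sum() == 0 or not neuron_clusters:
        raise ValidationError("need both neuron and non-neuron cells")
    raw = {
        cl: wilcoxon_rank_sum(expr[labels == cl], expr[non_neuron], "greater")
        for cl in neuron_clusters
    }
    adj_vals = bh_fdr(list(raw.values()))
    adjusted = dict(zip(raw, adj_vals))
    return ReporterReport(
        p_values=raw, adjusted=adjusted, alpha=alpha,
        passed=bool(all(v <= alpha for v in adjusted.values())),
    )


@dataclass
class DirectedEdge:
    sender: object
    receiver: object
    ligand: str
    receptor: str
    pathway: str
    ligand_fold: float
    ligand_fdr: float
    receptor_fold: float
    receptor_fdr: float


def _passes(table: pd.DataFrame, gene: str, mode: str,
            fold_min: float, fdr_max: float,
            detect_cpm_frac: float) -> bool:
    if gene not in table.index:
        return False
    row = table.loc[gene]
    if mode == "expressed":
        return bool(row["detect_frac_A"] >= detect_cpm_frac)
    return bool(row["fold_change"] >= fold_min and row["fdr"] <= fdr_max)


def ligand_receptor_directionality(
    de_tables: dict,
    lr_pairs: pd.DataFrame | None = None,
    mode: str = "enriched",
    fold_min: float = 2.0,
    fdr_max: float = 0.05,
    detect_frac: float = 0.2,
):
    """Descriptive sender->receiver edges from one-vs-rest DE tables.

    ``de_tables`` maps cluster/report-group name to its one-vs-rest DETable.
    An edge (S -> R, ligand, receptor) is emitted iff the ligand passes the
    rule in S and the receptor passes it in R. ``mode='enriched'`` requires
    fold >= fold_min and FDR <= fdr_max; ``mode='expressed'`` requires
    detection at >= 5 CPM in >= detect_frac of the cluster's cells. Output is
    deterministic: ordered by (pathway, sender, receiver, ligand, receptor).
    Rows whose genes cannot be resolved in any table are flagged, not silently
    dropped.
    """
    if mode not in ("enriched", "expressed"):
        raise ValidationError("mode must be 'enriched' or 'expressed'")
    lr_pairs = DEFAULT_LR_PAIRS if lr_pairs is None else lr_pairs
    tables = {k: v.table for k, v in de_tables.items()}
    known = set()
    for t in tables.values():
        known |= set(t.index)

    edges, unresolved = [], []
    for _, row in lr_pairs.iterrows():
        lig, rec, pw = row["ligand"], row["receptor"], row["pathway"]
        if lig not in known or rec not in known:
            unresolved.append((lig, rec, pw))
            continue
        for s, ts in tables.items():
            if not _passes(ts, lig, mode, fold_min, fdr_max, detect_frac):
                continue
            for r, tr in tables.items():
                if s == r:
                    continue
                if not _passes(tr, rec, mode, fold_min, fdr_max, detect_frac):
                    continue
                edges.append(DirectedEdge(
                    sender=s, receiver=r, ligand=lig, receptor=rec, pathway=pw,
                    ligand_fold=float(ts.loc[lig, "fold_change"]),
                    ligand_fdr=float(ts.loc[lig, "fdr"]),
                    receptor_fold=float(tr.loc[rec, "fold_change"]),
                    receptor_fdr=float(tr.loc[rec, "fdr"]),
                ))
    edges.sort(key=lambda d: (d.pathway, str(d.sender), str(d.receiver),
                              d.ligand, d.receptor))
    return edges, unresolved
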