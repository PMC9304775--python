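"""End-to-end orchestration: QC -> gene filter -> normalization -> HVG ->
correlation filter -> iterative clustering -> one-vs-rest DE (with neuronal
merge) -> annotation -> reporter validation -> ligand-receptor edges.

All scalar thresholds live in :class:`PipelineConfig` with the workflow's
published defaults; every random stage draws from the single config seed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate as ann
from . import cluster as cl
from . import de as de_mod
from . import hvg as hvg_mod
from . import normalize as norm
from . import qc as qc_mod
from .matrix import CountMatrix, ValidationError

log = logging.getLogger("scmntb")

__all__ = ["PipelineConfig", "RunReport", "run_pipeline"]


@dataclass
class PipelineConfig:
    # cell QC
    n_mads: float = 3.0
    # gene filter
    min_count: int = 10
    min_cells: int = 3
    quartile_filter: bool = False
    # normalization
    pool_sizes: list | None = None
    min_mean: float = 1.0
    pseudocount: float = 1.0
    # HVG
    loess_span: float = 0.3
    variance_fold: float = 2.0
    variance_fdr: float = 0.05
    rho_min: float = 0.4
    corr_fdr: float = 0.001
    n_perm: int = 10_000
    # clustering
    min_cluster_size: int = 5
    max_iter: int = 10
    exclude_cells: list = field(default_factory=list)
    # DE gates
    de_fold: float = 2.0
    de_fdr: float = 0.05
    detect_cpm: float = 5.0
    detect_frac: float = 0.2
    # annotation / validation
    reporter_alpha: float = 0.005
    # imaging stats
    bky_q: float = 0.01
    seed: int = 0

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


@dataclass
class RunReport:
    config: PipelineConfig
    n_cells_input: int = 0
    n_cells_kept: int = 0
    n_genes_input: int = 0
    n_genes_kept: int = 0
    n_hvg: int = 0
    n_clustering_genes: int = 0
    cluster_sizes: dict = field(default_factory=dict)
    n_refine_rounds: int = 0
    converged: bool = False
    annotation: object = None
    reporter: object = None
    de_tables: dict = field(default_factory=dict)
    edges: list = field(default_factory=list)
    unresolved_lr: list = field(default_factory=list)
    clustering: object = None
    expression: object = None
    size_factors: object = None
    qc_keep: np.ndarray | None = None
    filtered: CountMatrix | None = None

    def cluster_types(self) -> dict:
        return dict(self.annotation.assignments) if self.annotation else {}


def _persist(outdir, name, df):
    if outdir is None:
        return
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df.to_csv(outdir / name, sep="\t")


def run_pipeline(
    m: CountMatrix,
    config: PipelineConfig | None = None,
    marker_sets=None,
    lr_pairs=None,
    outdir=None,
) -> RunReport:
    """Run the full analysis on a count matrix and return a RunReport.

    Stages log their tallies; with ``outdir`` set, intermediates are persisted
    as TSV. Raises with the failing stage's name on error.
    """
    config = config or PipelineConfig()
    report = RunReport(config=config, n_cells_input=m.n_cells, n_genes_input=m.n_genes)
    stage = "cell_qc"
    try:
        metrics = qc_mod.compute_cell_qc(m)
        excluded = (
            m.cell_meta["excluded_manually"].to_numpy()
            if "excluded_manually" in m.cell_meta
            else None
        )
        keep_cells = qc_mod.mad_outlier_filter(
            metrics, qc_mod.QCThresholds(n_mads=config.n_mads), excluded
        )
        report.qc_keep = keep_cells
        mc = m.subset_cells(keep_cells)
        report.n_cells_kept = mc.n_cells
        log.info("cell_qc: %d/%d cells kept", mc.n_cells, m.n_cells)
        _persist(outdir, "cell_qc.tsv", metrics.assign(kept=keep_cells))

        stage = "gene_filter"
        keep_genes = qc_mod.filter_genes(
            mc, config.min_count, config.min_cells, config.quartile_filter
        )
        mf = mc.subset_genes(keep_genes)
        report.n_genes_kept = mf.n_genes
        report.filtered = mf
        log.info("gene_filter: %d/%d genes kept", mf.n_genes, m.n_genes)

        stage = "normalization"
        sf = norm.deconvolution_size_factors(mf, config.pool_sizes, config.min_mean)
        e = norm.log2_cpm(mf, sf, config.pseudocount)
        report.size_factors = sf
        report.expression = e
        _persist(outdir, "size_factors.tsv",
                 pd.DataFrame({"factor": sf.factor}, index=mf.cell_ids))

        stage = "hvg_selection"
        # the reporter transcript never enters HVG selection or clustering
        reporter_mask = mf.gene_flags["reporter"].to_numpy()
        e_noreporter = e.subset_genes(~reporter_mask)
        fit = hvg_mod.fit_variance_trend(e_noreporter, config.loess_span)
        hvgs = hvg_mod.select_variable_genes(
            fit, config.variance_fold, config.variance_fdr
        )
        report.n_hvg = len(hvgs)
        _persist(outdir, "variance_fit.tsv", fit.table)
        log.info("hvg_selection: %d variable genes", len(hvgs))
        if len(hvgs) < 2:
            raise ValidationError("fewer than 2 variable genes selected")

        stage = "correlation_filter"
        corr = hvg_mod.correlation_filter(
            e_noreporter, hvgs, config.rho_min, config.corr_fdr,
            config.n_perm, seed=config.seed,
        )
        genes0 = corr.kept_genes
        report.n_clustering_genes = len(genes0)
        log.info("correlation_filter: %d genes retained", len(genes0))
        if len(genes0) < 2:
            raise ValidationError("correlation filter removed all genes")

        stage = "iterative_clustering"
        de_thr = de_mod.DEThresholds(
            fold_min=config.de_fold, fdr_max=config.de_fdr,
            detect_cpm=config.detect_cpm, detect_frac=config.detect_frac,
            direction="both",
        )
        clustering = cl.iterative_refine(
            mf, sf, e, genes0, de_thr,
            min_cluster_size=config.min_cluster_size,
            max_iter=config.max_iter,
            exclude_cells=config.exclude_cells,
        )
        report.clustering = clustering
        report.cluster_sizes = clustering.cluster_sizes()
        report.n_refine_rounds = len(clustering.iterations)
        report.converged = clustering.converged
        log.info("clustering: %s, converged=%s",
                 report.cluster_sizes, clustering.converged)
        _persist(outdir, "clusters.tsv",
                 pd.DataFrame({"cluster": clustering.labels},
                              index=clustering.cell_ids))

        stage = "annotation"
        labels = clustering.labels
        annot = ann.assign_cluster_types(e, labels, marker_sets)
        report.annotation = annot
        _persist(outdir, "annotation_scores.tsv", annot.scores)

        stage = "one_vs_rest_de"
        merge_map = dict(annot.assignments)  # same-type clusters merge (N1+N2)
        thr_up = dataclasses.replace(de_thr, direction="up")
        tables = de_mod.one_vs_rest_tables(mf, sf, labels, merge_map,
                                           thresholds=thr_up)
        report.de_tables = tables
        if outdir is not None:
            for name, tab in tables.items():
                _persist(outdir, f"de_{name}_vs_rest.tsv", tab.table)

        stage = "reporter_validation"
        reporter_genes = list(mf.gene_ids[reporter_mask])
        neuron_clusters = [c for c, t in annot.assignments.items() if t == "neuron"]
        if reporter_genes and neuron_clusters:
            report.reporter = ann.reporter_validation(
                e, labels, reporter_genes[0], neuron_clusters,
                alpha=config.reporter_alpha,
            )

        stage = "ligand_receptor"
        edges, unresolved = ann.ligand_receptor_directionality(
            tables, lr_pairs, mode="enriched",
            fold_min=config.de_fold, fdr_max=config.de_fdr,
            detect_frac=config.detect_frac,
        )
        report.edges = edges
        report.unresolved_lr = unresolved
        if outdir is not None and edges:
            _persist(outdir, "lr_edges.tsv",
                     pd.DataFrame([dataclasses.asdict(ed) for ed in edges]))
        log.info("ligand_receptor: %d edges", len(edges))
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err
    return report
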