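"""Cell and gene quality control.

Cells are filtered on two metrics — number of expressed genes and
mitochondrial read proportion — by a 3-MAD outlier rule (two-sided on genes
detected, upper tail only on mitochondrial fraction). Genes are filtered by a
detection threshold (default: at least 10 counts in at least 3 cells) with an
optional fourth-quartile mean-expression filter. All filters operate on raw
counts; normalization comes after.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import CountMatrix, ValidationError

__all__ = ["QCThresholds", "compute_cell_qc", "mad_outlier_filter", "filter_genes", "mad"]

#: consistency constant making the MAD estimate sigma for Gaussian data
MAD_SCALE = 1.4826


@dataclass
class QCThresholds:
    n_mads: float = 3.0
    genes_detected_two_sided: bool = True
    mito_upper_only: bool = True
    scaled_mad: bool = True  # multiply raw MAD by 1.4826

    def __post_init__(self):
        if self.n_mads <= 0:
            raise ValidationError("n_mads must be positive")


def mad(x: np.ndarray, scaled: bool = True) -> float:
    """Median absolute deviation, optionally scaled by 1.4826."""
    x = np.asarray(x, dtype=float)
    m = float(np.median(np.abs(x - np.median(x))))
    return m * MAD_SCALE if scaled else m


def compute_cell_qc(m: CountMatrix) -> pd.DataFrame:
    """Per-cell QC metrics: genes detected, total counts, mito proportion.

    Cells with zero total counts get mito_proportion 0 and are flagged
    ``degenerate``.
    """
    if m.n_cells == 0 or m.n_genes == 0:
        raise ValidationError("empty count matrix")
    counts = m.counts
    genes_detected = np.asarray((counts > 0).sum(axis=0)).ravel()
    total = m.total_counts().astype(float)
    mito_mask = m.gene_flags["mito"].to_numpy()
    if not mito_mask.any():
        warnings.warn("no mitochondrial genes flagged; mito_proportion set to 0")
        mito_counts = np.zeros(m.n_cells)
    else:
        mito_counts = np.asarray(counts[mito_mask, :].sum(axis=0)).ravel().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_prop = np.where(total > 0, mito_counts / np.maximum(total, 1e-300), 0.0)
    return pd.DataFrame(
        {
            "genes_detected": genes_detected,
            "total_counts": total,
            "mito_proportion": mito_prop,
            "degenerate": total == 0,
        },
        index=m.cell_ids,
    )


def mad_outlier_filter(
    metrics: pd.DataFrame,
    thresholds: QCThresholds | None = None,
    excluded_manually: np.ndarray | None = None,
) -> np.ndarray:
    """Boolean keep-mask over cells from the MAD outlier rule.

    A cell is dropped iff its genes-detected value sits more than
    ``n_mads`` MADs from the median (both tails by default), or its
    mitochondrial proportion exceeds the median by more than ``n_mads`` MADs
    (upper tail only), or it is flagged for manual exclusion. A metric whose
    MAD is zero produces no outliers on that metric.
    """
    thresholds = thresholds or QCThresholds()
    if len(metrics) < 2:
        raise ValidationError("need at least 2 cells for outlier filtering")
    genes = metrics["genes_detected"].to_numpy(dtype=float)
    mito = metrics["mito_proportion"].to_numpy(dtype=float)

    def outliers(x, two_sided):
        med = np.median(x)
        m = mad(x, scaled=thresholds.scaled_mad)
        if m == 0:
            return np.zeros_like(x, dtype=bool)
        dev = x - med
        if two_sided:
            return np.abs(dev) > thresholds.n_mads * m
        return dev > thresholds.n_mads * m

    drop = outliers(genes, thresholds.genes_detected_two_sided)
    drop |= outliers(mito, two_sided=not thresholds.mito_upper_only)
    if excluded_manually is not None:
        drop |= np.asarray(excluded_manually, dtype=bool)
    return ~drop


def filter_genes(
    m: CountMatrix,
    min_count: int = 10,
    min_cells: int = 3,
    quartile_filter: bool = False,
) -> np.ndarray:
    """Boolean keep-mask over genes.

    Drops all-zero genes; keeps a gene iff it has ``count >= min_count`` in at
    least ``min_cells`` cells. With ``quartile_filter``, additionally keeps only
    survivors in the top 25% of mean expression.
    """
    if min_cells > m.n_cells:
        raise ValidationError(
            f"min_cells={min_cells} exceeds number of cells ({m.n_cells})"
        )
    counts = m.counts
    n_above = np.asarray((counts >= min_count).sum(axis=1)).ravel()
    nonzero = np.asarray((counts > 0).sum(axis=1)).ravel() > 0
    keep = nonzero & (n_above >= min_cells)
    if quartile_filter and keep.any():
        means = np.asarray(counts.mean(axis=1)).ravel()
        cutoff = np.quantile(means[keep], 0.75)
        keep = keep & (means >= cutoff)
    return keep
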