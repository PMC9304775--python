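"""Size-factor normalization by pooling/deconvolution, and log2 CPM.

Per-cell size factors are estimated with a pooling strategy: cells are laid on
a ring ordered by library size; for each pool size, every window of
consecutive cells is summed and compared with an average pseudo-cell by the
median of gene-wise ratios. Each window contributes one linear equation
(the pooled factor equals the sum of the member cells' factors), and the
per-cell factors are recovered by least squares. Pooling damps the
zero-inflation that makes per-cell median-ratio estimators unstable at
single-cell depths.

CPM uses an effective library size ``factor_c * mean(total counts)`` so the
factors and CPM stay mutually consistent and CPM keeps its per-million scale.
"""

from __future__ import annotations

import warnings

import numpy as np

from .matrix import CountMatrix, ExpressionMatrix, SizeFactors, ValidationError

__all__ = ["deconvolution_size_factors", "log2_cpm", "cpm", "DEFAULT_POOL_SIZES"]

DEFAULT_POOL_SIZES = (20, 40, 60, 80, 100)
#: weight of the per-cell library-size rows that make the pooled system full rank
_ANCHOR_WEIGHT = 0.1


def deconvolution_size_factors(
    m: CountMatrix,
    pool_sizes=None,
    min_mean: float = 1.0,
) -> SizeFactors:
    """Pooled deconvolution size factors, rescaled to unit mean.

    Parameters
    ----------
    m
        Count matrix, genes already filtered.
    pool_sizes
        Ring-window sizes; defaults to ``{20, 40, 60, 80, 100}`` capped at
        ``n_cells // 2`` (at least one window size is always used).
    min_mean
        Genes whose pseudo-cell mean count falls below this are excluded from
        the gene-wise ratio medians.
    """
    n = m.n_cells
    if n < 2:
        raise ValidationError("need at least 2 cells")
    if pool_sizes is None:
        cap = max(n // 2, 1)
        pool_sizes = [k for k in DEFAULT_POOL_SIZES if k <= cap] or [cap]
    pool_sizes = sorted(set(int(k) for k in pool_sizes))
    if pool_sizes[0] < 1 or pool_sizes[-1] > n:
        raise ValidationError(f"pool sizes must lie in [1, {n}]")

    counts = m.dense().astype(float)
    total = counts.sum(axis=0)
    ref = counts.mean(axis=1)  # average pseudo-cell
    use = ref >= min_mean
    if not use.any():
        raise ValidationError("pseudo-cell has no genes above min_mean")

    # cells sit on a ring ordered by library-size rank; windows wrap around
    ring = np.argsort(total, kind="stable")

    rows, rhs = [], []
    ref_use = ref[use]
    ringed = counts[np.ix_(use, ring)]
    kmax = pool_sizes[-1]
    ext = np.concatenate([ringed, ringed[:, :kmax]], axis=1)
    csum = np.concatenate(
        [np.zeros((ringed.shape[0], 1)), np.cumsum(ext, axis=1)], axis=1
    )
    for k in pool_sizes:
        starts = np.arange(n)
        pooled = csum[:, starts + k] - csum[:, starts]  # genes x windows
        ratios = np.median(pooled / ref_use[:, None], axis=0)
        for start in range(n):
            members = ring[(start + np.arange(k)) % n]
            row = np.zeros(n)
            row[members] = 1.0
            rows.append(row)
            rhs.append(ratios[start])
    # low-weight anchor rows: tie each factor to its library-size factor.
    # Keeps the ring system full rank; exact when composition is DE-free.
    lib_factor = total / total.mean() if total.mean() > 0 else np.ones(n)
    for c in range(n):
        row = np.zeros(n)
        row[c] = _ANCHOR_WEIGHT
        rows.append(row)
        rhs.append(_ANCHOR_WEIGHT * lib_factor[c])

    A = np.asarray(rows)
    b = np.asarray(rhs)
    theta, *_ = np.linalg.lstsq(A, b, rcond=None)
    if (theta <= 0).any():
        positive = theta[theta > 0]
        if positive.size == 0:
            raise ValidationError("all deconvolution factors non-positive")
        warnings.warn(
            f"{int((theta <= 0).sum())} non-positive size factors clipped"
        )
        theta = np.where(theta <= 0, positive.min(), theta)
    theta = theta / theta.mean()
    return SizeFactors(
        factor=theta,
        cell_ids=m.cell_ids,
        pool_sizes_used=list(pool_sizes),
        rescaled_to_unit_mean=True,
    )


def _effective_library(m: CountMatrix, sf: SizeFactors) -> np.ndarray:
    if not np.array_equal(np.asarray(sf.cell_ids), np.asarray(m.cell_ids)):
        raise ValidationError("size factors not aligned to cells")
    mean_total = m.total_counts().mean()
    if mean_total <= 0:
        raise ValidationError("empty library")
    return sf.factor * mean_total


def cpm(m: CountMatrix, sf: SizeFactors) -> np.ndarray:
    """Counts per million on the effective library size (dense genes x cells)."""
    eff = _effective_library(m, sf)
    return m.dense() / eff[None, :] * 1e6


def log2_cpm(
    m: CountMatrix, sf: SizeFactors, pseudocount: float = 1.0
) -> ExpressionMatrix:
    """log2(CPM + pseudocount); zero counts map to log2(pseudocount)."""
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be positive")
    values = np.log2(cpm(m, sf) + pseudocount)
    return ExpressionMatrix(
        values=values, gene_ids=m.gene_ids, cell_ids=m.cell_ids, pseudocount=pseudocount
    )
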