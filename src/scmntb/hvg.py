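"""Highly variable gene selection.

Three stages: (1) a LOESS fit of per-gene variance against mean log2 CPM
gives a technical-noise trend; (2) genes whose variance exceeds the trend more
than twofold at FDR < 5% (scaled chi-square test) become candidates; (3) a
Spearman correlation filter with a pooled permutation null keeps only
candidates that co-vary with at least one other candidate (FDR <= 0.001 and
|rho| > 0.4), removing genes that are variable but uncorrelated noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
from statsmodels.nonparametric.smoothers_lowess import lowess

from .matrix import ExpressionMatrix, ValidationError
from .stats import bh_fdr

__all__ = [
    "VarianceFit",
    "CorrelationResult",
    "fit_variance_trend",
    "select_variable_genes",
    "correlation_filter",
]

_TREND_FLOOR = 1e-8


@dataclass
class VarianceFit:
    table: pd.DataFrame  # per-gene: mean, variance, trend, ratio, p, fdr
    loess_span: float
    n_cells: int

    def __getitem__(self, col):
        return self.table[col]


@dataclass
class CorrelationResult:
    pairs: pd.DataFrame  # gene_a, gene_b, rho, p, fdr
    kept_genes: list = field(default_factory=list)
    n_perm: int = 0


def fit_variance_trend(e: ExpressionMatrix, span: float = 0.3) -> VarianceFit:
    """LOESS mean-variance trend with a scaled chi-square deviation test.

    The trend is a local-linear tricube-weighted fit of variance on mean;
    ``ratio = variance / trend`` (trend floored at a small epsilon) and the
    one-sided p-value comes from ``(n-1) * ratio ~ chi2(n-1)``. Constant genes
    get ratio 0 and p = 1.
    """
    n_genes, n = e.values.shape
    if n_genes < 20:
        raise ValidationError("need at least 20 genes to fit a trend")
    if n < 3:
        raise ValidationError("need at least 3 cells")
    means = e.values.mean(axis=1)
    variances = e.values.var(axis=1, ddof=1)
    fitted = lowess(variances, means, frac=span, return_sorted=False)
    trend = np.maximum(fitted, _TREND_FLOOR)
    ratio = np.where(variances > 0, variances / trend, 0.0)
    p = np.where(variances > 0, st.chi2.sf((n - 1) * ratio, df=n - 1), 1.0)
    table = pd.DataFrame(
        {
            "mean": means,
            "variance": variances,
            "trend": trend,
            "ratio": ratio,
            "p": p,
            "fdr": bh_fdr(p),
        },
        index=e.gene_ids,
    )
    return VarianceFit(table=table, loess_span=span, n_cells=n)


def select_variable_genes(
    fit: VarianceFit, fold: float = 2.0, fdr_max: float = 0.05
) -> list:
    """Genes with variance ratio > fold and FDR < fdr_max."""
    t = fit.table
    keep = (t["ratio"] > fold) & (t["fdr"] < fdr_max)
    return list(t.index[keep])


def _null_rho(n_cells: int, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """Spearman rho between independent random rankings of n_cells items."""
    base = np.arange(n_cells, dtype=float)
    base = (base - base.mean()) / base.std()
    perms = rng.permuted(np.tile(base, (n_perm, 1)), axis=1)
    return perms @ base / n_cells


def correlation_filter(
    e: ExpressionMatrix,
    candidates,
    rho_min: float = 0.4,
    fdr_max: float = 0.001,
    n_perm: int = 10_000,
    seed: int = 0,
) -> CorrelationResult:
    """Spearman filter over all candidate pairs with a pooled permutation null.

    Rank correlations use mid-ranks for ties. One pooled null distribution of
    rho (``n_perm`` random rankings against a fixed ranking) is shared across
    pairs; two-sided p-values get BH-adjusted across pairs. A gene is kept iff
    it participates in at least one pair with ``fdr <= fdr_max`` and
    ``|rho| > rho_min``.
    """
    candidates = list(candidates)
    if len(candidates) < 2:
        raise ValidationError("need at least 2 candidate genes")
    if n_perm < 100:
        raise ValidationError("n_perm < 100: permutation null too coarse")
    sub = e.subset_genes(candidates)
    n = sub.values.shape[1]
    ranks = st.rankdata(sub.values, axis=1)
    # Pearson on mid-ranks == Spearman; guard constant genes (zero variance)
    sd = ranks.std(axis=1)
    const = sd == 0
    z = (ranks - ranks.mean(axis=1, keepdims=True)) / np.where(const, 1.0, sd)[:, None]
    rho = z @ z.T / n
    np.fill_diagonal(rho, 1.0)
    rho[const, :] = 0.0
    rho[:, const] = 0.0

    rng = np.random.default_rng(seed)
    null = np.abs(_null_rho(n, n_perm, rng))
    null_sorted = np.sort(null)

    iu = np.triu_indices(len(candidates), k=1)
    obs = np.abs(rho[iu])
    # p = (1 + #null >= |rho|) / (n_perm + 1)
    n_ge = n_perm - np.searchsorted(null_sorted, obs, side="left")
    p = (1.0 + n_ge) / (n_perm + 1.0)
    fdr = bh_fdr(p)

    names = np.asarray(candidates)
    pairs = pd.DataFrame(
        {
            "gene_a": names[iu[0]],
            "gene_b": names[iu[1]],
            "rho": rho[iu],
            "p": p,
            "fdr": fdr,
        }
    )
    sig = (pairs["fdr"] <= fdr_max) & (pairs["rho"].abs() > rho_min)
    kept = sorted(set(pairs.loc[sig, "gene_a"]) | set(pairs.loc[sig, "gene_b"]))
    # preserve candidate order
    kept_genes = [g for g in candidates if g in set(kept)]
    return CorrelationResult(pairs=pairs, kept_genes=kept_genes, n_perm=n_perm)
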