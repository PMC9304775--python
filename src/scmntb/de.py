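"""Negative-binomial differential expression between cell clusters.

Contrasts (pairwise or one-vs-rest) use a per-gene NB likelihood-ratio test of
group-mean equality with log effective-library-size offsets. Dispersions are
method-of-moments estimates within groups, shrunk toward a LOESS trend over
mean expression. Fold changes follow the average-CPM convention: the ratio of
mean CPM in one cluster to mean CPM in the comparison group, reported
alongside its log2, and used (not the GLM coefficient) for the >= 2-fold gate.
A significance call additionally requires the detection rule: >= 5 CPM in at
least 20% of cells of at least one of the compared groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
from statsmodels.nonparametric.smoothers_lowess import lowess

from .matrix import CountMatrix, SizeFactors, ValidationError
from .normalize import cpm as compute_cpm, _effective_library
from .stats import bh_fdr

__all__ = [
    "DEThresholds",
    "DispersionModel",
    "DETable",
    "detection_fraction",
    "estimate_dispersion",
    "nb_contrast",
    "one_vs_rest_tables",
]


@dataclass
class DEThresholds:
    fold_min: float = 2.0
    fdr_max: float = 0.05
    detect_cpm: float = 5.0
    detect_frac: float = 0.2
    direction: str = "both"  # "up": A over B only; "both": either direction
    continuity_cpm: float = 0.5  # added to a zero denominator, flagged


@dataclass
class DispersionModel:
    """Per-gene NB dispersion alpha with a mean trend and shrinkage weight."""

    alpha: np.ndarray
    gene_ids: pd.Index
    trend: np.ndarray
    raw: np.ndarray
    shrinkage_weight: float


@dataclass
class DETable:
    contrast: tuple
    table: pd.DataFrame  # fold_change, log2_fold, p, fdr, detect_frac_A/B, significant
    thresholds: DEThresholds

    def significant_genes(self) -> list:
        return list(self.table.index[self.table["significant"]])

    def sort_by_fdr(self) -> "DETable":
        return DETable(self.contrast, self.table.sort_values("fdr", kind="stable"),
                       self.thresholds)


def detection_fraction(
    cpm_values: np.ndarray, labels, gene_ids=None, threshold: float = 5.0
) -> pd.DataFrame:
    """Fraction of cells per cluster with CPM >= threshold, per gene."""
    labels = np.asarray(labels)
    if labels.shape[0] != cpm_values.shape[1]:
        raise ValidationError("labels must cover all cells")
    out = {}
    for lab in pd.unique(labels):
        members = labels == lab
        if members.sum() == 0:
            raise ValidationError(f"empty cluster {lab!r}")
        out[lab] = (cpm_values[:, members] >= threshold).mean(axis=1)
    return pd.DataFrame(out, index=gene_ids)


def estimate_dispersion(
    m: CountMatrix,
    sf: SizeFactors,
    labels,
    shrinkage_weight: float = 0.7,
    span: float = 0.3,
) -> DispersionModel:
    """Trended, shrunken method-of-moments NB dispersions.

    Counts are depth-normalized by the effective size factor; within each
    group of >= 3 cells, alpha_hat = (var - mean) / mean^2, combined across
    groups by a df-weighted average and clipped at 0. A LOESS trend over log
    mean expression absorbs genes with unstable estimates; gene-wise values are
    shrunk toward the trend with the given weight. Constant or all-zero genes
    take the trend value.
    """
    labels = np.asarray(labels)
    groups = [labels == lab for lab in pd.unique(labels)]
    groups = [g for g in groups if g.sum() >= 3]
    if len(groups) < 1:
        raise ValidationError("need at least one group with >= 3 cells")
    eff = _effective_library(m, sf)
    norm = m.dense() / (eff[None, :] / eff.mean())  # depth-normalized counts

    num = np.zeros(m.n_genes)
    den = np.zeros(m.n_genes)
    for g in groups:
        x = norm[:, g]
        mu = x.mean(axis=1)
        v = x.var(axis=1, ddof=1)
        ok = mu > 0
        w = g.sum() - 1
        a = np.zeros(m.n_genes)
        a[ok] = (v[ok] - mu[ok]) / mu[ok] ** 2
        num += np.where(ok, w * a, 0.0)
        den += np.where(ok, w, 0.0)
    raw = np.where(den > 0, num / np.maximum(den, 1), np.nan)
    raw = np.clip(raw, 0.0, None)

    mean_expr = norm.mean(axis=1)
    ok = np.isfinite(raw) & (mean_expr > 0)
    if ok.sum() >= 10:
        fitted = lowess(raw[ok], np.log1p(mean_expr[ok]), frac=span,
                        return_sorted=False)
        trend = np.full(m.n_genes, np.nanmedian(np.clip(fitted, 0, None)))
        trend[ok] = np.clip(fitted, 0.0, None)
    else:
        trend = np.full(m.n_genes, np.nanmedian(raw[ok]) if ok.any() else 0.0)
    alpha = np.where(
        ok,
        (1 - shrinkage_weight) * raw + shrinkage_weight * trend,
        trend,
    )
    return DispersionModel(
        alpha=np.clip(alpha, 0.0, None),
        gene_ids=m.gene_ids,
        trend=trend,
        raw=raw,
        shrinkage_weight=shrinkage_weight,
    )


def _nb_loglik(y, mu, alpha):
    """NB log-likelihood up to terms constant in mu (alpha fixed per gene)."""
    mu = np.maximum(mu, 1e-12)
    if np.ndim(alpha) == 0:
        alpha = np.full(y.shape[0], float(alpha))
    small = alpha < 1e-8
    ll = np.empty(y.shape[0])
    if small.any():
        ll[small] = (y[small] * np.log(mu[small]) - mu[small]).sum(axis=1)
    big = ~small
    if big.any():
        r = (1.0 / alpha[big])[:, None]
        ll[big] = (
            y[big] * np.log(mu[big]) - (y[big] + r) * np.log(r + mu[big])
        ).sum(axis=1)
    return ll


def _fit_group_mean(y, eff, alpha, n_iter: int = 50, tol: float = 1e-10):
    """Per-gene NB MLE of a single mean on the offset scale (Newton steps).

    y: genes x cells counts; eff: per-cell effective library; alpha: per-gene
    dispersion. Returns mu (genes x cells) at the fitted mean.
    """
    tot = y.sum(axis=1)
    base = np.where(tot > 0, tot / eff.sum(), 1e-12)
    beta = np.log(np.maximum(base, 1e-300))
    if np.ndim(alpha) == 0:
        alpha = np.full(y.shape[0], float(alpha))
    a = alpha[:, None]
    for _ in range(n_iter):
        mu = np.exp(beta)[:, None] * eff[None, :]
        denom = 1.0 + a * mu
        score = ((y - mu) / denom).sum(axis=1)
        info = (mu * (1.0 + a * y) / denom**2).sum(axis=1)
        step = score / np.maximum(info, 1e-300)
        step = np.clip(step, -5.0, 5.0)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return np.exp(beta)[:, None] * eff[None, :]


def nb_contrast(
    m: CountMatrix,
    sf: SizeFactors,
    labels,
    group_a,
    group_b="rest",
    dispersion: DispersionModel | None = None,
    thresholds: DEThresholds | None = None,
) -> DETable:
    """NB likelihood-ratio contrast of ``group_a`` vs ``group_b`` (or the rest).

    p-values come from chi2(1) on the LRT of separate vs shared group means;
    BH FDR within the contrast. The reported fold change is the ratio of
    average CPM (A over B), independent of the test statistic.
    """
    thresholds = thresholds or DEThresholds()
    labels = np.asarray(labels)
    in_a = labels == group_a
    in_b = (labels != group_a) if (isinstance(group_b, str) and group_b == "rest") \
        else (labels == group_b)
    if in_a.sum() == 0 or in_b.sum() == 0:
        raise ValidationError("both contrast groups must be nonempty")
    if dispersion is None:
        dispersion = estimate_dispersion(m, sf, labels)
    alpha = dispersion.alpha

    counts = m.dense().astype(float)
    eff = _effective_library(m, sf)
    ya, yb = counts[:, in_a], counts[:, in_b]
    ea, eb = eff[in_a], eff[in_b]

    mu_a = _fit_group_mean(ya, ea, alpha)
    mu_b = _fit_group_mean(yb, eb, alpha)
    y_ab = np.concatenate([ya, yb], axis=1)
    e_ab = np.concatenate([ea, eb])
    mu_0 = _fit_group_mean(y_ab, e_ab, alpha)

    ll_alt = _nb_loglik(ya, mu_a, alpha) + _nb_loglik(yb, mu_b, alpha)
    ll_null = _nb_loglik(y_ab, mu_0, alpha)
    lrt = np.maximum(2.0 * (ll_alt - ll_null), 0.0)
    p = st.chi2.sf(lrt, df=1)
    all_zero = y_ab.sum(axis=1) == 0
    p[all_zero] = 1.0
    fdr = bh_fdr(p)

    cpm_all = counts / eff[None, :] * 1e6
    avg_a = cpm_all[:, in_a].mean(axis=1)
    avg_b = cpm_all[:, in_b].mean(axis=1)
    zero_den = avg_b == 0
    fold = avg_a / np.where(zero_den, avg_b + thresholds.continuity_cpm, avg_b)
    fold = np.where((avg_a == 0) & zero_den, 1.0, fold)

    det_a = (cpm_all[:, in_a] >= thresholds.detect_cpm).mean(axis=1)
    det_b = (cpm_all[:, in_b] >= thresholds.detect_cpm).mean(axis=1)
    detected = (det_a >= thresholds.detect_frac) | (det_b >= thresholds.detect_frac)

    if thresholds.direction == "up":
        fold_pass = fold >= thresholds.fold_min
    else:
        with np.errstate(divide="ignore"):
            fold_pass = np.maximum(fold, np.where(fold > 0, 1.0 / fold, np.inf)) \
                >= thresholds.fold_min
    significant = fold_pass & (fdr <= thresholds.fdr_max) & detected

    with np.errstate(divide="ignore"):
        log2_fold = np.log2(np.where(fold > 0, fold, np.nan))
    table = pd.DataFrame(
        {
            "fold_change": fold,
            "log2_fold": log2_fold,
            "p": p,
            "fdr": fdr,
            "detect_frac_A": det_a,
            "detect_frac_B": det_b,
            "zero_denominator": zero_den,
            "significant": significant,
        },
        index=m.gene_ids,
    )
    name_b = "rest" if (isinstance(group_b, str) and group_b == "rest") else group_b
    return DETable(contrast=(group_a, name_b), table=table, thresholds=thresholds)


def one_vs_rest_tables(
    m: CountMatrix,
    sf: SizeFactors,
    labels,
    merge_map: dict | None = None,
    dispersion: DispersionModel | None = None,
    thresholds: DEThresholds | None = None,
) -> dict:
    """One-vs-rest DETables per reporting group, sorted by FDR.

    ``merge_map`` maps raw cluster labels to reporting groups (e.g. both
    neuronal clusters onto "neuron"); identity when omitted. Raises if fewer
    than two reporting groups remain after merging.
    """
    labels = np.asarray(labels)
    if merge_map:
        merged = np.asarray([merge_map.get(lab, lab) for lab in labels])
    else:
        merged = labels.copy()
    groups = pd.unique(merged)
    if len(groups) < 2:
        raise ValidationError("merge produced fewer than 2 groups")
    if thresholds is None:
        thresholds = DEThresholds(direction="up")
    if dispersion is None:
        dispersion = estimate_dispersion(m, sf, merged)
    return {
        g: nb_contrast(m, sf, merged, g, "rest", dispersion, thresholds).sort_by_fdr()
        for g in groups
    }
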