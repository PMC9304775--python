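"""Multiple-testing procedures shared across the pipeline.

Implements Benjamini-Hochberg step-up and the adaptive two-stage
Benjamini-Krieger-Yekutieli procedure (stage one estimates the number of true
nulls at a deflated rate q/(1+q); stage two reruns BH at the inflated rate
q * m / m0_hat).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats as st

__all__ = ["bh_fdr", "bh_reject", "bky_two_stage", "MultiTestResult", "multiple_t_tests"]


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def bh_reject(p, q: float) -> np.ndarray:
    """BH step-up rejection set at level q (boolean mask)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    if m == 0:
        return np.zeros(0, dtype=bool)
    order = np.argsort(p, kind="stable")
    below = p[order] <= q * np.arange(1, m + 1) / m
    k = np.max(np.nonzero(below)[0]) + 1 if below.any() else 0
    rejected = np.zeros(m, dtype=bool)
    rejected[order[:k]] = True
    return rejected


@dataclass
class MultiTestResult:
    p: np.ndarray
    rejected: np.ndarray
    procedure: str
    q: float
    m0_hat: int | None = None

    @property
    def n_rejected(self) -> int:
        return int(self.rejected.sum())


def bky_two_stage(p, q: float = 0.01) -> MultiTestResult:
    """Two-stage adaptive FDR control (Benjamini, Krieger & Yekutieli 2006).

    Stage 1: BH at q' = q/(1+q); the number of non-rejections estimates the
    true nulls m0. If nothing or everything is rejected, stop there. Stage 2:
    BH at q * m / m0_hat, which is the reported rejection set.
    """
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return MultiTestResult(p=p, rejected=np.zeros(0, bool), procedure="BKY-two-stage",
                               q=q, m0_hat=0)
    q1 = q / (1.0 + q)
    stage1 = bh_reject(p, q1)
    r1 = int(stage1.sum())
    m0_hat = m - r1
    if r1 == 0 or r1 == m:
        return MultiTestResult(p=p, rejected=stage1, procedure="BKY-two-stage",
                               q=q, m0_hat=m0_hat)
    stage2 = bh_reject(p, q1 * m / m0_hat)
    return MultiTestResult(p=p, rejected=stage2, procedure="BKY-two-stage",
                           q=q, m0_hat=m0_hat)


def multiple_t_tests(pairs, q: float = 0.01, equal_var: bool = False) -> MultiTestResult:
    """Welch t-tests over a family of (group_a, group_b) pairs with BKY at q.

    Mirrors the imaging-statistics convention of running one t test per
    comparison and controlling the family with the adaptive two-stage FDR at
    q = 1%.
    """
    p = np.array(
        [st.ttest_ind(a, b, equal_var=equal_var).pvalue for a, b in pairs], dtype=float
    )
    return bky_two_stage(p, q=q)
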