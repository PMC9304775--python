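"""Core in-memory containers for the pipeline.

The root object is :class:`CountMatrix`, a sparse genes x cells integer count
matrix with gene flags (mitochondrial, reporter) and per-cell annotations.
Normalized expression lives in :class:`ExpressionMatrix` (log2 CPM) which stays
aligned to the subset of the count matrix it was derived from.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["CountMatrix", "SizeFactors", "ExpressionMatrix", "ValidationError"]


class ValidationError(ValueError):
    """Raised when an input object violates a structural contract."""


def _as_csr(counts) -> sp.csr_matrix:
    if sp.issparse(counts):
        return counts.tocsr()
    return sp.csr_matrix(np.asarray(counts))


@dataclass
class CountMatrix:
    """Genes x cells nonnegative integer counts with metadata.

    Parameters
    ----------
    counts
        Sparse (or dense, converted) matrix of shape ``(n_genes, n_cells)``.
    gene_ids, cell_ids
        Unique string identifiers for rows and columns.
    gene_flags
        DataFrame indexed like ``gene_ids`` with boolean columns ``mito`` and
        ``reporter``.
    cell_meta
        DataFrame indexed like ``cell_ids``; the pipeline uses the boolean
        column ``excluded_manually`` when present (manual doublet/dead-cell
        annotations from capture-site images).
    """

    counts: sp.csr_matrix
    gene_ids: pd.Index
    cell_ids: pd.Index
    gene_flags: pd.DataFrame = None
    cell_meta: pd.DataFrame = None

    def __post_init__(self):
        self.counts = _as_csr(self.counts)
        self.gene_ids = pd.Index(self.gene_ids, name="gene")
        self.cell_ids = pd.Index(self.cell_ids, name="cell")
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if not self.gene_ids.is_unique:
            dup = self.gene_ids[self.gene_ids.duplicated()][0]
            raise ValidationError(f"duplicate gene id: {dup!r}")
        if not self.cell_ids.is_unique:
            dup = self.cell_ids[self.cell_ids.duplicated()][0]
            raise ValidationError(f"duplicate cell id: {dup!r}")
        data = self.counts.data
        if data.size and data.min() < 0:
            raise ValidationError("counts must be nonnegative")
        if data.size and not np.allclose(data, np.round(data)):
            raise ValidationError("counts must be integral")
        self.counts.data = np.asarray(np.round(data), dtype=np.int64)
        if self.gene_flags is None:
            self.gene_flags = pd.DataFrame(
                {"mito": False, "reporter": False}, index=self.gene_ids
            )
        else:
            self.gene_flags = self.gene_flags.reindex(self.gene_ids)
            for col in ("mito", "reporter"):
                if col not in self.gene_flags:
                    self.gene_flags[col] = False
                self.gene_flags[col] = self.gene_flags[col].fillna(False).astype(bool)
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=self.cell_ids)
        else:
            self.cell_meta = self.cell_meta.reindex(self.cell_ids)

    # -- basic accessors -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def total_counts(self) -> np.ndarray:
        """Per-cell library size (column sums)."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())

    # -- subsetting ------------------------------------------------------
    def subset_genes(self, mask_or_ids) -> "CountMatrix":
        idx = self._gene_indexer(mask_or_ids)
        return CountMatrix(
            self.counts[idx, :],
            self.gene_ids[idx],
            self.cell_ids,
            self.gene_flags.iloc[idx],
            self.cell_meta,
        )

    def subset_cells(self, mask_or_ids) -> "CountMatrix":
        idx = self._cell_indexer(mask_or_ids)
        return CountMatrix(
            self.counts[:, idx],
            self.gene_ids,
            self.cell_ids[idx],
            self.gene_flags,
            self.cell_meta.iloc[idx],
        )

    def _gene_indexer(self, key):
        return _indexer(key, self.gene_ids)

    def _cell_indexer(self, key):
        return _indexer(key, self.cell_ids)


def _indexer(key, index: pd.Index) -> np.ndarray:
    key = np.asarray(key)
    if key.dtype == bool:
        if key.shape != (len(index),):
            raise ValidationError("boolean mask length mismatch")
        return np.flatnonzero(key)
    if key.dtype.kind in "iu":
        return key
    pos = index.get_indexer(key)
    if (pos < 0).any():
        missing = key[pos < 0][0]
        raise KeyError(f"id not found: {missing!r}")
    return pos


@dataclass
class SizeFactors:
    """Per-cell scaling factors from pooled deconvolution.

    ``factor`` has unit mean after rescaling; ``pool_sizes_used`` records the
    ring-window sizes that built the linear system.
    """

    factor: np.ndarray
    cell_ids: pd.Index
    pool_sizes_used: list = field(default_factory=list)
    rescaled_to_unit_mean: bool = True

    def __post_init__(self):
        self.factor = np.asarray(self.factor, dtype=float)
        self.cell_ids = pd.Index(self.cell_ids)
        if (self.factor <= 0).any():
            raise ValidationError("size factors must be positive")


@dataclass
class ExpressionMatrix:
    """Genes x cells log2 CPM values aligned to a CountMatrix subset."""

    values: np.ndarray
    gene_ids: pd.Index
    cell_ids: pd.Index
    pseudocount: float = 1.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = pd.Index(self.gene_ids, name="gene")
        self.cell_ids = pd.Index(self.cell_ids, name="cell")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError("expression shape/id mismatch")
        if not np.isfinite(self.values).all():
            raise ValidationError("expression values must be finite")

    def subset_genes(self, mask_or_ids) -> "ExpressionMatrix":
        idx = _indexer(np.asarray(mask_or_ids), self.gene_ids)
        return ExpressionMatrix(
            self.values[idx, :], self.gene_ids[idx], self.cell_ids, self.pseudocount
        )

    def loc(self, gene) -> np.ndarray:
        """Expression vector of a single gene across cells."""
        pos = self.gene_ids.get_loc(gene)
        return self.values[pos, :]
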