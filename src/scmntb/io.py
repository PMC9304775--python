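"""Readers and writers for count matrices and synthetic-dataset bundles.

On disk a dataset is a directory with Matrix Market coordinate counts
(1-based indices) plus TSV sidecars: ``genes.tsv`` (id, mito, reporter),
``cells.tsv`` (id plus annotations) and, for synthetic data, ``truth.tsv``
with the ground-truth labels and artifact flags. Small matrices may instead be
a single dense TSV (genes in rows, first column gene id, header = cell ids).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .matrix import CountMatrix, ValidationError

__all__ = ["ParseError", "read_counts", "write_counts", "write_dataset", "read_dataset"]


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


def _validate_mtx(path: Path) -> None:
    """Check the coordinate header against the actual number of data lines."""
    header = None
    n_data = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("%"):
                continue
            if header is None:
                parts = s.split()
                if len(parts) != 3:
                    raise ParseError(f"{path.name}:{lineno}: malformed size line {s!r}")
                header = (lineno, tuple(int(x) for x in parts))
            else:
                n_data += 1
    if header is None:
        raise ParseError(f"{path.name}: no size line found")
    lineno, (nr, nc, nnz) = header
    if n_data != nnz:
        raise ParseError(
            f"{path.name}:{lineno}: header declares nnz={nnz} "
            f"but {n_data} data lines follow"
        )


def read_counts(path) -> CountMatrix:
    """Read a CountMatrix from an MTX+TSV directory or a dense TSV file."""
    path = Path(path)
    if path.is_dir():
        return _read_mtx_dir(path)
    return _read_dense_tsv(path)


def _read_mtx_dir(directory: Path) -> CountMatrix:
    mtx = directory / "matrix.mtx"
    genes_tsv = directory / "genes.tsv"
    cells_tsv = directory / "cells.tsv"
    for f in (mtx, genes_tsv, cells_tsv):
        if not f.exists():
            raise ParseError(f"missing file: {f}")
    _validate_mtx(mtx)
    counts = sp.csr_matrix(mmread(str(mtx)))
    genes = pd.read_csv(genes_tsv, sep="\t", dtype={"id": str})
    cells = pd.read_csv(cells_tsv, sep="\t", dtype={"id": str})
    if "id" not in genes or "id" not in cells:
        raise ParseError("genes.tsv and cells.tsv need an 'id' column")
    gene_flags = pd.DataFrame(index=pd.Index(genes["id"], name="gene"))
    for col in ("mito", "reporter"):
        gene_flags[col] = (
            genes[col].astype(bool).to_numpy() if col in genes else False
        )
    cell_meta = cells.set_index("id")
    cell_meta.index.name = "cell"
    if "excluded_manually" in cell_meta:
        cell_meta["excluded_manually"] = cell_meta["excluded_manually"].astype(bool)
    try:
        return CountMatrix(counts, genes["id"], cells["id"], gene_flags, cell_meta)
    except ValidationError as err:
        raise ParseError(str(err)) from err


def _read_dense_tsv(path: Path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy()
    if values.dtype.kind not in "iu":
        if not np.allclose(values, np.round(values)):
            bad = np.argwhere(~np.isclose(values, np.round(values)))[0]
            raise ParseError(
                f"{path.name}: non-integer value at data row {bad[0] + 1}, "
                f"column {bad[1] + 1}"
            )
        values = values.astype(np.int64)
    try:
        return CountMatrix(sp.csr_matrix(values), df.index.astype(str),
                           df.columns.astype(str))
    except ValidationError as err:
        raise ParseError(f"{path.name}: {err}") from err


def write_counts(m: CountMatrix, directory) -> dict:
    """Write matrix.mtx + genes.tsv + cells.tsv; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mtx = directory / "matrix.mtx"
    mmwrite(str(mtx), sp.coo_matrix(m.counts), field="integer")
    genes = m.gene_flags.reset_index().rename(columns={"gene": "id"})
    genes[["id", "mito", "reporter"]].astype({"mito": int, "reporter": int}).to_csv(
        directory / "genes.tsv", sep="\t", index=False
    )
    cells = m.cell_meta.reset_index().rename(columns={"cell": "id", "index": "id"})
    cells.to_csv(directory / "cells.tsv", sep="\t", index=False)
    return {"matrix": mtx, "genes": directory / "genes.tsv",
            "cells": directory / "cells.tsv"}


def write_dataset(ds, directory) -> dict:
    """Write a SyntheticDataset bundle (counts + truth.tsv)."""
    directory = Path(directory)
    paths = write_counts(ds.counts, directory)
    truth = pd.DataFrame(
        {
            "id": ds.counts.cell_ids,
            "true_type": ds.true_type.to_numpy(),
            "is_doublet": ds.is_doublet.to_numpy().astype(int),
            "is_low_quality": ds.is_low_quality.to_numpy().astype(int),
        }
    )
    truth_path = directory / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    paths["truth"] = truth_path
    return paths


def read_dataset(directory):
    """Read back a SyntheticDataset bundle written by :func:`write_dataset`."""
    from .simulate import SyntheticDataset

    directory = Path(directory)
    cm = read_counts(directory)
    truth = pd.read_csv(directory / "truth.tsv", sep="\t", dtype={"id": str})
    truth = truth.set_index("id").reindex(cm.cell_ids)
    return SyntheticDataset(
        counts=cm,
        true_type=truth["true_type"].rename("true_type"),
        is_doublet=truth["is_doublet"].astype(bool).rename("is_doublet"),
        is_low_quality=truth["is_low_quality"].astype(bool).rename("is_low_quality"),
        marker_map={},
        config=None,
    )
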