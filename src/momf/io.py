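"""Readers and writers for count matrices, label files and result tables.

Two on-disk layouts are supported:

* delimited text (comma or tab, auto-detected from the header line) with row
  and column names;
* MatrixMarket (``.mtx``) with two sidecar name files next to the matrix,
  ``<stem>_rows.txt`` and ``<stem>_cols.txt`` (one name per line).

Counts may be stored samples-by-genes or genes-by-samples; the caller must
say which (``orientation``) — orientation is never guessed, because a silent
transpose is the classic deconvolution failure mode. In memory everything is
samples-by-genes.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread

from .data import BulkCountMatrix, SingleCellCountMatrix

__all__ = [
    "read_counts",
    "read_labels",
    "write_proportions",
    "read_proportions",
]

_ORIENTATIONS = ("samples_by_genes", "genes_by_samples")


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def _read_table(path: Path) -> pd.DataFrame:
    if path.suffix == ".mtx":
        stem = path.with_suffix("")
        rows_file = Path(f"{stem}_rows.txt")
        cols_file = Path(f"{stem}_cols.txt")
        for side in (rows_file, cols_file):
            if not side.exists():
                raise FileNotFoundError(
                    f"MatrixMarket sidecar name file not found: {side}"
                )
        mat = mmread(os.fspath(path))
        if hasattr(mat, "toarray"):
            mat = mat.toarray()
        mat = np.asarray(mat)
        rows = rows_file.read_text().split()
        cols = cols_file.read_text().split()
        return pd.DataFrame(mat, index=rows, columns=cols)
    sep = _sniff_sep(path)
    # duplicate header detection must precede pandas, which mangles duplicates
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    dups = {h for h in header if header.count(h) > 1}
    if dups:
        raise ValueError(f"duplicate column name(s) in {path}: {sorted(dups)[:5]}")
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except ValueError as exc:
        raise ValueError(f"failed to parse {path}: {exc}") from exc
    bad = df.select_dtypes(exclude="number").columns
    if len(bad):
        col = bad[0]
        row = df.index[df[col].map(lambda v: not isinstance(v, (int, float, np.number)))][0]
        raise ValueError(f"non-numeric value in {path} at row {row!r}, column {col!r}")
    return df


def read_counts(
    path: str | os.PathLike,
    orientation: str,
    labels: str | os.PathLike | None = None,
):
    """Read a count matrix; with ``labels`` given, as single-cell data.

    Parameters
    ----------
    path
        Delimited text with a header row and a leading name column, or a
        ``.mtx`` file with ``_rows.txt`` / ``_cols.txt`` sidecars.
    orientation
        ``"samples_by_genes"`` or ``"genes_by_samples"`` — how the file on
        disk is laid out.
    labels
        Optional two-column delimited file (cell_id, cell_type). When given,
        a :class:`SingleCellCountMatrix` is returned; labels are joined to
        cells by id.
    """
    if orientation not in _ORIENTATIONS:
        raise ValueError(f"orientation must be one of {_ORIENTATIONS}, got {orientation!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = _read_table(path)
    if orientation == "genes_by_samples":
        df = df.T
    values = df.to_numpy()
    sample_ids = [str(s) for s in df.index]
    gene_ids = [str(g) for g in df.columns]
    if labels is None:
        return BulkCountMatrix(values, sample_ids, gene_ids)
    label_map = read_labels(labels)
    missing = [s for s in sample_ids if s not in label_map]
    if missing:
        raise ValueError(f"no cell-type label for cell(s): {missing[:5]}")
    return SingleCellCountMatrix(
        values, sample_ids, gene_ids, [label_map[s] for s in sample_ids]
    )


def read_labels(path: str | os.PathLike) -> dict[str, str]:
    """Read a two-column (cell_id, cell_type) delimited file, header optional."""
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"label file {path} needs two columns (cell_id, cell_type)")
    first = df.iloc[0]
    if str(first[0]).lower() in {"cell_id", "cell", "barcode", "id"}:
        df = df.iloc[1:]
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_proportions(result, path: str | os.PathLike) -> None:
    """Write estimated proportions as CSV (rows individuals, sorted type columns).

    ``result`` may be a fit result object exposing ``.proportions`` (a
    DataFrame) or a proportions DataFrame itself.
    """
    df = result.proportions if hasattr(result, "proportions") else result
    if not isinstance(df, pd.DataFrame):
        raise TypeError("expected a proportions DataFrame or a fit result")
    if df.isna().to_numpy().any():
        raise ValueError("proportions contain NaN; refusing to write")
    sums = df.to_numpy().sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise ValueError("proportion rows do not sum to 1")
    df = df[sorted(df.columns)]
    df.to_csv(path, float_format="%.10g")


def read_proportions(path: str | os.PathLike) -> pd.DataFrame:
    """Read a proportions table written by :func:`write_proportions`."""
    sep = _sniff_sep(Path(path))
    return pd.read_csv(path, sep=sep, index_col=0)
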