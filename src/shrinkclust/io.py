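"""Delimited-text readers and writers for matrices and label tables.

Matrices travel as comma- or tab-separated text, one object per row, with an
optional header row and an optional leading column of object identifiers.
The delimiter is sniffed from the first line unless given explicitly.
Cluster labels are written as a two-column table (object_id, cluster) with
clusters renumbered 1..K in order of first appearance.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "sniff_delimiter",
    "read_matrix",
    "read_similarity",
    "read_features",
    "write_matrix",
    "read_labels",
    "write_labels",
    "write_path_log",
    "renumber_labels",
]


def sniff_delimiter(path, delimiter: Optional[str] = None) -> str:
    """Pick the delimiter: an explicit one, else tab vs comma by first line."""
    if delimiter:
        return delimiter
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def _is_numeric_like(values) -> bool:
    try:
        pd.to_numeric(pd.Series(values))
        return True
    except (ValueError, TypeError):
        return False


def read_matrix(path, delimiter: Optional[str] = None):
    """Read a numeric matrix, auto-detecting a header row and an id column.

    Returns
    -------
    (numpy.ndarray, list of str or None)
        The matrix and the object ids (None when the file has no id column).
    """
    path = Path(path)
    sep = sniff_delimiter(path, delimiter)
    try:
        df = pd.read_csv(path, sep=sep, header=None, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"{path}: cannot parse as {sep!r}-delimited text: {exc}")
    if df.empty:
        raise ValueError(f"{path}: file is empty")

    has_header = not _is_numeric_like(df.iloc[0, 1:] if df.shape[1] > 1 else df.iloc[0, :])
    body = df.iloc[1:, :] if has_header else df
    has_ids = not _is_numeric_like(body.iloc[:, 0])
    ids = body.iloc[:, 0].tolist() if has_ids else None
    values = body.iloc[:, 1:] if has_ids else body

    mat = np.empty(values.shape, dtype=float)
    for j, col in enumerate(values.columns):
        try:
            mat[:, j] = pd.to_numeric(values[col]).to_numpy()
        except (ValueError, TypeError):
            name = df.iloc[0, col] if has_header else f"column {j + 1}"
            raise ValueError(f"{path}: non-numeric values in {name}")
    return mat, ids


def read_similarity(path, delimiter: Optional[str] = None):
    """Read a square similarity matrix (values validated by the caller)."""
    mat, ids = read_matrix(path, delimiter)
    if mat.shape[0] != mat.shape[1]:
        raise ValueError(
            f"{path}: similarity matrix must be square, got shape {mat.shape}"
        )
    return mat, ids


def read_features(path, delimiter: Optional[str] = None):
    """Read an objects-by-features matrix."""
    return read_matrix(path, delimiter)


def write_matrix(path, matrix, ids=None, delimiter: str = "\t") -> None:
    """Write a numeric matrix, optionally with a leading id column."""
    M = np.asarray(matrix)
    df = pd.DataFrame(M)
    if ids is not None:
        df.insert(0, "object_id", list(ids))
        df.to_csv(path, sep=delimiter, index=False, header=False)
    else:
        df.to_csv(path, sep=delimiter, index=False, header=False)


def renumber_labels(labels) -> np.ndarray:
    """Renumber cluster ids to consecutive 1..K by order of first appearance."""
    labels = np.asarray(labels)
    mapping: dict = {}
    out = np.empty(labels.size, dtype=np.intp)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


def write_labels(path, labels, ids=None, delimiter: str = "\t") -> None:
    """Write an (object_id, cluster) table; clusters renumbered 1..K."""
    labels = renumber_labels(labels)
    if ids is None:
        ids = [str(i + 1) for i in range(labels.size)]
    df = pd.DataFrame({"object_id": list(ids), "cluster": labels})
    df.to_csv(path, sep=delimiter, index=False)


def read_labels(path, delimiter: Optional[str] = None) -> np.ndarray:
    """Read a label vector from a one- or two-column table.

    Accepts files with or without a header; in two-column files the second
    column holds the cluster labels.
    """
    path = Path(path)
    sep = sniff_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, header=None, dtype=str)
    if df.empty:
        raise ValueError(f"{path}: file is empty")
    col = df.iloc[:, -1]
    if not _is_numeric_like(col.iloc[:1]):  # header row
        col = col.iloc[1:]
    if col.empty:
        raise ValueError(f"{path}: no label rows found")
    try:
        return pd.to_numeric(col).to_numpy()
    except (ValueError, TypeError):
        # labels may be arbitrary strings; factorize them
        codes, _ = pd.factorize(col)
        return codes


def write_path_log(path, solver_path) -> None:
    """Write the shrinkage path as tab-separated (iteration, k, objective)."""
    arr = np.asarray(solver_path)
    df = pd.DataFrame(arr, columns=["iteration", "k", "objective"])
    df["iteration"] = df["iteration"].astype(int)
    df["k"] = df["k"].astype(int)
    df.to_csv(path, sep="\t", index=False)
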