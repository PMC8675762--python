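"""Matrix file I/O: MatrixMarket, CSV/TSV, whitespace-delimited text."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .core import as_binary_matrix

__all__ = ["read_matrix", "write_matrix"]

_SUFFIX_FORMAT = {
    ".mtx": "mtx",
    ".csv": "csv",
    ".tsv": "tsv",
    ".txt": "dense-txt",
}


def _infer_format(path, fmt):
    if fmt is not None:
        if fmt not in ("mtx", "csv", "tsv", "dense-txt"):
            raise ValueError(f"unknown format {fmt!r}")
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix not in _SUFFIX_FORMAT:
        raise ValueError(f"cannot infer format from suffix {suffix!r}; pass format=")
    return _SUFFIX_FORMAT[suffix]


def read_matrix(path, format: str | None = None, binary: bool = False) -> np.ndarray:
    """Read a dense ndarray from ``path``.

    ``format`` is one of ``mtx`` (MatrixMarket coordinate, including
    pattern files), ``csv``, ``tsv``, or ``dense-txt`` (whitespace
    delimited); when omitted it is inferred from the suffix.  CSV/TSV files
    may carry a single non-numeric header row, which is skipped.  With
    ``binary=True`` the entries are validated to be 0/1 and returned as
    int64.
    """
    fmt = _infer_format(path, format)
    try:
        if fmt == "mtx":
            mat = scipy.io.mmread(path)
            arr = mat.toarray() if sp.issparse(mat) else np.asarray(mat)
        elif fmt in ("csv", "tsv"):
            sep = "," if fmt == "csv" else "\t"
            df = pd.read_csv(path, sep=sep, header=None)
            if df.map(lambda v: isinstance(v, str)).any().any():
                df = pd.read_csv(path, sep=sep, header=0)
            arr = df.to_numpy(dtype=np.float64)
        else:
            arr = np.loadtxt(path, ndmin=2)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"failed to parse {path} as {fmt}: {exc}") from exc
    if binary:
        return as_binary_matrix(arr, str(path))
    return arr


def write_matrix(matrix, path, format: str | None = None) -> None:
    """Write a matrix to ``path`` in the given (or inferred) format.

    MatrixMarket output uses the sparse coordinate integer field for
    integer-valued data; delimited formats write plain numbers with no
    header.  Round-trips through :func:`read_matrix` are exact for integer
    matrices.
    """
    fmt = _infer_format(path, format)
    arr = np.asarray(matrix)
    integral = np.issubdtype(arr.dtype, np.integer) or (
        arr.size and np.all(arr == np.round(arr))
    )
    if fmt == "mtx":
        data = arr.astype(np.int64) if integral else arr.astype(np.float64)
        scipy.io.mmwrite(path, sp.coo_matrix(data))
        return
    sep = {"csv": ",", "tsv": "\t", "dense-txt": " "}[fmt]
    out = arr.astype(np.int64) if integral else arr
    np.savetxt(path, out, fmt="%d" if integral else "%.17g", delimiter=sep)
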