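"""Synthetic binary matrices and gene-expression discretization.

Two synthetic regimes drive testing and benchmarking:

* planted matrices with an exact rank-r factorization, so the ideal
  factorization error is exactly 0;
* i.i.d. Bernoulli(p) matrices with no planted structure, probing behavior
  on unstructured data at densities 0.2 / 0.5 / 0.8.

The discretizer turns a real-valued expression matrix into a binary one by
flagging entries that are extreme relative to the global mean, the standard
preprocessing for expression biclustering: values far below or far above
average expression carry the signal, mid-range values are noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import as_binary_matrix

__all__ = [
    "DiscretizeConfig",
    "LEUKEMIA_PRESET",
    "MELANOMA_PRESET",
    "gen_exact_rank_r",
    "gen_bernoulli",
    "discretize",
]

_MAX_RESAMPLES = 10_000


def gen_exact_rank_r(m: int, n: int, r: int, rng, row_density: float = 0.5):
    """Generate ``(A, U, V)`` with ``A = U V^T`` exact and binary.

    Each row of U is one-hot with a uniformly chosen factor, so the rank-1
    blocks have disjoint row supports and the product is automatically
    binary; V entries are i.i.d. Bernoulli(``row_density``).  Draws are
    rejected until every factor is used by at least one row of U, every
    factor has a nonzero column in V, and A is nonzero.
    """
    if not 1 <= r <= min(m, n):
        raise ValueError(f"need 1 <= r <= min(m, n) = {min(m, n)}, got r={r}")
    if not 0 < row_density < 1:
        raise ValueError("row_density must be strictly between 0 and 1")
    rng = np.random.default_rng(rng)
    for _ in range(_MAX_RESAMPLES):
        assignment = rng.integers(0, r, size=m)
        U = np.zeros((m, r), dtype=np.int64)
        U[np.arange(m), assignment] = 1
        V = (rng.random((n, r)) < row_density).astype(np.int64)
        if len(np.unique(assignment)) < r:
            continue
        if (V.sum(axis=0) == 0).any():
            continue
        A = U @ V.T
        if A.sum() == 0:
            continue
        return as_binary_matrix(A, "A"), U, V
    raise RuntimeError("failed to generate a non-degenerate planted matrix")


def gen_bernoulli(m: int, n: int, p: float, rng) -> np.ndarray:
    """i.i.d. Bernoulli(``p``) binary matrix; ``p`` strictly inside (0, 1)."""
    if not 0 < p < 1:
        raise ValueError("p must be strictly between 0 and 1")
    rng = np.random.default_rng(rng)
    return (rng.random((m, n)) < p).astype(np.int64)


@dataclass(frozen=True)
class DiscretizeConfig:
    """Thresholding rule for turning expression values into bits.

    With ``kappa`` the mean of all (preprocessed) entries, an entry becomes
    1 when it is ``<= kappa * c1`` or ``>= kappa * c2`` and 0 otherwise
    (``0 <= c1 < c2``).  Optional preprocessing: shift by the global minimum
    to make entries nonnegative, and/or scale columns to unit Euclidean
    norm.  ``kappa`` is computed after both preprocessing steps.
    """

    c1: float
    c2: float
    normalize_columns: bool = False
    shift_nonnegative: bool = False

    def __post_init__(self):
        if not 0 <= self.c1 < self.c2:
            raise ValueError("need 0 <= c1 < c2")


#: Thresholds used for two-class leukemia expression data: raw values, no
#: column normalization.
LEUKEMIA_PRESET = DiscretizeConfig(c1=1 / 7, c2=5.0)

#: Thresholds for melanoma cDNA data, which contains negative values: shift
#: to nonnegative, normalize columns, then use tight thresholds around the
#: mean.
MELANOMA_PRESET = DiscretizeConfig(
    c1=0.96, c2=1.04, normalize_columns=True, shift_nonnegative=True
)


def discretize(X, cfg: DiscretizeConfig):
    """Binarize an expression matrix and drop all-zero rows.

    Returns ``(A, kept_rows)`` where ``kept_rows`` are the original indices
    of the surviving rows, in increasing order.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.size == 0:
        raise ValueError("X must be a nonempty 2-D matrix")
    if np.isnan(X).any():
        raise ValueError("X contains NaN")
    if cfg.shift_nonnegative:
        X = X - X.min()
    if (X < 0).any():
        raise ValueError(
            "X has negative entries; enable shift_nonnegative or shift beforehand"
        )
    if cfg.normalize_columns:
        norms = np.linalg.norm(X, axis=0)
        safe = np.where(norms > 0, norms, 1.0)  # all-zero columns left as-is
        X = X / safe
    kappa = X.mean()
    A = ((X <= kappa * cfg.c1) | (X >= kappa * cfg.c2)).astype(np.int64)
    keep = np.flatnonzero(A.any(axis=1))
    return A[keep], keep
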