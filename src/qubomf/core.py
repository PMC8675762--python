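"""Core types for binary matrix factorization (BMF).

Rank-r BMF approximates a binary matrix ``A`` (m x n) by the product
``U @ V.T`` of two binary factors ``U`` (m x r) and ``V`` (n x r) under the
ordinary integer inner product, minimizing the squared Frobenius error
``||A - U V^T||_F^2``.  When ``U V^T`` happens to be binary this objective is
exactly the number of mismatched cells.

This module holds the exact-arithmetic building blocks shared by the QUBO
assembly and the solvers: validated binary matrices, the objective and its
relative-error normalization, the quadratization penalty ``f`` used to
enforce product constraints on auxiliary variables, and the variable layouts
that map factor/auxiliary matrix entries onto flat decision vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "as_binary_matrix",
    "penalty_f",
    "bmf_objective",
    "relative_error",
    "safe_penalty_weight",
    "FactorPair",
    "PenaltyConfig",
    "VariableLayout",
]


def as_binary_matrix(a, name: str = "matrix") -> np.ndarray:
    """Validate and return ``a`` as a 2-D int64 array with entries in {0, 1}.

    Entries are stored as integers, never floats, so that objectives are
    exact mismatch counts.
    """
    arr = np.asarray(a)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got ndim={arr.ndim}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError(f"{name} must have at least one row and one column")
    if arr.dtype == bool:
        return arr.astype(np.int64)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} has entries outside {{0, 1}}")
    return arr.astype(np.int64)


def penalty_f(a: int, b: int, c: int) -> int:
    """Quadratization penalty ``f(a, b, c) = bc - 2ba - 2ca + 3a``.

    For binary inputs, ``f`` is 0 exactly when ``a == b * c`` and at least 1
    otherwise, so ``lambda * f(w, u, v)`` added to a quadratic objective
    enforces the product constraint ``w = u v`` at optimality for a
    sufficiently large weight ``lambda``.
    """
    for name, val in (("a", a), ("b", b), ("c", c)):
        if val not in (0, 1):
            raise ValueError(f"penalty_f argument {name} must be 0 or 1, got {val!r}")
    return b * c - 2 * b * a - 2 * c * a + 3 * a


def bmf_objective(A, U, V) -> int:
    """Squared Frobenius error ``||A - U V^T||_F^2`` for binary A, U, V.

    Equals the number of mismatched cells whenever ``U V^T`` is itself
    binary; in general it is the elementwise sum of squared differences.
    """
    A = as_binary_matrix(A, "A")
    U = as_binary_matrix(U, "U")
    V = as_binary_matrix(V, "V")
    m, n = A.shape
    if U.shape[0] != m:
        raise ValueError(f"U has {U.shape[0]} rows, expected {m}")
    if V.shape[0] != n:
        raise ValueError(f"V has {V.shape[0]} rows, expected {n}")
    if U.shape[1] != V.shape[1]:
        raise ValueError("U and V must share the same rank (column count)")
    diff = A - U @ V.T
    return int((diff * diff).sum())


def relative_error(A, U, V) -> float:
    """``||A - U V^T||_F^2 / ||A||_F^2``; the norm is squared.

    For binary data this is the number of incorrect cells divided by the
    number of nonzero cells of ``A``.  Raises for an all-zero ``A`` (the
    denominator would vanish).
    """
    A = as_binary_matrix(A, "A")
    nnz = int(A.sum())
    if nnz == 0:
        raise ValueError("relative error is undefined for an all-zero matrix")
    return bmf_objective(A, U, V) / nnz


def safe_penalty_weight(A, r: int) -> int:
    """Smallest integer penalty weight exceeding ``2 r ||A||_F^2``.

    Above this threshold the penalized and constrained formulations share
    their minimizers, so the QUBO optimum certifies a BMF optimum.
    """
    A = as_binary_matrix(A, "A")
    return 2 * int(r) * int(A.sum()) + 1


@dataclass(frozen=True)
class FactorPair:
    """A pair of binary factors ``U`` (m x r) and ``V`` (n x r)."""

    U: np.ndarray
    V: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "U", as_binary_matrix(self.U, "U"))
        object.__setattr__(self, "V", as_binary_matrix(self.V, "V"))
        if self.U.shape[1] != self.V.shape[1]:
            raise ValueError("U and V must have the same number of columns")
        if self.U.shape[1] < 1:
            raise ValueError("rank must be at least 1")

    @property
    def rank(self) -> int:
        return self.U.shape[1]

    def product(self) -> np.ndarray:
        return self.U @ self.V.T


@dataclass(frozen=True)
class PenaltyConfig:
    """Penalty weights for QUBO assembly.

    lambda_quad
        Weight on the quadratization penalties tying auxiliary variables to
        the products they stand for.  Default 1, the practical choice: large
        weights steepen the landscape and hurt annealers, and constraint
        violations can be detected and repaired downstream.
    lambda_cluster
        If set, weight of the one-hot clustering penalty forcing each row of
        V to sum to 1 (each sample assigned to exactly one cluster).
    """

    lambda_quad: float = 1.0
    lambda_cluster: float | None = None

    def __post_init__(self):
        if not self.lambda_quad > 0:
            raise ValueError("lambda_quad must be positive")
        if self.lambda_cluster is not None and not self.lambda_cluster > 0:
            raise ValueError("lambda_cluster must be positive when set")


@dataclass(frozen=True)
class VariableLayout:
    """Bijection between factor/auxiliary entries and flat bitvector slots.

    Two encodings are supported.  Both store ``u = vec(U)`` and ``v = vec(V)``
    first, with ``vec`` stacking columns (column-major order).

    F1 : ``x = [u; v; w^(1); ...; w^(r)]`` of length ``(m + n + mn) r``,
         where ``w_ij^(k)`` is an auxiliary variable for ``u_ik v_jk``.
    F2 : ``y = [u; v; utilde; vtilde]`` of length ``(m + n)(r + r^2)``, where
         ``utilde_i^(k,k')`` stands for ``u_ik u_ik'`` and ``vtilde_j^(k,k')``
         for ``v_jk v_jk'``.  The auxiliary pair ``(k, k')`` (0-based) is
         stored in column ``k' * r + k`` of the m x r^2 (resp. n x r^2)
         auxiliary matrix; correctness is enforced by energy equivalence,
         not by any particular column order.

    All indices are 0-based.
    """

    formulation: str
    m: int
    n: int
    r: int

    def __post_init__(self):
        if self.formulation not in ("F1", "F2"):
            raise ValueError("formulation must be 'F1' or 'F2'")
        if min(self.m, self.n, self.r) < 1:
            raise ValueError("m, n, r must all be at least 1")

    # ------------------------------------------------------------------
    # positions
    # ------------------------------------------------------------------
    @property
    def length(self) -> int:
        m, n, r = self.m, self.n, self.r
        if self.formulation == "F1":
            return (m + n + m * n) * r
        return (m + n) * (r + r * r)

    def u_pos(self, i, k):
        return k * self.m + i

    def v_pos(self, j, k):
        return self.m * self.r + k * self.n + j

    def w_pos(self, i, j, k):
        if self.formulation != "F1":
            raise ValueError("w variables exist only in formulation F1")
        return (self.m + self.n) * self.r + k * self.m * self.n + j * self.m + i

    def _aux_col(self, k, kp):
        return kp * self.r + k

    def utilde_pos(self, i, k, kp):
        if self.formulation != "F2":
            raise ValueError("utilde variables exist only in formulation F2")
        return (self.m + self.n) * self.r + self._aux_col(k, kp) * self.m + i

    def vtilde_pos(self, j, k, kp):
        if self.formulation != "F2":
            raise ValueError("vtilde variables exist only in formulation F2")
        base = (self.m + self.n) * self.r + self.m * self.r * self.r
        return base + self._aux_col(k, kp) * self.n + j

    # ------------------------------------------------------------------
    # encode / decode
    # ------------------------------------------------------------------
    def consistent_aux(self, U, V) -> dict:
        """Auxiliary values implied by (U, V): products of the factor bits."""
        U = as_binary_matrix(U, "U")
        V = as_binary_matrix(V, "V")
        m, n, r = self.m, self.n, self.r
        if self.formulation == "F1":
            W = np.empty((m, n, r), dtype=np.int64)
            for k in range(r):
                W[:, :, k] = np.outer(U[:, k], V[:, k])
            return {"W": W}
        Ut = np.empty((m, r * r), dtype=np.int64)
        Vt = np.empty((n, r * r), dtype=np.int64)
        for k in range(r):
            for kp in range(r):
                c = self._aux_col(k, kp)
                Ut[:, c] = U[:, k] * U[:, kp]
                Vt[:, c] = V[:, k] * V[:, kp]
        return {"Utilde": Ut, "Vtilde": Vt}

    def encode(self, U, V, aux: dict | None = None) -> np.ndarray:
        """Flatten (U, V, aux) into a bitvector.

        If ``aux`` is omitted, the consistent auxiliary values (products of
        the corresponding factor entries) are used, yielding a feasible point
        of the constrained formulation.
        """
        U = as_binary_matrix(U, "U")
        V = as_binary_matrix(V, "V")
        m, n, r = self.m, self.n, self.r
        if U.shape != (m, r):
            raise ValueError(f"U must be {m} x {r}, got {U.shape}")
        if V.shape != (n, r):
            raise ValueError(f"V must be {n} x {r}, got {V.shape}")
        if aux is None:
            aux = self.consistent_aux(U, V)
        parts = [U.ravel(order="F"), V.ravel(order="F")]
        if self.formulation == "F1":
            W = np.asarray(aux["W"])
            if W.shape != (m, n, r):
                raise ValueError(f"W must be {m} x {n} x {r}, got {W.shape}")
            W = as_binary_matrix(W.reshape(m, n * r), "W").reshape(m, n, r)
            parts.extend(W[:, :, k].ravel(order="F") for k in range(r))
        else:
            Ut = as_binary_matrix(aux["Utilde"], "Utilde")
            Vt = as_binary_matrix(aux["Vtilde"], "Vtilde")
            if Ut.shape != (m, r * r) or Vt.shape != (n, r * r):
                raise ValueError("auxiliary matrices have wrong shape")
            parts.append(Ut.ravel(order="F"))
            parts.append(Vt.ravel(order="F"))
        x = np.concatenate(parts)
        assert x.size == self.length
        return x

    def decode(self, x) -> tuple[np.ndarray, np.ndarray, dict]:
        """Inverse of :meth:`encode`: recover (U, V, aux) from a bitvector."""
        x = np.asarray(x)
        if x.ndim != 1 or x.size != self.length:
            raise ValueError(f"bitvector must have length {self.length}, got {x.size}")
        if not np.isin(x, (0, 1)).all():
            raise ValueError("bitvector entries must be 0 or 1")
        x = x.astype(np.int64)
        m, n, r = self.m, self.n, self.r
        U = x[: m * r].reshape(m, r, order="F")
        V = x[m * r : (m + n) * r].reshape(n, r, order="F")
        rest = x[(m + n) * r :]
        if self.formulation == "F1":
            W = np.empty((m, n, r), dtype=np.int64)
            for k in range(r):
                W[:, :, k] = rest[k * m * n : (k + 1) * m * n].reshape(m, n, order="F")
            return U, V, {"W": W}
        Ut = rest[: m * r * r].reshape(m, r * r, order="F")
        Vt = rest[m * r * r :].reshape(n, r * r, order="F")
        return U, V, {"Utilde": Ut, "Vtilde": Vt}

    def aux_violations(self, x) -> int:
        """Number of auxiliary entries that differ from the product they encode."""
        U, V, aux = self.decode(x)
        ref = self.consistent_aux(U, V)
        return int(sum(np.sum(aux[k] != ref[k]) for k in aux))
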