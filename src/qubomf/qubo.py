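"""QUBO assembly for binary matrix factorization.

A QUBO (quadratic unconstrained binary optimization) problem minimizes
``x^T Q x`` over bitvectors ``x``.  The quartic BMF objective is made
quadratic by introducing auxiliary variables for bit products, tied to their
definitions through the penalty ``f(a, b, c) = bc - 2ba - 2ca + 3a``:

* formulation F1 introduces ``w_ij^(k) = u_ik v_jk`` (one auxiliary per cell
  per factor), giving ``(m + n + mn) r`` variables;
* formulation F2 introduces ``utilde_i^(kk') = u_ik u_ik'`` and
  ``vtilde_j^(kk') = v_jk v_jk'``, giving ``(m + n)(r + r^2)`` variables.

Both store the constant ``||A||_F^2`` as an offset so that the energy of a
feasible encoding equals the BMF objective itself.  Coefficients are kept in
canonical upper-triangular form (diagonal = linear terms, since ``x^2 = x``),
with symmetric contributions folded, and are assembled sparsely from index
arithmetic so tall problems never materialize dense blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .core import PenaltyConfig, VariableLayout, as_binary_matrix

__all__ = [
    "QuboProblem",
    "build_formulation1",
    "build_formulation2",
    "clustering_penalty_block",
    "build_bls_qubo",
    "write_qubo",
    "read_qubo",
]


@dataclass
class QuboProblem:
    """A QUBO in canonical upper-triangular form.

    ``energy(x) = sum_{i <= j} q_ij x_i x_j + offset``.  The diagonal holds
    linear coefficients (``x^2 = x`` for bits).  ``target_energy``, when set,
    is an energy value certifying global optimality: a solver may stop as
    soon as it is reached.
    """

    n_vars: int
    coefficients: sp.csr_matrix
    offset: float
    layout: VariableLayout | None = None
    target_energy: float | None = None

    def __post_init__(self):
        if self.n_vars < 1:
            raise ValueError("a QUBO needs at least one variable")
        c = sp.csr_matrix(self.coefficients)
        if c.shape != (self.n_vars, self.n_vars):
            raise ValueError("coefficient matrix shape does not match n_vars")
        if sp.tril(c, k=-1).nnz:
            raise ValueError("coefficients must be upper triangular")
        self.coefficients = c

    @staticmethod
    def from_triplets(n_vars, rows, cols, vals, offset, layout=None, target_energy=None):
        """Build a canonical problem from (i, j, coeff) triplets.

        Lower-triangular entries are folded onto their upper mirror and
        duplicates are summed.  Integer-valued data stays in int64 so that
        energies of integer problems are exact.
        """
        rows = np.asarray(rows, dtype=np.int64)
        cols = np.asarray(cols, dtype=np.int64)
        vals = np.asarray(vals)
        lo = rows > cols
        rows2 = np.where(lo, cols, rows)
        cols2 = np.where(lo, rows, cols)
        if vals.size and np.all(vals == np.round(vals)):
            vals = vals.astype(np.int64)
            offset = int(offset) if float(offset).is_integer() else offset
        else:
            vals = vals.astype(np.float64)
        coo = sp.coo_matrix((vals, (rows2, cols2)), shape=(n_vars, n_vars))
        csr = coo.tocsr()
        csr.sum_duplicates()
        csr.eliminate_zeros()
        return QuboProblem(n_vars, csr, offset, layout, target_energy)

    def energy(self, x):
        """Evaluate ``x^T Q x + offset`` for a bitvector ``x``."""
        x = np.asarray(x)
        if x.ndim != 1 or x.size != self.n_vars:
            raise ValueError(f"assignment must have length {self.n_vars}")
        if not np.isin(x, (0, 1)).all():
            raise ValueError("assignment entries must be 0 or 1")
        x = x.astype(self.coefficients.dtype)
        val = x @ (self.coefficients @ x)
        if np.issubdtype(self.coefficients.dtype, np.integer):
            return int(val) + self.offset
        return float(val) + self.offset


def _f1_index_grids(m, n, r):
    K, J, I = np.meshgrid(
        np.arange(r), np.arange(n), np.arange(m), indexing="ij"
    )
    return K.ravel(), J.ravel(), I.ravel()


def build_formulation1(A, r: int, penalties: PenaltyConfig | None = None) -> QuboProblem:
    """Assemble the F1 QUBO for rank-``r`` BMF of binary ``A``.

    The energy of any bitvector equals the penalized objective

    ``||A||_F^2 - 2 sum_ijk a_ij w_ij^(k) + sum_ijkk' w_ij^(k) w_ij^(k')
    + lambda sum_ijk f(w_ij^(k), u_ik, v_jk)``

    (the constant entering through the offset), so feasible encodings --
    those with ``w = u v`` -- have energy exactly ``||A - U V^T||_F^2``.
    """
    A = as_binary_matrix(A, "A")
    if r < 1:
        raise ValueError("rank must be at least 1")
    pen = penalties if penalties is not None else PenaltyConfig()
    lam = pen.lambda_quad
    m, n = A.shape
    lay = VariableLayout("F1", m, n, r)

    K, J, I = _f1_index_grids(m, n, r)
    up = K * m + I
    vp = m * r + K * n + J
    wbase = (m + n) * r
    wp = wbase + K * (m * n) + J * m + I
    aval = A[I, J]

    rows = [wp, up, up, vp]
    cols = [wp, vp, wp, wp]
    vals = [1 + 3 * lam - 2 * aval, np.full(up.size, lam), np.full(up.size, -2 * lam), np.full(vp.size, -2 * lam)]

    # cross terms w^(k) w^(k') for k < k', same cell (i, j); the double sum
    # over ordered pairs contributes 2 per unordered pair
    Jg, Ig = np.meshgrid(np.arange(n), np.arange(m), indexing="ij")
    cell = Jg.ravel() * m + Ig.ravel()
    for k in range(r):
        for kp in range(k + 1, r):
            rows.append(wbase + k * m * n + cell)
            cols.append(wbase + kp * m * n + cell)
            vals.append(np.full(cell.size, 2))

    offset = int(A.sum())
    target = 0.0
    if pen.lambda_cluster is not None:
        crow, ccol, cval, coff = _cluster_triplets(m, n, r, pen.lambda_cluster)
        rows.append(crow)
        cols.append(ccol)
        vals.append(cval)
        offset = offset + coff
        target = None
    return QuboProblem.from_triplets(
        lay.length,
        np.concatenate(rows),
        np.concatenate(cols),
        np.concatenate([np.asarray(v, dtype=np.float64) for v in vals]),
        offset,
        layout=lay,
        target_energy=target,
    )


def build_formulation2(A, r: int, penalties: PenaltyConfig | None = None) -> QuboProblem:
    """Assemble the F2 QUBO for rank-``r`` BMF of binary ``A``.

    Auxiliaries are pairwise products within each factor.  Feasible
    encodings (``utilde``, ``vtilde`` consistent) have energy equal to
    ``||A - U V^T||_F^2``.
    """
    A = as_binary_matrix(A, "A")
    if r < 1:
        raise ValueError("rank must be at least 1")
    pen = penalties if penalties is not None else PenaltyConfig()
    lam = pen.lambda_quad
    m, n = A.shape
    lay = VariableLayout("F2", m, n, r)
    ut_base = (m + n) * r
    vt_base = ut_base + m * r * r

    rows, cols, vals = [], [], []

    # -2 sum_ijk a_ij u_ik v_jk over the nonzero cells of A
    nz_i, nz_j = A.nonzero()
    for k in range(r):
        rows.append(k * m + nz_i)
        cols.append(m * r + k * n + nz_j)
        vals.append(np.full(nz_i.size, -2))

    # + sum over all i, j and ordered pairs (k, k') of utilde_i vtilde_j
    ii = np.arange(m)
    jj = np.arange(n)
    Jg, Ig = np.meshgrid(jj, ii, indexing="ij")
    for c in range(r * r):
        rows.append(ut_base + c * m + Ig.ravel())
        cols.append(vt_base + c * n + Jg.ravel())
        vals.append(np.full(Ig.size, 1))

    # quadratization penalties lambda * f(aux, b, c) for both factors
    def add_factor_penalties(count, u_of, t_of):
        for k in range(r):
            for kp in range(r):
                c = kp * r + k
                t = t_of + c * count + np.arange(count)
                b = u_of + k * count + np.arange(count)
                cc = u_of + kp * count + np.arange(count)
                rows.append(t)
                cols.append(t)
                vals.append(np.full(count, 3 * lam))
                if k == kp:
                    # f(a, b, b) = b - 4ab + 3a
                    rows.append(b)
                    cols.append(b)
                    vals.append(np.full(count, lam))
                    rows.append(b)
                    cols.append(t)
                    vals.append(np.full(count, -4 * lam))
                else:
                    rows.append(b)
                    cols.append(cc)
                    vals.append(np.full(count, lam))
                    rows.append(b)
                    cols.append(t)
                    vals.append(np.full(count, -2 * lam))
                    rows.append(cc)
                    cols.append(t)
                    vals.append(np.full(count, -2 * lam))

    add_factor_penalties(m, 0, ut_base)
    add_factor_penalties(n, m * r, vt_base)

    offset = int(A.sum())
    target = 0.0
    if pen.lambda_cluster is not None:
        crow, ccol, cval, coff = _cluster_triplets(m, n, r, pen.lambda_cluster)
        rows.append(crow)
        cols.append(ccol)
        vals.append(cval)
        offset = offset + coff
        target = None
    return QuboProblem.from_triplets(
        lay.length,
        np.concatenate(rows),
        np.concatenate(cols),
        np.concatenate([np.asarray(v, dtype=np.float64) for v in vals]),
        offset,
        layout=lay,
        target_energy=target,
    )


def _cluster_triplets(m, n, r, lam):
    """Triplets (+ constant) of the one-hot penalty on the rows of V.

    Implements ``lam * sum_j (1 - sum_k v_jk + 2 sum_{k<k'} v_jk v_jk')``:
    zero when every row of V sums to 1, at least ``lam`` otherwise.  The
    constant ``lam * n`` is returned separately for folding into the offset.
    """
    rows, cols, vals = [], [], []
    jj = np.arange(n)
    for k in range(r):
        p = m * r + k * n + jj
        rows.append(p)
        cols.append(p)
        vals.append(np.full(n, -lam))
        for kp in range(k + 1, r):
            rows.append(p)
            cols.append(m * r + kp * n + jj)
            vals.append(np.full(n, 2 * lam))
    return (
        np.concatenate(rows),
        np.concatenate(cols),
        np.concatenate(vals),
        lam * n,
    )


def clustering_penalty_block(m: int, n: int, r: int, lambda_cluster: float):
    """One-hot clustering penalty as an ``(m+n)r x (m+n)r`` block.

    Returns ``(block, offset)`` where ``block`` acts on the ``[u; v]`` prefix
    of either formulation's decision vector (only the v-v region is nonzero)
    and ``offset`` is the folded constant ``lambda_cluster * n``.  Added
    energy is 0 when every row of V sums to 1 and >= ``lambda_cluster``
    otherwise.
    """
    if not lambda_cluster > 0:
        raise ValueError("lambda_cluster must be positive")
    rows, cols, vals, off = _cluster_triplets(m, n, r, lambda_cluster)
    block = sp.coo_matrix((vals, (rows, cols)), shape=((m + n) * r, (m + n) * r)).tocsr()
    return block, off


def build_bls_qubo(M, y) -> QuboProblem:
    """QUBO for the binary least-squares problem ``min_x ||M x - y||_2^2``.

    Coefficients are ``M^T M - 2 diag(y^T M)`` (upper-triangularized) with
    offset ``||y||^2``, so ``energy(x) = ||M x - y||^2`` for every bitvector.
    """
    M = np.asarray(M, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    if M.ndim != 2:
        raise ValueError("M must be 2-D")
    if M.shape[0] != y.size:
        raise ValueError(f"M has {M.shape[0]} rows but y has {y.size} entries")
    G = M.T @ M
    lin = y @ M
    n = M.shape[1]
    iu, ju = np.triu_indices(n, k=1)
    rows = np.concatenate([np.arange(n), iu])
    cols = np.concatenate([np.arange(n), ju])
    vals = np.concatenate([np.diag(G) - 2 * lin, 2 * G[iu, ju]])
    return QuboProblem.from_triplets(n, rows, cols, vals, float(y @ y))


def _fmt_num(v) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def write_qubo(problem: QuboProblem, path) -> None:
    """Write a problem in the coordinate text format.

    Line 1: ``n_vars offset``; then one ``i j coeff`` triplet per line
    (0-based, i <= j).  Integer coefficients round-trip bit-exactly.
    """
    coo = problem.coefficients.tocoo()
    with open(path, "w") as fh:
        fh.write(f"{problem.n_vars} {_fmt_num(problem.offset)}\n")
        for i, j, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{i} {j} {_fmt_num(v)}\n")


def read_qubo(path) -> QuboProblem:
    """Read a problem written by :func:`write_qubo`."""

    def _num(tok):
        return int(tok) if tok.lstrip("+-").isdigit() else float(tok)

    with open(path) as fh:
        lines = fh.readlines()
    if not lines:
        raise ValueError(f"{path}: empty QUBO file")
    head = lines[0].split()
    if len(head) != 2:
        raise ValueError(f"{path}:1: expected 'n_vars offset'")
    try:
        n_vars = int(head[0])
        offset = _num(head[1])
    except ValueError as exc:
        raise ValueError(f"{path}:1: malformed header") from exc
    rows, cols, vals = [], [], []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 3:
            raise ValueError(f"{path}:{lineno}: expected 'i j coeff'")
        try:
            i, j, v = int(parts[0]), int(parts[1]), _num(parts[2])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed triplet") from exc
        if not (0 <= i <= j < n_vars):
            raise ValueError(f"{path}:{lineno}: index out of range or not upper-triangular")
        rows.append(i)
        cols.append(j)
        vals.append(v)
    return QuboProblem.from_triplets(n_vars, rows, cols, np.asarray(vals), offset)
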