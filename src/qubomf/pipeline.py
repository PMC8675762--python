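"""End-to-end factorization pipeline.

For a tall binary matrix (m >> n) the QUBO would need (m + n + mn) r
variables, far beyond what an annealer-style solver handles comfortably.
The pipeline instead samples s << m rows with replacement according to the
matrix's leverage scores (squared row norms of an orthonormal basis of the
column space, normalized by the rank), factorizes the small sampled matrix,
keeps its V, and lifts U back to all m rows by solving m independent binary
least-squares (BLS) problems over the 2^r candidate rows.  An optional
alternating-BLS refinement then polishes (U, V).

Also here: the density baseline, a deliberately crude reference method that
picks the best of three cheap candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .anneal import AnnealConfig, solve_parallel_tempering, solve_sa
from .core import (
    FactorPair,
    PenaltyConfig,
    as_binary_matrix,
    bmf_objective,
    relative_error,
)
from .qubo import build_formulation1, build_formulation2

__all__ = [
    "LeveragePlan",
    "AlsState",
    "leverage_scores",
    "sample_rows",
    "bls_lift",
    "als_refine",
    "factorize",
    "baseline_bmf",
]

BLS_EXHAUSTIVE_MAX_RANK = 10


@dataclass
class LeveragePlan:
    """Leverage scores and the induced row-sampling distribution.

    ``scores[i]`` is the squared i-th row norm of an orthonormal basis of
    range(A); scores lie in [0, 1] and sum to the numerical rank.
    ``probabilities = scores / rank`` sum to 1.  ``sampled_indices`` is a
    multiset (sampling is with replacement); it is ``None`` until rows are
    drawn.
    """

    scores: np.ndarray
    probabilities: np.ndarray
    numerical_rank: int
    sample_size: int | None = None
    sampled_indices: np.ndarray | None = None


@dataclass
class AlsState:
    """Result of alternating-BLS refinement."""

    U: np.ndarray
    V: np.ndarray
    objective_history: list
    solves_used: int


def leverage_scores(A) -> LeveragePlan:
    """Leverage scores of ``A`` via the SVD.

    The numerical rank counts singular values above
    ``max(m, n) * eps * sigma_1`` (the standard rank tolerance).
    """
    Af = np.asarray(A, dtype=np.float64)
    if Af.ndim != 2 or Af.size == 0:
        raise ValueError("A must be a nonempty 2-D matrix")
    if not Af.any():
        raise ValueError("leverage scores are undefined for an all-zero matrix")
    B, s, _ = np.linalg.svd(Af, full_matrices=False)
    tol = max(Af.shape) * np.finfo(np.float64).eps * s[0]
    rank = int((s > tol).sum())
    basis = B[:, :rank]
    scores = (basis * basis).sum(axis=1)
    probs = scores / scores.sum()
    return LeveragePlan(scores=scores, probabilities=probs, numerical_rank=rank)


def sample_rows(A, s: int, rng, plan: LeveragePlan | None = None):
    """Draw ``s`` rows of ``A`` i.i.d. from the leverage-score distribution.

    Sampling is with replacement; duplicates are retained.  Returns the
    ``s x n`` sampled matrix and the drawn row indices.
    """
    A = np.asarray(A)
    if s < 1:
        raise ValueError("sample size must be at least 1")
    rng = np.random.default_rng(rng)
    if plan is None:
        plan = leverage_scores(A)
    idx = rng.choice(A.shape[0], size=s, replace=True, p=plan.probabilities)
    plan.sample_size = s
    plan.sampled_indices = idx
    return A[idx], idx


def _bls_candidates(r: int) -> np.ndarray:
    """All 2^r binary rows in lexicographic order (first bit most significant)."""
    codes = np.arange(1 << r)
    return ((codes[:, None] >> (r - 1 - np.arange(r))) & 1).astype(np.int64)


def bls_lift(A, V, exhaustive_max_rank: int = BLS_EXHAUSTIVE_MAX_RANK) -> np.ndarray:
    """Optimal binary U for fixed V: ``argmin_U ||A - U V^T||_F^2``.

    The problem separates into one r-variable BLS problem per row of A.  For
    r up to ``exhaustive_max_rank`` every candidate row is tested (exactly
    optimal, ties broken toward the lexicographically smallest row); above
    that each row is solved as a small QUBO by exhaustive enumeration or
    annealing.
    """
    A = as_binary_matrix(A, "A")
    V = as_binary_matrix(V, "V")
    if A.shape[1] != V.shape[0]:
        raise ValueError(f"A has {A.shape[1]} columns but V has {V.shape[0]} rows")
    r = V.shape[1]
    if r <= exhaustive_max_rank:
        C = _bls_candidates(r)
        P = C @ V.T  # (2^r, n) candidate reconstructions
        a2 = (A * A).sum(axis=1)
        p2 = (P * P).sum(axis=1)
        err = a2[:, None] + p2[None, :] - 2 * (A @ P.T)
        pick = err.argmin(axis=1)  # argmin keeps the first (lex smallest) tie
        return C[pick]
    # QUBO fallback for wide ranks: one annealed BLS per row
    from .qubo import build_bls_qubo
    from .anneal import brute_force_min

    U = np.empty((A.shape[0], r), dtype=np.int64)
    for i in range(A.shape[0]):
        prob = build_bls_qubo(V, A[i])
        if r <= 25:
            res = brute_force_min(prob)
        else:
            res = solve_sa(prob, AnnealConfig(total_flips=20_000, restarts=3, seed=i))
        U[i] = res.best_assignment
    return U


def als_refine(A, U, V, max_solves: int = 20) -> AlsState:
    """Alternating BLS refinement of an initial factor pair.

    One "solve" updates one full factor by exact BLS, starting with V.  The
    objective is non-increasing; iteration stops after ``max_solves`` solves
    or as soon as two consecutive solves bring no strict improvement.
    """
    A = as_binary_matrix(A, "A")
    U = as_binary_matrix(U, "U")
    V = as_binary_matrix(V, "V")
    history = [bmf_objective(A, U, V)]
    solves = 0
    no_improvement = 0
    while solves < max_solves and no_improvement < 2:
        if solves % 2 == 0:
            V = bls_lift(A.T, U)
        else:
            U = bls_lift(A, V)
        solves += 1
        obj = bmf_objective(A, U, V)
        no_improvement = 0 if obj < history[-1] else no_improvement + 1
        history.append(obj)
    return AlsState(U=U, V=V, objective_history=history, solves_used=solves)


def _derived_seed(seed_seq) -> int:
    return int(seed_seq.generate_state(1)[0] & 0x7FFFFFFF)


def factorize(
    A,
    r: int,
    *,
    formulation: int = 1,
    penalties: PenaltyConfig | None = None,
    anneal: AnnealConfig | None = None,
    sample_size: int | None = None,
    do_als: bool = True,
    seed: int | None = None,
):
    """Rank-``r`` BMF of ``A`` through the full QUBO pipeline.

    Runs ``anneal.restarts`` independent annealing runs (each with its own
    stream derived from the seed); every run is decoded, optionally lifted
    to the full row set when sampling is active, optionally refined by
    alternating BLS, and the candidate with the lowest objective is
    returned.  Iteration stops early once an exact factorization (error 0)
    is found.

    Returns ``(FactorPair, report)`` where the report carries the relative
    error, solver energies, seeds, and the count of auxiliary-constraint
    violations in the best raw solver state (expected to be 0 at the default
    penalty weight; a nonzero count flags an infeasible decoding that the
    lift/refinement steps then repair).
    """
    A = as_binary_matrix(A, "A")
    if int(A.sum()) == 0:
        raise ValueError("cannot factorize an all-zero matrix")
    if r < 1:
        raise ValueError("rank must be at least 1")
    pen = penalties if penalties is not None else PenaltyConfig()
    # Default solver for the full pipeline: parallel tempering.  At the weak
    # default penalty weight the landscape has broad plateaus where plain
    # annealing stalls at desk budgets; a replica ladder crosses them.
    cfg = anneal if anneal is not None else AnnealConfig(replicas=5, exchange_interval=2_000)
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    root = np.random.SeedSequence(cfg.seed)
    sample_ss, solver_ss = root.spawn(2)

    indices = None
    if sample_size is not None:
        plan = leverage_scores(A)
        A_work, indices = sample_rows(A, sample_size, np.random.default_rng(sample_ss), plan)
        A_work = as_binary_matrix(A_work, "sampled A")
    else:
        A_work = A

    build = build_formulation1 if formulation == 1 else build_formulation2
    if formulation not in (1, 2):
        raise ValueError("formulation must be 1 or 2")
    problem = build(A_work, r, pen)
    solver = solve_parallel_tempering if cfg.replicas > 1 else solve_sa

    best = None
    runs = []
    for restart in range(cfg.restarts):
        run_cfg = replace(
            cfg,
            restarts=1,
            seed=_derived_seed(np.random.SeedSequence(
                entropy=solver_ss.entropy, spawn_key=solver_ss.spawn_key + (restart,)
            )),
        )
        res = solver(problem, run_cfg)
        U_w, V, _ = problem.layout.decode(res.best_assignment)
        violations = problem.layout.aux_violations(res.best_assignment)
        U = bls_lift(A, V) if sample_size is not None else U_w
        als_info = None
        if do_als:
            state = als_refine(A, U, V)
            U, V = state.U, state.V
            als_info = {
                "objective_history": state.objective_history,
                "solves_used": state.solves_used,
            }
        obj = bmf_objective(A, U, V)
        runs.append(
            {
                "seed": run_cfg.seed,
                "energy": res.best_energy,
                "flips_used": res.flips_used,
                "terminated_by": res.terminated_by,
                "objective": obj,
                "feasibility_violations": violations,
                "als": als_info,
            }
        )
        if best is None or obj < best[0]:
            best = (obj, U, V, runs[-1])
        if obj == 0:
            break

    obj, U, V, best_run = best
    report = {
        "relative_error": relative_error(A, U, V),
        "objective": obj,
        "nnz": int(A.sum()),
        "rank": r,
        "formulation": formulation,
        "lambda_quad": pen.lambda_quad,
        "lambda_cluster": pen.lambda_cluster,
        "n_vars": problem.n_vars,
        "offset": problem.offset,
        "seed": cfg.seed,
        "sample_size": sample_size,
        "sampled_indices": None if indices is None else [int(i) for i in indices],
        "best_energy": best_run["energy"],
        "feasibility_violations": best_run["feasibility_violations"],
        "runs": runs,
    }
    return FactorPair(U, V), report


def baseline_bmf(A, r: int) -> FactorPair:
    """Density baseline: the best of three cheap rank-``r`` candidates.

    (a) densest columns: the r columns with the largest sums (ties toward
        the lowest index) copied into U, with V the column-selection
        indicator -- reproduces those columns exactly and nothing else;
    (b) densest rows: the symmetric construction;
    (c) all-ones rank-1: U and V each have an all-ones first column and
        zeros elsewhere, approximating a high-density matrix by 1s
        everywhere.

    The candidate with the smallest relative error wins (first on ties).
    """
    A = as_binary_matrix(A, "A")
    if int(A.sum()) == 0:
        raise ValueError("baseline is undefined for an all-zero matrix")
    m, n = A.shape
    if r < 1:
        raise ValueError("rank must be at least 1")
    candidates = []

    if r <= n:
        col_order = np.argsort(-A.sum(axis=0), kind="stable")[:r]
        U = A[:, col_order]
        V = np.zeros((n, r), dtype=np.int64)
        V[col_order, np.arange(r)] = 1
        candidates.append(FactorPair(U, V))

    if r <= m:
        row_order = np.argsort(-A.sum(axis=1), kind="stable")[:r]
        V = A[row_order, :].T
        U = np.zeros((m, r), dtype=np.int64)
        U[row_order, np.arange(r)] = 1
        candidates.append(FactorPair(U, V))

    U = np.zeros((m, r), dtype=np.int64)
    V = np.zeros((n, r), dtype=np.int64)
    U[:, 0] = 1
    V[:, 0] = 1
    candidates.append(FactorPair(U, V))

    errors = [relative_error(A, fp.U, fp.V) for fp in candidates]
    return candidates[int(np.argmin(errors))]
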