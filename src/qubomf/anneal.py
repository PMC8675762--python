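"""Classical QUBO solvers: simulated annealing, parallel tempering, brute force.

The annealer is a seeded single-bit-flip Metropolis sampler with cached
local fields: the energy change of flipping variable ``i`` is read in
constant time from ``(1 - 2 x_i) * local_i`` where
``local_i = h_i + sum_j J_ij x_j``, and an accepted flip updates only the
fields of variables coupled to the flipped one.  Temperatures follow a
geometric schedule.  Parallel tempering runs a ladder of constant-
temperature replicas with periodic neighbor swaps accepted by the standard
replica-exchange criterion.

All randomness flows from one seed through ``numpy.random.SeedSequence``;
identical configuration implies an identical result, bit for bit.  The hot
loops are JIT-compiled with numba.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from numba import njit

from .qubo import QuboProblem

__all__ = [
    "AnnealConfig",
    "SolveResult",
    "solve_sa",
    "solve_parallel_tempering",
    "brute_force_min",
]

BRUTE_FORCE_GUARD = 25


@dataclass(frozen=True)
class AnnealConfig:
    """Solver configuration.

    total_flips
        Single-bit-flip proposals per restart (per replica for parallel
        tempering).  Default 10^6, a desk-scale budget.
    t_start, t_end
        Geometric temperature schedule endpoints.  ``None`` defaults to the
        largest absolute coefficient of the problem and 10^-3 times that,
        respectively; equal values give a constant-temperature chain.
    restarts
        Independent runs from fresh random states; the best incumbent wins
        (earlier incumbent kept on ties).
    replicas
        1 = plain annealing; >= 2 enables parallel tempering with a
        geometric temperature ladder between t_end and t_start.
    exchange_interval
        Flips between replica-swap attempts.
    target_energy
        Stop as soon as the best energy (offset included) reaches this value;
        overrides the problem's own certificate when set.
    """

    total_flips: int = 1_000_000
    t_start: float | None = None
    t_end: float | None = None
    restarts: int = 5
    replicas: int = 1
    exchange_interval: int = 1_000
    seed: int = 0
    target_energy: float | None = None

    def __post_init__(self):
        if self.total_flips < 1:
            raise ValueError("total_flips must be at least 1")
        if self.restarts < 1:
            raise ValueError("restarts must be at least 1")
        if self.replicas < 1:
            raise ValueError("replicas must be at least 1")
        if self.exchange_interval < 1:
            raise ValueError("exchange_interval must be at least 1")
        if self.t_start is not None and self.t_end is not None:
            if not (self.t_start >= self.t_end > 0):
                raise ValueError("need t_start >= t_end > 0")


@dataclass
class SolveResult:
    """Outcome of a solver run.

    ``best_energy`` includes the problem offset and always equals
    ``problem.energy(best_assignment)`` re-evaluated from scratch.  The
    trace holds ``(flip index, best-so-far energy)`` pairs and is
    non-increasing in energy.
    """

    best_assignment: np.ndarray
    best_energy: float
    flips_used: int
    trace: list = field(default_factory=list)
    terminated_by: str = "budget"
    seed: int = 0


# ----------------------------------------------------------------------
# kernels
# ----------------------------------------------------------------------
@njit(cache=True)
def _initial_state(indptr, indices, data, h, x):
    n = x.size
    local = h.copy()
    for i in range(n):
        if x[i] == 1:
            for p in range(indptr[i], indptr[i + 1]):
                local[indices[p]] += data[p]
    e = 0.0
    for i in range(n):
        if x[i] == 1:
            e += h[i] + 0.5 * (local[i] - h[i])
    return local, e


@njit(cache=True)
def _sa_kernel(indptr, indices, data, h, x, t0, ratio, nflips, var_choice,
               accept_u, target, trace_idx, trace_e):
    local, e = _initial_state(indptr, indices, data, h, x)
    best_e = e
    best_x = x.copy()
    nt = 0
    trace_idx[nt] = 0
    trace_e[nt] = e
    nt += 1
    if best_e <= target:
        return best_e, best_x, nt, 0, True
    T = t0
    for t in range(nflips):
        i = var_choice[t]
        delta = (1.0 - 2.0 * x[i]) * local[i]
        if delta <= 0.0 or accept_u[t] < np.exp(-delta / T):
            s = 1.0 - 2.0 * x[i]
            x[i] = 1 - x[i]
            e += delta
            for p in range(indptr[i], indptr[i + 1]):
                local[indices[p]] += s * data[p]
            if e < best_e:
                best_e = e
                best_x[:] = x
                trace_idx[nt] = t + 1
                trace_e[nt] = e
                nt += 1
                if best_e <= target:
                    return best_e, best_x, nt, t + 1, True
        T *= ratio
    return best_e, best_x, nt, nflips, False


@njit(cache=True)
def _pt_kernel(indptr, indices, data, h, X, temps, rounds, per_round,
               var_choice, accept_u, swap_u, target, trace_idx, trace_e):
    R, n = X.shape
    locals_ = np.empty((R, n))
    energies = np.empty(R)
    for a in range(R):
        la, ea = _initial_state(indptr, indices, data, h, X[a])
        locals_[a] = la
        energies[a] = ea
    best_e = energies[0]
    best_x = X[0].copy()
    for a in range(R):
        if energies[a] < best_e:
            best_e = energies[a]
            best_x[:] = X[a]
    nt = 0
    trace_idx[nt] = 0
    trace_e[nt] = best_e
    nt += 1
    if best_e <= target:
        return best_e, best_x, nt, 0, True
    flips_done = 0
    for rd in range(rounds):
        for a in range(R):
            T = temps[a]
            base = rd * per_round
            for t in range(per_round):
                i = var_choice[a, base + t]
                delta = (1.0 - 2.0 * X[a, i]) * locals_[a, i]
                if delta <= 0.0 or accept_u[a, base + t] < np.exp(-delta / T):
                    s = 1.0 - 2.0 * X[a, i]
                    X[a, i] = 1 - X[a, i]
                    energies[a] += delta
                    for p in range(indptr[i], indptr[i + 1]):
                        locals_[a, indices[p]] += s * data[p]
                    if energies[a] < best_e:
                        best_e = energies[a]
                        best_x[:] = X[a]
                        trace_idx[nt] = flips_done + a * per_round + t + 1
                        trace_e[nt] = best_e
                        nt += 1
                        if best_e <= target:
                            return best_e, best_x, nt, flips_done + per_round * (a + 1), True
        flips_done += R * per_round
        # neighbor swaps, alternating parity; exchange criterion
        # min(1, exp((1/T_a - 1/T_b)(E_a - E_b)))
        for a in range(rd % 2, R - 1, 2):
            b = a + 1
            arg = (1.0 / temps[a] - 1.0 / temps[b]) * (energies[a] - energies[b])
            if arg >= 0.0 or swap_u[rd, a] < np.exp(arg):
                for q in range(n):
                    tmp = X[a, q]
                    X[a, q] = X[b, q]
                    X[b, q] = tmp
                    tmpl = locals_[a, q]
                    locals_[a, q] = locals_[b, q]
                    locals_[b, q] = tmpl
                te = energies[a]
                energies[a] = energies[b]
                energies[b] = te
    return best_e, best_x, nt, flips_done, False


@njit(cache=True)
def _bf_kernel(indptr, indices, data, h, n):
    x = np.zeros(n, dtype=np.int8)
    local = h.copy()
    e = 0.0
    best_e = 0.0
    best_code = np.int64(0)  # bit (n-1-i) of the code holds x_i: integer order = lex order
    code = np.int64(0)
    total = np.int64(1) << n
    step = np.int64(1)
    while step < total:
        s = step
        i = 0
        while s & 1 == 0:
            s >>= 1
            i += 1
        delta = (1.0 - 2.0 * x[i]) * local[i]
        sgn = 1.0 - 2.0 * x[i]
        x[i] = 1 - x[i]
        e += delta
        for p in range(indptr[i], indptr[i + 1]):
            local[indices[p]] += sgn * data[p]
        code ^= np.int64(1) << (n - 1 - i)
        if e < best_e or (e == best_e and code < best_code):
            best_e = e
            best_code = code
        step += 1
    return best_e, best_code


# ----------------------------------------------------------------------
# drivers
# ----------------------------------------------------------------------
def _solver_arrays(problem: QuboProblem):
    """Symmetric CSR couplings plus linear field from the canonical form."""
    q = problem.coefficients.tocoo()
    off = q.row != q.col
    J = sp.coo_matrix(
        (
            np.concatenate([q.data[off], q.data[off]]).astype(np.float64),
            (
                np.concatenate([q.row[off], q.col[off]]),
                np.concatenate([q.col[off], q.row[off]]),
            ),
        ),
        shape=(problem.n_vars, problem.n_vars),
    ).tocsr()
    J.sum_duplicates()
    h = np.zeros(problem.n_vars, dtype=np.float64)
    diag = ~off
    h[q.row[diag]] = q.data[diag]
    return J.indptr, J.indices, J.data.astype(np.float64), h


def _temps(problem, config):
    data = problem.coefficients.data
    scale = float(np.abs(data).max()) if data.size else 1.0
    if scale == 0.0:
        scale = 1.0
    t0 = config.t_start if config.t_start is not None else scale
    t1 = config.t_end if config.t_end is not None else 1e-3 * t0
    if not (t0 >= t1 > 0):
        raise ValueError("need t_start >= t_end > 0")
    return t0, t1


def _raw_target(problem, config):
    tgt = config.target_energy
    if tgt is None:
        tgt = problem.target_energy
    if tgt is None:
        return -np.inf
    return float(tgt) - float(problem.offset)


def restart_streams(config: AnnealConfig, n_vars: int, restart: int):
    """Random streams for one restart: initial state, proposals, uniforms.

    Exposed so that a straight-line reference implementation can replay the
    solver's exact random sequence.
    """
    ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(restart,))
    rng = np.random.default_rng(ss)
    x0 = rng.integers(0, 2, n_vars).astype(np.int8)
    var_choice = rng.integers(0, n_vars, config.total_flips).astype(np.int64)
    accept_u = rng.random(config.total_flips)
    return x0, var_choice, accept_u


def solve_sa(problem: QuboProblem, config: AnnealConfig | None = None) -> SolveResult:
    """Simulated annealing with restarts; deterministic given (problem, config)."""
    config = config if config is not None else AnnealConfig()
    n = problem.n_vars
    if n < 1:
        raise ValueError("empty problem")
    indptr, indices, data, h = _solver_arrays(problem)
    t0, t1 = _temps(problem, config)
    ratio = (t1 / t0) ** (1.0 / max(config.total_flips - 1, 1))
    target = _raw_target(problem, config)

    best_e = np.inf
    best_x = None
    trace = []
    flips_total = 0
    terminated = "budget"
    cap = config.total_flips + 1
    trace_idx = np.empty(cap, dtype=np.int64)
    trace_e = np.empty(cap, dtype=np.float64)
    for restart in range(config.restarts):
        x0, var_choice, accept_u = restart_streams(config, n, restart)
        e, x, nt, used, hit = _sa_kernel(
            indptr, indices, data, h, x0, t0, ratio, config.total_flips,
            var_choice, accept_u, target, trace_idx, trace_e,
        )
        for q in range(nt):
            if trace_e[q] < best_e or (best_x is None and q == 0):
                trace.append((flips_total + int(trace_idx[q]), float(trace_e[q]) + problem.offset))
        flips_total += used
        if e < best_e:
            best_e = e
            best_x = x.copy()
        elif best_x is None:
            best_x = x.copy()
        if hit:
            terminated = "target"
            break
    best_x = best_x.astype(np.int8)
    energy = problem.energy(best_x)
    # keep the monotone best-so-far envelope exact
    trace = _monotone(trace)
    return SolveResult(best_x, energy, flips_total, trace, terminated, config.seed)


def _monotone(trace):
    out = []
    best = np.inf
    for idx, e in trace:
        if e < best or not out:
            best = min(best, e)
            out.append((idx, best))
    return out


def solve_parallel_tempering(problem: QuboProblem, config: AnnealConfig) -> SolveResult:
    """Replica-exchange annealing; requires ``config.replicas >= 2``.

    Each replica runs at a fixed temperature from a geometric ladder between
    ``t_end`` (cold) and ``t_start`` (hot); neighbor swaps are attempted
    every ``exchange_interval`` flips.  ``total_flips`` is the per-replica
    budget (truncated to whole exchange rounds).
    """
    if config.replicas < 2:
        raise ValueError("parallel tempering needs at least 2 replicas")
    n = problem.n_vars
    if n < 1:
        raise ValueError("empty problem")
    indptr, indices, data, h = _solver_arrays(problem)
    t0, t1 = _temps(problem, config)
    R = config.replicas
    if t0 == t1:
        temps = np.full(R, t0)
    else:
        temps = t1 * (t0 / t1) ** (np.arange(R) / (R - 1))
    target = _raw_target(problem, config)
    per_round = min(config.exchange_interval, config.total_flips)
    rounds = max(config.total_flips // per_round, 1)
    nflips = rounds * per_round

    best_e = np.inf
    best_x = None
    trace = []
    flips_total = 0
    terminated = "budget"
    cap = R * nflips + 1
    trace_idx = np.empty(cap, dtype=np.int64)
    trace_e = np.empty(cap, dtype=np.float64)
    for restart in range(config.restarts):
        ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(restart,))
        rng = np.random.default_rng(ss)
        X = rng.integers(0, 2, (R, n)).astype(np.int8)
        var_choice = rng.integers(0, n, (R, nflips)).astype(np.int64)
        accept_u = rng.random((R, nflips))
        swap_u = rng.random((rounds, R))
        e, x, nt, used, hit = _pt_kernel(
            indptr, indices, data, h, X, temps, rounds, per_round,
            var_choice, accept_u, swap_u, target, trace_idx, trace_e,
        )
        for q in range(nt):
            if trace_e[q] < best_e or (best_x is None and q == 0):
                trace.append((flips_total + int(trace_idx[q]), float(trace_e[q]) + problem.offset))
        flips_total += used
        if e < best_e:
            best_e = e
            best_x = x.copy()
        elif best_x is None:
            best_x = x.copy()
        if hit:
            terminated = "target"
            break
    best_x = best_x.astype(np.int8)
    energy = problem.energy(best_x)
    trace = _monotone(trace)
    return SolveResult(best_x, energy, flips_total, trace, terminated, config.seed)


def brute_force_min(problem: QuboProblem) -> SolveResult:
    """Exact global minimum by Gray-code enumeration of all ``2^n`` states.

    Guarded to ``n_vars <= 25``.  Ties are broken toward the
    lexicographically smallest bitvector (``x_0`` most significant).
    """
    n = problem.n_vars
    if n > BRUTE_FORCE_GUARD:
        raise ValueError(
            f"brute force refused: {n} variables exceeds the guard of {BRUTE_FORCE_GUARD}"
        )
    indptr, indices, data, h = _solver_arrays(problem)
    best_raw, best_code = _bf_kernel(indptr, indices, data, h, n)
    x = np.zeros(n, dtype=np.int8)
    for i in range(n):
        if (int(best_code) >> (n - 1 - i)) & 1:
            x[i] = 1
    energy = problem.energy(x)
    return SolveResult(
        x, energy, (1 << n) - 1, [((1 << n) - 1, energy)], "exhaustive", 0
    )
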