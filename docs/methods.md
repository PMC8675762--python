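# Methods

## Model

Rank-r binary matrix factorization (BMF) minimizes ‖A − UVᵀ‖²_F over
U ∈ {0,1}^(m×r), V ∈ {0,1}^(n×r) with standard integer inner products
(not Boolean OR, not GF(2)). Expanding the norm gives

    ‖A‖²_F − 2 Σ_ijk a_ij u_ik v_jk + Σ_ijkk′ u_ik u_ik′ v_jk v_jk′ ,

quartic in the decision bits. Two quadratizations make it a QUBO:

* **F1** introduces w_ij^(k) for the product u_ik·v_jk. The objective in
  (u, v, w) is quadratic once each quartic term is rewritten through w;
  the decision vector [u; v; w^(1); …; w^(r)] (column-major within each
  matrix) has (m + n + mn)r entries.
* **F2** introduces pairwise within-factor products ũ_i^(kk′) = u_ik·u_ik′
  and ṽ_j^(kk′) = v_jk·v_jk′; the vector [u; v; ũ; ṽ] has
  (m + n)(r + r²) entries. F2 needs far fewer variables for small r on
  large matrices, but F1 has consistently produced lower energies per
  flip budget in our runs, so F1 is the pipeline default.

Each auxiliary a standing for a product b·c is tied to it by
λ·f(a, b, c) with f(a,b,c) = bc − 2ba − 2ca + 3a, which is 0 exactly when
a = bc and ≥ 1 otherwise. For λ > 2r‖A‖²_F every minimizer of the
penalized quadratic is feasible and minimizes the original objective
(`safe_penalty_weight` returns the smallest integer above the bound, and
the oracle tests enumerate both QUBO and factorization spaces to confirm
the equivalence). The constant ‖A‖²_F is stored as the QUBO offset, so the
energy of a feasible encoding *is* the factorization objective and energy
0 certifies an exact factorization (`target_energy = 0` enables early
stopping; it is unset when the clustering penalty shifts the optimum).

**Default λ = 1.** The safe bound makes the landscape so steep that local
search stalls; a unit weight keeps penalty and data terms on the same
scale. The price is that the annealer's raw state may violate product
constraints. Violations are counted and reported, and the pipeline's BLS
lift / ALS refinement steps operate on the decoded (U, V) only, so the
returned factors are always feasible regardless.

## Clustering constraint

Requiring each row of V to sum to 1 (each sample in exactly one cluster)
is added as λ_c Σ_j (1 − Σ_k v_jk + 2 Σ_{k<k′} v_jk v_jk′), zero at
one-hot rows and ≥ λ_c otherwise; the constant λ_c·n is folded into the
offset so the satisfied case contributes exactly 0. Exhaustive
minimization on small instances confirms that with λ_c above the safe
bound every global minimizer decodes to a one-hot V.

## Solver

Single-bit-flip Metropolis with cached local fields: local_i = h_i +
Σ_j J_ij x_j is maintained incrementally, so proposing a flip costs O(1)
and accepting one costs O(degree). The schedule is geometric from
T_start = max|coefficient| down to T_end = 10⁻³·T_start over the flip
budget (defaults: 10⁶ flips, 5 restarts). All randomness flows from one
`SeedSequence`; restart and replica streams are spawned children, so a
run is bit-reproducible from its configuration. Ties between equal-energy
incumbents keep the earlier one.

**Parallel tempering** runs a geometric ladder of constant-temperature
replicas with neighbor swaps every `exchange_interval` flips, accepted
with min(1, exp((1/T_a − 1/T_b)(E_a − E_b))). The full factorization
pipeline defaults to tempering with 5 replicas: at λ = 1 the landscape has
broad plateaus (flipping any single bit of a half-consistent auxiliary
block is uphill) where a single cooling chain freezes; the test suite
contains a planted double-well on which tempering reaches the optimum at
a budget where plain annealing fails roughly half the time. The hardware
trick of rejection-free sampling is deliberately out of scope — only
solution quality is compared, never iteration counts.

`brute_force_min` enumerates all 2^n states in Gray-code order with O(1)
incremental energy updates (guarded to n ≤ 25, ties toward the
lexicographically smallest bitvector) and serves as the independent
oracle throughout the tests.

## Tall matrices

For m ≫ n the QUBO is built on a sampled matrix instead. Leverage scores
l_i = ‖B_i∗‖² (B an orthonormal basis of range(A) from the SVD; numerical
rank counts singular values above max(m,n)·eps·σ₁) define p_i = l_i/rank;
s rows are drawn with replacement. The sampled matrix keeps the dominant
row patterns with high probability, V is taken from its factorization,
and U is recovered row by row: each row of U is an independent r-variable
binary least-squares problem, solved exactly by testing all 2^r
candidates (up to r = 10; a per-row QUBO fallback exists above that,
though practical use stays at r ≤ 5). Ties go to the lexicographically
smallest candidate row.

**ALS refinement**: alternate exact one-factor BLS solves, V first. One
"solve" updates one factor, so the objective is non-increasing by
construction; refinement stops at 20 solves or after two consecutive
solves without strict improvement. Counting half-sweeps (one factor per
solve) makes the two-consecutive rule meaningful: a full U+V sweep
without improvement is exactly two idle solves.

`factorize` runs `restarts` independent solver runs, decodes each, lifts
and refines each, and returns the candidate with the lowest objective,
stopping early on an exact factorization. Refining every restart rather
than only the lowest-energy one costs little (ALS is cheap relative to
annealing) and guards against the case where a slightly higher-energy
state decodes to a better basin.

## Baseline

The density baseline evaluates three explicit candidates and returns the
lowest-error one: (a) the r densest columns copied into U with V the
selection indicator, (b) the symmetric densest-rows construction, (c) the
all-ones rank-1 pair padded with zero columns. On sparse matrices (a)/(b)
win and the error falls with r; on dense matrices (c) wins and the error
is the zeros-to-ones ratio, independent of r — which is why its error is
constant across ranks on Bernoulli(0.8) draws.

## Synthetic data

* **Planted**: U has one-hot rows (uniform factor choice), V entries are
  i.i.d. Bernoulli(0.5); draws are rejected until every factor is used by
  at least one row of U and has a nonzero column in V, and A ≠ 0. One-hot
  rows make the rank-1 blocks row-disjoint, so A = UVᵀ is automatically
  binary and an exact rank-≤r factorization exists by construction. This
  emulates the "an exact factorization exists and should be found"
  regime; it does *not* emulate overlapping block supports, correlated
  noise, or the heavy-tailed structure of real discretized expression
  data. Passing the planted tests shows exact recovery of idealized
  disjoint-block structure, not performance on real matrices.
* **Bernoulli(p)**: i.i.d. entries at p ∈ {0.2, 0.5, 0.8} probe the
  unstructured regime where no good low-rank factorization exists.

## Discretization

For a nonnegative expression matrix, κ is the global mean and entries
with a_ij ≤ κ·c₁ or a_ij ≥ κ·c₂ become 1 (0 ≤ c₁ < c₂); all-zero rows
are dropped and the surviving original row indices returned. Optional
preprocessing: shift by −min (for data with negative values) and/or
column normalization to unit Euclidean norm; κ is computed *after* both
steps, matching the shift → normalize → threshold pipeline order.
Normalizing an all-zero column is a no-op. Two presets ship:
c₁ = 1/7, c₂ = 5 without normalization (two-class leukemia data), and
shift + normalize with c₁ = 0.96, c₂ = 1.04 (melanoma cDNA data).

## Numerical choices

* Binary matrices are int64 end to end; QUBO coefficients stay int64
  whenever the penalty weights are integral, so energy identities in the
  tests are exact equalities, not approximate ones.
* Upper-triangular canonical storage with symmetric terms folded; the
  solver symmetrizes once into CSR for field updates.
* Baseline/BLS ties break toward the lowest index / lexicographically
  smallest row for determinism.
* Degenerate inputs fail loudly: all-zero matrices (undefined relative
  error, undefined leverage distribution), p ∈ {0, 1} Bernoulli, NaN in
  discretization, rank 0.

## Problem sizes used in the shipped checks

The test suite and acceptance script run at desk scale: planted 30×30
matrices and 2000×30 matrices with sample size 30, ranks 1–2, 10
instances per configuration, 10⁶ flips per restart with best-of-5
(tempered) restarts; the baseline comparison uses 10 Bernoulli(0.8)
draws at each shape across ranks 1–5. Oracle-backed equivalence checks
run exhaustively at 2×2, rank 1–2. Larger ranks and 50000-row matrices
follow the same code paths and only cost more solver budget
(`bmf experiment --full-scale` raises budgets 1000×).

## Known limitations

* Plain simulated annealing at λ = 1 stalls on plateaus for r ≥ 2; use
  the tempered default or raise the budget.
* F1 QUBOs scale as mnr variables: beyond roughly 100×100 the direct
  build is impractical and sampling is the intended route.
* The sampling pipeline assumes the column space is captured by s rows;
  adversarial matrices with many rare-but-important row patterns can
  defeat leverage sampling.
* Boolean (OR-semiring) and GF(2) factorizations are different problems
  and out of scope, as is approximate leverage-score estimation.
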