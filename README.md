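# qubomf

Binary matrix factorization (BMF) formulated as quadratic unconstrained
binary optimization (QUBO) and solved with seeded simulated annealing and
parallel tempering — the classical counterpart of running the same
encodings on annealing hardware.

## The problem

Given a binary matrix **A** ∈ {0,1}^(m×n) and a target rank *r*, rank-*r*
BMF seeks binary factors

    min_{U, V}  ‖A − U Vᵀ‖²_F,   U ∈ {0,1}^(m×r),  V ∈ {0,1}^(n×r),

under the ordinary integer inner product. When **UVᵀ** is binary the
objective is exactly the number of mismatched cells, which makes the
squared norm the natural error unit for 0/1 data; we report the
**relative error** ‖A − UVᵀ‖²_F / ‖A‖²_F (mismatches over nonzeros).
BMF underlies biclustering of discretized gene-expression matrices,
pattern mining, and binary dimensionality reduction, and is NP-hard.

## The method

The quartic objective is quadratized with auxiliary variables and the
penalty f(a,b,c) = bc − 2ba − 2ca + 3a, which is 0 iff a = bc and ≥ 1
otherwise:

* **Formulation 1** — auxiliaries w_ij^(k) = u_ik·v_jk, giving
  (m + n + mn)·r variables;
* **Formulation 2** — auxiliaries ũ_i^(kk′) = u_ik·u_ik′ and
  ṽ_j^(kk′) = v_jk·v_jk′, giving (m + n)(r + r²) variables.

Both solve for **U** and **V** *simultaneously* (no alternating updates in
the core solve). A penalty weight λ > 2r‖A‖²_F guarantees that QUBO and BMF
minimizers coincide; in practice λ = 1 gives a gentler landscape and the
solver's output is repaired downstream. Extras:

* **one-hot clustering constraint** — a quadratic penalty forcing each row
  of **V** to sum to 1, so every sample joins exactly one cluster;
* **leverage-score row sampling** — for tall matrices (m ≫ n), factorize a
  small sampled matrix, keep **V**, and recover **U** by m independent
  binary least-squares (BLS) problems over the 2^r candidate rows;
* **alternating BLS refinement** — up to 20 exact one-factor solves,
  stopping after two consecutive non-improvements;
* **density baseline** — best of three cheap candidates (densest columns,
  densest rows, all-ones rank-1);
* **generators and discretization** — planted exact factorizations,
  Bernoulli(p) noise, and the κ·c₁ / κ·c₂ thresholding rule for
  expression matrices.

## Worked example

```python
import numpy as np
from qubomf import (build_formulation1, bmf_objective, factorize,
                    gen_exact_rank_r, relative_error, toy_exact_bmf)

A, U, V = toy_exact_bmf()          # 3x3 matrix with an exact rank-2 BMF
print(bmf_objective(A, U, V))      # 0   (A == U @ V.T, no mismatches)
print(relative_error(A, U, V))     # 0.0

prob = build_formulation1(A, r=2)
print(prob.n_vars, prob.offset)    # 30 6   ((3+3+9)*2 variables, nnz(A)=6)

# a tall planted matrix, factorized through 30-row leverage sampling
A_big, _, _ = gen_exact_rank_r(2000, 30, 2, np.random.default_rng(0))
pair, report = factorize(A_big, r=2, sample_size=30, seed=0)
print(report["relative_error"])    # 0.0  (exact recovery)
```

The energy of any feasible encoding equals the factorization objective, so
a solver energy of 0 certifies an exact factorization. The report also
carries the raw solver energy and the count of auxiliary-constraint
violations in the annealer's best state; at λ = 1 the raw state may violate
some product constraints, which the BLS lift and refinement repair (the
final factors are always exactly binary and feasible by construction).

The same pipeline from the shell:

```bash
bmf generate planted --m 2000 --n 30 --rank 2 --seed 0 --out A.mtx
bmf factorize --input A.mtx --rank 2 --sample-size 30 --replicas 5 \
              --seed 0 --out fit
bmf evaluate --input A.mtx --u fit.U.mtx --v fit.V.mtx
```

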