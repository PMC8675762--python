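"""QUBO assembly: energy identities, penalty bounds, clustering, BLS, I/O."""

import itertools

import numpy as np
import pytest
import scipy.sparse as sp

from qubomf import (
    QuboProblem,
    bmf_objective,
    brute_force_min,
    build_bls_qubo,
    build_formulation1,
    build_formulation2,
    clustering_penalty_block,
    penalty_f,
    read_qubo,
    safe_penalty_weight,
    toy_exact_bmf,
    write_qubo,
)
from qubomf.core import PenaltyConfig, VariableLayout


def penalized_objective_f1(A, U, V, W, lam):
    """Term-by-term penalized F1 objective, the independent oracle."""
    m, n = A.shape
    r = U.shape[1]
    total = int(A.sum())
    for i in range(m):
        for j in range(n):
            for k in range(r):
                total += -2 * A[i, j] * W[i, j, k]
                for kp in range(r):
                    total += W[i, j, k] * W[i, j, kp]
                total += lam * penalty_f(W[i, j, k], U[i, k], V[j, k])
    return total


def penalized_objective_f2(A, U, V, Ut, Vt, lam, lay):
    """Term-by-term penalized F2 objective."""
    m, n = A.shape
    r = U.shape[1]
    total = int(A.sum())
    for i in range(m):
        for j in range(n):
            for k in range(r):
                total += -2 * A[i, j] * U[i, k] * V[j, k]
                for kp in range(r):
                    c = lay._aux_col(k, kp)
                    total += Ut[i, c] * Vt[j, c]
    for k in range(r):
        for kp in range(r):
            c = lay._aux_col(k, kp)
            for i in range(m):
                total += lam * penalty_f(Ut[i, c], U[i, k], U[i, kp])
            for j in range(n):
                total += lam * penalty_f(Vt[j, c], V[j, k], V[j, kp])
    return total


class TestEnergyIdentity:
    """QUBO energy equals the penalized objective, exactly in integers."""

    def test_f1_random_encodings(self, rng):
        checked = 0
        while checked < 100:
            m, n, r = rng.integers(1, 6), rng.integers(1, 6), rng.integers(1, 4)
            A = rng.integers(0, 2, (m, n))
            if A.sum() == 0:
                continue
            lam = int(rng.integers(1, 6))
            prob = build_formulation1(A, r, PenaltyConfig(lam))
            U = rng.integers(0, 2, (m, r))
            V = rng.integers(0, 2, (n, r))
            W = rng.integers(0, 2, (m, n, r))
            x = prob.layout.encode(U, V, {"W": W})
            assert prob.energy(x) == penalized_objective_f1(A, U, V, W, lam)
            checked += 1

    def test_f2_random_encodings(self, rng):
        checked = 0
        while checked < 100:
            m, n, r = rng.integers(1, 5), rng.integers(1, 5), rng.integers(1, 4)
            A = rng.integers(0, 2, (m, n))
            if A.sum() == 0:
                continue
            lam = int(rng.integers(1, 6))
            prob = build_formulation2(A, r, PenaltyConfig(lam))
            lay = prob.layout
            U = rng.integers(0, 2, (m, r))
            V = rng.integers(0, 2, (n, r))
            Ut = rng.integers(0, 2, (m, r * r))
            Vt = rng.integers(0, 2, (n, r * r))
            x = lay.encode(U, V, {"Utilde": Ut, "Vtilde": Vt})
            assert prob.energy(x) == penalized_objective_f2(A, U, V, Ut, Vt, lam, lay)
            checked += 1

    @pytest.mark.parametrize("build", [build_formulation1, build_formulation2])
    def test_feasible_encoding_energy_is_bmf_objective(self, build, rng):
        for _ in range(30):
            m, n, r = rng.integers(1, 5), rng.integers(1, 5), rng.integers(1, 4)
            A = rng.integers(0, 2, (m, n))
            if A.sum() == 0:
                continue
            prob = build(A, r)
            U = rng.integers(0, 2, (m, r))
            V = rng.integers(0, 2, (n, r))
            x = prob.layout.encode(U, V)  # consistent auxiliaries
            assert prob.energy(x) == bmf_objective(A, U, V)

    def test_toy_example_feasible_energy_zero(self):
        A, U, V = toy_exact_bmf()
        prob = build_formulation1(A, 2)
        assert prob.energy(prob.layout.encode(U, V)) == 0


class TestFormulationEquivalence:
    """With a safe penalty weight, the QUBO optimum equals the BMF optimum."""

    @staticmethod
    def exhaustive_bmf_min(A, r):
        m, n = A.shape
        best = None
        for ubits in itertools.product((0, 1), repeat=m * r):
            U = np.array(ubits).reshape(m, r)
            for vbits in itertools.product((0, 1), repeat=n * r):
                V = np.array(vbits).reshape(n, r)
                obj = bmf_objective(A, U, V)
                best = obj if best is None else min(best, obj)
        return best

    @pytest.mark.parametrize("build", [build_formulation1, build_formulation2])
    def test_exhaustive_minimum_matches(self, build, rng):
        done = 0
        while done < 20:
            A = rng.integers(0, 2, (2, 2))
            if A.sum() == 0:
                continue
            lam = safe_penalty_weight(A, 1)
            prob = build(A, 1, PenaltyConfig(lam))
            assert prob.n_vars == 8
            res = brute_force_min(prob)
            assert res.best_energy == self.exhaustive_bmf_min(A, 1)
            done += 1

    def test_infeasible_states_cost_more_than_trivial_point(self, rng):
        """Any encoding violating the product constraints exceeds the
        all-zero objective when the penalty weight is above 2 r nnz(A)."""
        A = np.array([[1, 0], [1, 1]])
        lam = safe_penalty_weight(A, 1)
        prob = build_formulation1(A, 1, PenaltyConfig(lam))
        lay = prob.layout
        for bits in itertools.product((0, 1), repeat=8):
            x = np.array(bits)
            if lay.aux_violations(x) > 0:
                assert prob.energy(x) > int(A.sum())


class TestVariableCounts:
    @pytest.mark.parametrize("r", [1, 2, 3, 4, 5])
    def test_f1_sizes(self, r):
        assert VariableLayout("F1", 30, 30, r).length == 960 * r
        assert VariableLayout("F1", 28, 28, r).length == 840 * r
        assert VariableLayout("F1", 30, 38, r).length == 1208 * r

    @pytest.mark.parametrize("r", [1, 2])
    def test_f2_sizes(self, r):
        assert VariableLayout("F2", 30, 30, r).length == 60 * (r + r * r)


class TestClusteringPenalty:
    def lam_energy(self, V, lam=3.0, m=2):
        n, r = V.shape
        block, off = clustering_penalty_block(m, n, r, lam)
        x = np.concatenate([np.zeros(m * r), V.ravel(order="F")])
        return x @ (block.toarray() @ x) + off

    def test_one_hot_rows_cost_nothing(self):
        assert self.lam_energy(np.eye(2, dtype=int)) == 0.0

    def test_all_zero_row_costs_lambda(self):
        assert self.lam_energy(np.array([[1, 0], [0, 0]])) == 3.0

    def test_double_assignment_costs_lambda(self):
        assert self.lam_energy(np.array([[1, 1], [1, 0]])) == 3.0

    def test_exhaustive_minimizers_have_one_hot_v(self, rng):
        done = 0
        while done < 5:
            A = rng.integers(0, 2, (2, 2))
            if A.sum() == 0:
                continue
            lam = safe_penalty_weight(A, 2)
            prob = build_formulation1(A, 2, PenaltyConfig(lam, lambda_cluster=lam))
            res = brute_force_min(prob)
            _, V, _ = prob.layout.decode(res.best_assignment)
            assert (V.sum(axis=1) == 1).all()
            done += 1

    def test_clustered_problem_has_no_target(self):
        A = np.array([[1, 0], [0, 1]])
        prob = build_formulation1(A, 2, PenaltyConfig(1, lambda_cluster=1))
        assert prob.target_energy is None
        assert build_formulation1(A, 2).target_energy == 0.0


class TestBlsQubo:
    def test_identity_system(self):
        prob = build_bls_qubo(np.eye(2), [1.0, 0.0])
        res = brute_force_min(prob)
        assert res.best_assignment.tolist() == [1, 0]
        assert res.best_energy == 0

    def test_zero_assignment_energy_is_norm_of_y(self, rng):
        y = rng.normal(size=4)
        prob = build_bls_qubo(rng.normal(size=(4, 3)), y)
        assert prob.energy(np.zeros(3, dtype=int)) == pytest.approx(float(y @ y))

    def test_energy_equals_residual_for_all_assignments(self, rng):
        M = rng.normal(size=(4, 3))
        y = rng.normal(size=4)
        prob = build_bls_qubo(M, y)
        for bits in itertools.product((0, 1), repeat=3):
            x = np.array(bits)
            resid = M @ x - y
            assert prob.energy(x) == pytest.approx(float(resid @ resid))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            build_bls_qubo(np.eye(2), [1.0, 0.0, 0.0])


class TestCanonicalForm:
    def test_lower_triangle_is_folded(self):
        prob = QuboProblem.from_triplets(3, [2, 0], [0, 2], [5, 1], 0)
        assert sp.tril(prob.coefficients, k=-1).nnz == 0
        assert prob.coefficients[0, 2] == 6

    def test_rejects_non_canonical_matrix(self):
        bad = sp.csr_matrix(np.array([[0, 0], [1.0, 0]]))
        with pytest.raises(ValueError):
            QuboProblem(2, bad, 0.0)

    def test_triplet_order_does_not_matter(self, rng):
        n = 6
        iu, ju = np.triu_indices(n)
        vals = rng.integers(-3, 4, iu.size)
        perm = rng.permutation(iu.size)
        p1 = QuboProblem.from_triplets(n, iu, ju, vals, 2)
        p2 = QuboProblem.from_triplets(n, iu[perm], ju[perm], vals[perm], 2)
        assert (p1.coefficients != p2.coefficients).nnz == 0


class TestQuboFileFormat:
    def test_roundtrip_integer_exact(self, tmp_path, rng):
        A = rng.integers(0, 2, (3, 4))
        A[0, 0] = 1
        prob = build_formulation1(A, 2, PenaltyConfig(3))
        path = tmp_path / "p.qubo"
        write_qubo(prob, path)
        back = read_qubo(path)
        assert back.n_vars == prob.n_vars
        assert back.offset == prob.offset
        assert (back.coefficients != prob.coefficients).nnz == 0

    def test_malformed_line_reports_lineno(self, tmp_path):
        path = tmp_path / "bad.qubo"
        path.write_text("4 0\n0 1 2\n0 nonsense\n")
        with pytest.raises(ValueError, match=":3"):
            read_qubo(path)

    def test_rejects_lower_triangular_entry(self, tmp_path):
        path = tmp_path / "lower.qubo"
        path.write_text("4 0\n2 1 1\n")
        with pytest.raises(ValueError):
            read_qubo(path)


@pytest.mark.parametrize("build", [build_formulation1, build_formulation2])
def test_builders_reject_degenerate_inputs(build):
    A = np.array([[1, 0], [0, 1]])
    with pytest.raises(ValueError):
        build(A, 0)
    with pytest.raises(ValueError):
        build(A, 1, PenaltyConfig(0))
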