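"""Gaussian elimination, normal-system assembly and end-to-end weight optimization."""

import numpy as np
import pytest

import abiplan as ab
from abiplan.errors import DegenerateSystemError, SingularSystemError
from abiplan.objective import prescribed_dose_vector
from abiplan.solver import build_normal_system, default_lambda

from conftest import make_consistent_system


def cramer_solve(A, b):
    """Independent oracle: Cramer's rule via determinants (small n only)."""
    A = np.asarray(A, float)
    b = np.asarray(b, float)
    det = np.linalg.det(A)
    x = np.empty(len(b))
    for j in range(len(b)):
        Aj = A.copy()
        Aj[:, j] = b
        x[j] = np.linalg.det(Aj) / det
    return x


class TestGaussianEliminate:
    def test_identity(self):
        x = ab.gaussian_eliminate(np.eye(2), np.array([3.0, 5.0]))
        assert x == pytest.approx([3.0, 5.0])

    def test_diagonal(self):
        x = ab.gaussian_eliminate(np.diag([2.0, 4.0]), np.array([2.0, 8.0]))
        assert x == pytest.approx([1.0, 2.0])

    def test_requires_pivoting(self):
        # leading zero forces a row swap
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert ab.gaussian_eliminate(A, np.array([2.0, 3.0])) == pytest.approx([3.0, 2.0])

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_cramer_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 9)
        A = rng.normal(size=(n, n)) + n * np.eye(n)
        b = rng.normal(size=n)
        x = ab.gaussian_eliminate(A, b)
        ref = cramer_solve(A, b)
        assert np.abs(x - ref).max() <= 1e-8 * (1 + np.abs(ref).max())

    def test_residual_bound_medium_systems(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            n = int(rng.integers(10, 51))
            A = rng.normal(size=(n, n)) + n * np.eye(n)
            b = rng.normal(size=n)
            x = ab.gaussian_eliminate(A, b)
            assert np.abs(A @ x - b).max() <= 1e-8 * (1 + np.abs(b).max())

    def test_singular_matrix_reports_step(self):
        A = np.array([[1.0, 2.0], [2.0, 4.0]])
        with pytest.raises(SingularSystemError) as exc:
            ab.gaussian_eliminate(A, np.array([1.0, 2.0]))
        assert exc.value.step == 1

    def test_deterministic(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(12, 12)) + 12 * np.eye(12)
        b = rng.normal(size=12)
        assert np.array_equal(ab.gaussian_eliminate(A, b), ab.gaussian_eliminate(A, b))


class TestBuildNormalSystem:
    def test_identity_propagation(self):
        D = np.eye(3)
        t = np.array([1.0, 2.0, 3.0])
        sys_ = build_normal_system(D, t, np.ones(3), 0.0)
        assert sys_.A == pytest.approx(np.eye(3))
        assert sys_.b == pytest.approx(t)

    def test_hand_computed_two_by_one(self):
        D = np.array([[1.0], [1.0]])
        sys_ = build_normal_system(D, np.array([1.0, 3.0]), np.ones(2), 0.0)
        assert sys_.A[0, 0] == pytest.approx(2.0)
        assert sys_.b[0] == pytest.approx(4.0)

    def test_penalty_doubling_is_linear(self):
        rng = np.random.default_rng(5)
        D = rng.uniform(0, 1, size=(10, 3))
        t = rng.uniform(0, 60, size=10)
        p = rng.uniform(0.1, 2, size=10)
        lam = 0.5
        s1 = build_normal_system(D, t, p, lam)
        s2 = build_normal_system(D, t, 2 * p, lam)
        assert s2.A - lam * np.eye(3) == pytest.approx(2 * (s1.A - lam * np.eye(3)))
        assert s2.b == pytest.approx(2 * s1.b)

    def test_all_zero_penalties_rejected(self):
        with pytest.raises(DegenerateSystemError):
            build_normal_system(np.eye(2), np.ones(2), np.zeros(2), 0.0)


class TestOptimizeWeights:
    def test_consistent_system_recovery(self):
        rng = np.random.default_rng(123)
        D, w_true, d = make_consistent_system(rng, m=120, n=10)
        res = ab.optimize_weights(D, target_doses=d, lam=0.0, nonneg=True)
        assert np.abs(res.weights - w_true).max() <= 1e-6 * np.abs(w_true).max()
        assert res.surrogate_final <= 1e-12 * (d @ d)

    def test_recovery_through_objective_path(self):
        # one single-point target structure per sample point
        rng = np.random.default_rng(7)
        D, w_true, d = make_consistent_system(rng, m=40, n=5)
        labels = np.array([f"pt{i}" for i in range(40)])
        goals = tuple(
            ab.StructureGoal(f"pt{i}", "target", d_max=d[i], d_min=d[i],
                             prescription=d[i], penalty=1.0)
            for i in range(40)
        )
        res = ab.optimize_weights(D, ab.DoseObjective(goals), labels, lam=0.0)
        assert np.abs(res.weights - w_true).max() <= 1e-6 * np.abs(w_true).max()
        assert res.cost_final <= 1e-10

    def test_preset_cost_decreases(self, mini_matrix, mini_objective):
        res = ab.optimize_weights(mini_matrix, mini_objective)
        assert res.cost_final < res.cost_initial
        assert res.weights.min() >= 0
        assert res.doses == pytest.approx(mini_matrix.values @ res.weights)

    def test_repeated_solves_bit_identical(self, mini_matrix, mini_objective):
        r1 = ab.optimize_weights(mini_matrix, mini_objective)
        r2 = ab.optimize_weights(mini_matrix, mini_objective)
        assert np.array_equal(r1.weights, r2.weights)
        assert r1.cost_final == r2.cost_final

    def test_wls_stationarity_at_unconstrained_solution(self, mini_matrix, mini_objective):
        res = ab.optimize_weights(mini_matrix, mini_objective, nonneg=False)
        D = mini_matrix.values
        ref = D @ np.ones(mini_matrix.n)
        t, p = prescribed_dose_vector(mini_objective, ref, mini_matrix.row_structures)
        grad = D.T @ (p * (D @ res.weights - t)) + res.smoothing_lambda * res.weights
        scale = np.abs(D.T @ (p * t)).max()
        assert np.abs(grad).max() <= 1e-6 * scale

    def test_nonneg_clamp_yields_nonnegative_weights(self):
        # two nearly collinear columns force a negative unconstrained weight
        rng = np.random.default_rng(11)
        base = rng.uniform(0.5, 1.0, size=30)
        D = np.column_stack([base, base * 1.05 + rng.uniform(0, 0.01, 30), rng.uniform(0, 1, 30)])
        d = D @ np.array([1.0, 0.0, 0.5]) + rng.normal(0, 0.2, 30)
        unc = ab.optimize_weights(D, target_doses=d, lam=1e-9, nonneg=False)
        assert unc.weights.min() < 0  # premise of the clamp test
        res = ab.optimize_weights(D, target_doses=d, lam=1e-9, nonneg=True)
        assert res.weights.min() >= 0
        assert res.surrogate_final >= unc.surrogate_final  # constrained is never better

    def test_nnls_option_matches_scipy_route(self):
        rng = np.random.default_rng(13)
        D, _, d = make_consistent_system(rng, m=50, n=6)
        d = d + rng.normal(0, 0.5, size=50)
        res = ab.optimize_weights(D, target_doses=d, lam=1e-6, nonneg=True, nnls=True)
        assert res.weights.min() >= 0

    def test_smoothing_drives_weights_to_zero_monotonically(self):
        rng = np.random.default_rng(3)
        D, _, d = make_consistent_system(rng, m=80, n=6)
        norms = []
        for lam in (0.0, 1.0, 10.0, 100.0, 1000.0, 1e6):
            res = ab.optimize_weights(D, target_doses=d, lam=lam, nonneg=False)
            norms.append(np.linalg.norm(res.weights))
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))
        assert norms[-1] < 1e-2 * norms[0]
        # lambda = 0 reproduces the plain unsmoothed least-squares solution
        res0 = ab.optimize_weights(D, target_doses=d, lam=0.0, nonneg=False)
        ref = np.linalg.lstsq(D, d, rcond=None)[0]
        assert res0.weights == pytest.approx(ref, abs=1e-8)

    def test_default_lambda_scale(self):
        D = np.eye(4)
        lam = default_lambda(D, np.ones(4))
        assert lam == pytest.approx(1e-6 * 4 / 4)

    def test_infeasible_objective_rejected(self, mini_matrix, mini_objective):
        zeroed = mini_objective.with_penalties(
            {g.structure: 0.0 for g in mini_objective.goals}
        )
        with pytest.raises(DegenerateSystemError):
            ab.optimize_weights(mini_matrix, zeroed)


class TestReconstructDoses:
    def test_zero_and_uniform_weights(self, mini_matrix):
        n = mini_matrix.n
        assert np.array_equal(
            ab.reconstruct_doses(mini_matrix, np.zeros(n)), np.zeros(mini_matrix.m)
        )
        uniform = ab.reconstruct_doses(mini_matrix, np.ones(n))
        assert uniform == pytest.approx(mini_matrix.values.sum(axis=1))

    def test_matches_explicit_summation_oracle(self, mini_matrix):
        rng = np.random.default_rng(9)
        w = rng.uniform(0, 3, size=mini_matrix.n)
        doses = ab.reconstruct_doses(mini_matrix, w)
        explicit = np.array(
            [sum(mini_matrix.values[i, j] * w[j] for j in range(mini_matrix.n))
             for i in range(mini_matrix.m)]
        )
        assert doses == pytest.approx(explicit, rel=1e-12)

    def test_dimension_mismatch(self, mini_matrix):
        with pytest.raises(ValueError):
            ab.reconstruct_doses(mini_matrix, np.ones(mini_matrix.n + 1))
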