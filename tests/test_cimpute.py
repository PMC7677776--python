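import numpy as np
import pytest
from scipy.optimize import minimize

from iimpute import (
    ExpressionMatrix,
    ImputationConfig,
    build_affinity,
    build_regression_problem,
    cimpute,
    nnlasso_coordinate_descent,
)
from iimpute.affinity import AffinityMatrix
from iimpute.cimpute import nnlasso_objective
from iimpute.containers import LatentMatrix


def _em(vals):
    m, n = vals.shape
    return ExpressionMatrix(vals, [f"g{i}" for i in range(m)],
                            [f"c{j}" for j in range(n)])


def _full_affinity(n):
    return AffinityMatrix(values=np.ones((n, n)), bandwidths=np.ones(n), n_neighbor=n - 1)


def oracle_nnlasso(design, target, lam):
    """Independent solver: bound-constrained quadratic via L-BFGS-B."""
    def f(b):
        r = target - design @ b
        return 0.5 * r @ r + lam * b.sum()

    def grad(b):
        return -(design.T @ (target - design @ b)) + lam

    p = design.shape[1]
    res = minimize(f, np.zeros(p), jac=grad, method="L-BFGS-B",
                   bounds=[(0, None)] * p,
                   options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10})
    return res.x, res.fun


class TestBuildRegressionProblem:
    def test_unweighted_limit(self, rng):
        x = rng.random((5, 4))
        d = np.zeros((5, 4))
        a = np.ones((4, 4))
        design, target = build_regression_problem(x, d, a, 1)
        np.testing.assert_array_equal(target, x[:, 1])
        np.testing.assert_array_equal(design, x[:, [0, 2, 3]])

    def test_dropout_gene_leaves_target(self, rng):
        x = rng.random((5, 4))
        d = np.zeros((5, 4))
        d[2, 1] = 1.0
        _, target = build_regression_problem(x, d, np.ones((4, 4)), 1)
        assert target[2] == 0.0

    def test_hand_computed_3x3(self):
        x = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [7.0, 8.0, 9.0]])
        d = np.array([[0.1, 0.2, 0.3], [0.0, 0.5, 0.9], [1.0, 0.0, 0.4]])
        a = np.array([[1.0, 0.8, 0.0], [0.8, 1.0, 0.5], [0.0, 0.5, 1.0]])
        design, target = build_regression_problem(x, d, a, 0)
        # target_g = (1 - D_g0) * X_g0
        np.testing.assert_allclose(target, [0.9 * 1, 1.0 * 4, 0.0 * 7])
        # columns for cells 1 and 2: (1 - D_gc) * A_0c * X_gc
        np.testing.assert_allclose(
            design[:, 0], [(1 - 0.2) * 0.8 * 2, (1 - 0.5) * 0.8 * 5, (1 - 0.0) * 0.8 * 8]
        )
        np.testing.assert_allclose(design[:, 1], np.zeros(3))  # A_02 = 0

    def test_zero_affinity_column_is_zero(self, rng):
        x = rng.random((6, 5))
        a = np.ones((5, 5))
        a[2, 4] = 0.0
        design, _ = build_regression_problem(x, np.zeros((6, 5)), a, 2)
        np.testing.assert_array_equal(design[:, 3], np.zeros(6))


class TestNNLasso:
    def test_full_shrinkage_threshold(self, rng):
        design = rng.random((20, 6))
        target = rng.random(20)
        lam = float(np.abs(design.T @ target).max())
        w = nnlasso_coordinate_descent(design, target, lam)
        np.testing.assert_array_equal(w.b, np.zeros(6))

    def test_orthonormal_closed_form(self, rng):
        q, _ = np.linalg.qr(rng.normal(size=(10, 4)))
        target = rng.normal(size=10)
        w = nnlasso_coordinate_descent(q, target, lam=0.0)
        np.testing.assert_allclose(w.b, np.maximum(q.T @ target, 0.0), atol=1e-9)

    def test_matches_independent_optimizer(self, rng):
        design = rng.random((30, 8))
        target = design @ np.abs(rng.normal(size=8)) + 0.1 * rng.normal(size=30)
        lam = 0.1
        w = nnlasso_coordinate_descent(design, target, lam)
        obj_cd = nnlasso_objective(design, target, w.b, lam)
        _, obj_oracle = oracle_nnlasso(design, target, lam)
        assert obj_cd <= obj_oracle + 1e-6 * max(1.0, abs(obj_oracle))

    def test_objective_trace_non_increasing(self, rng):
        design = rng.random((25, 10))
        target = rng.random(25)
        w = nnlasso_coordinate_descent(design, target, 0.05)
        assert np.all(np.diff(w.objective_trace) <= 1e-10)

    def test_zero_column_weight_stays_zero(self, rng):
        design = rng.random((15, 4))
        design[:, 2] = 0.0
        w = nnlasso_coordinate_descent(design, rng.random(15), 0.01)
        assert w.b[2] == 0.0

    def test_negative_lambda_rejected(self, rng):
        with pytest.raises(ValueError):
            nnlasso_coordinate_descent(rng.random((5, 2)), rng.random(5), -1.0)

    def test_shrinkage_path_sparsity(self, rng):
        design = rng.random((40, 12))
        target = rng.random(40)
        lam_max = float(np.abs(design.T @ target).max())
        nnz = [
            int((nnlasso_coordinate_descent(design, target, f * lam_max).b > 1e-12).sum())
            for f in (0.01, 0.05, 0.1, 0.5, 1.0)
        ]
        assert nnz == sorted(nnz, reverse=True)


class TestCimpute:
    def test_no_dropouts_is_identity(self, rng):
        x = _em(rng.random((8, 5)))
        out = cimpute(x, np.zeros((8, 5)), _full_affinity(5))
        np.testing.assert_array_equal(out.values, x.values)
        assert not out.imputed_mask.any()

    def test_threshold_zero_replaces_everything(self, rng):
        vals = rng.random((8, 5)) + 0.5
        x = _em(vals)
        out = cimpute(x, np.zeros((8, 5)), _full_affinity(5), ImputationConfig(t=0.0))
        assert out.imputed_mask.all()

    def test_preservation_is_bitwise(self, rng):
        vals = rng.random((10, 6))
        d = rng.random((10, 6))
        x = _em(vals)
        out = cimpute(x, d, _full_affinity(6), ImputationConfig(t=0.5))
        keep = d < 0.5
        assert np.array_equal(out.values[keep], vals[keep])

    def test_duplicate_population_oracle(self):
        # two populations of duplicate cells; one zeroed entry with D = 1
        # must be imputed to (approximately) the duplicates' shared value
        a_prof = np.array([5.0, 0.2, 3.0, 1.0, 2.0])
        b_prof = np.array([0.3, 4.0, 0.5, 2.5, 0.1])
        vals = np.stack([a_prof] * 5 + [b_prof] * 5, axis=1).copy()
        vals[0, 0] = 0.0
        d = np.zeros((5, 10))
        d[0, 0] = 1.0
        x = _em(vals)
        z = LatentMatrix(vals.copy())
        aff = build_affinity(z, n=4)
        out = cimpute(x, d, aff, ImputationConfig(t=0.5))
        assert out.values[0, 0] == pytest.approx(5.0, rel=0.05)

    def test_nonnegative_output(self, rng):
        vals = rng.random((12, 7))
        d = (rng.random((12, 7)) > 0.5).astype(float)
        out = cimpute(_em(vals), d, _full_affinity(7))
        assert np.all(out.values >= 0)

    def test_isolated_cell_left_unchanged(self, rng):
        vals = rng.random((6, 4))
        aff = _full_affinity(4)
        aff.values[2, :] = 0.0
        aff.values[2, 2] = 1.0
        d = np.ones((6, 4))
        out = cimpute(_em(vals), d, aff)
        np.testing.assert_array_equal(out.values[:, 2], vals[:, 2])
        assert not out.imputed_mask[:, 2].any()
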