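import numpy as np
import pytest

from smtl import (
    l1_lambda_max,
    l21_lambda_max,
    select_features,
    solve_l1,
    solve_l21,
)
from smtl.selection import WeightMatrix, l21_optimality_residual

from oracles import bcd_l21, cd_l1

TIGHT = dict(rel_tol=1e-12, max_iter=30000)


class TestSolveL21:
    def test_zero_solution_above_critical_penalty(self, rng):
        X = rng.standard_normal((25, 12))
        Y = rng.standard_normal((25, 3))
        lam_max = l21_lambda_max(X, Y)
        w = solve_l21(X, Y, lam_max * 1.0001, **TIGHT)
        assert np.abs(w.W).max() == 0.0
        # just below the threshold the solution must be nonzero
        w2 = solve_l21(X, Y, lam_max * 0.99, **TIGHT)
        assert np.abs(w2.W).max() > 0.0

    def test_vanishing_penalty_recovers_least_squares(self, rng):
        X = rng.standard_normal((40, 10))
        Y = rng.standard_normal((40, 3))
        w = solve_l21(X, Y, 1e-10, **TIGHT)
        Wls = np.linalg.lstsq(X, Y, rcond=None)[0]
        np.testing.assert_allclose(w.W, Wls, atol=1e-6)

    @pytest.mark.parametrize("frac", [0.05, 0.3])
    def test_objective_matches_coordinate_descent_oracle(self, rng, frac):
        X = rng.standard_normal((30, 20))
        Y = rng.standard_normal((30, 4))
        lam = frac * l21_lambda_max(X, Y)
        w = solve_l21(X, Y, lam, **TIGHT)
        _, obj_oracle = bcd_l21(X, Y, lam)
        assert w.objective <= obj_oracle * (1 + 1e-6)
        assert abs(w.objective - obj_oracle) <= 1e-6 * abs(obj_oracle)

    def test_objective_trace_non_increasing(self, rng):
        X = rng.standard_normal((30, 15))
        Y = rng.standard_normal((30, 3))
        w = solve_l21(X, Y, 0.2 * l21_lambda_max(X, Y))
        trace = np.asarray(w.objective_trace)
        assert (np.diff(trace) <= 1e-10).all()

    def test_subgradient_certificate(self, rng):
        X = rng.standard_normal((30, 15))
        Y = rng.standard_normal((30, 3))
        lam = 0.2 * l21_lambda_max(X, Y)
        w = solve_l21(X, Y, lam, **TIGHT)
        assert l21_optimality_residual(X, Y, w.W, lam) < 1e-4

    def test_invalid_inputs_rejected(self, rng):
        X = rng.standard_normal((10, 4))
        Y = rng.standard_normal((10, 2))
        with pytest.raises(ValueError):
            solve_l21(X, Y, -1.0)
        X_bad = X.copy()
        X_bad[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            solve_l21(X_bad, Y, 0.1)


class TestSolveL1:
    def test_orthonormal_design_closed_form(self, rng):
        A = np.linalg.qr(rng.standard_normal((30, 8)))[0]  # orthonormal columns
        y = rng.standard_normal(30)
        lam = 0.5
        w = solve_l1(A, y, lam, **TIGHT)
        target = A.T @ y
        closed = np.sign(target) * np.maximum(np.abs(target) - lam / 2, 0.0)
        np.testing.assert_allclose(w.W, closed, atol=1e-8)

    def test_zero_solution_threshold(self, rng):
        X = rng.standard_normal((20, 10))
        y = rng.standard_normal(20)
        w = solve_l1(X, y, l1_lambda_max(X, y) * 1.0001, **TIGHT)
        assert np.abs(w.W).max() == 0.0

    def test_objective_matches_coordinate_descent_oracle(self, rng):
        X = rng.standard_normal((30, 20))
        y = rng.standard_normal(30)
        lam = 0.2 * l1_lambda_max(X, y)
        w = solve_l1(X, y, lam, **TIGHT)
        _, obj_oracle = cd_l1(X, y, lam)
        assert abs(w.objective - obj_oracle) <= 1e-6 * abs(obj_oracle)

    def test_single_task_l21_equals_l1(self, rng):
        X = rng.standard_normal((25, 12))
        y = rng.standard_normal(25)
        lam = 0.15 * l1_lambda_max(X, y)
        w1 = solve_l1(X, y, lam, **TIGHT)
        w21 = solve_l21(X, y[:, None], lam, **TIGHT)
        assert abs(w1.objective - w21.objective) <= 1e-6 * abs(w1.objective)
        np.testing.assert_allclose(w1.W, w21.W.ravel(), atol=1e-6)


class TestSelectFeatures:
    def _wm(self, norms):
        norms = np.asarray(norms, float)
        return WeightMatrix(W=norms.copy(), row_norms=norms, lam=0.1,
                            converged=True, n_iter=1, objective_trace=[0.0])

    def test_zero_weights_give_flagged_empty_selection(self):
        res = select_features(self._wm([0.0, 0.0, 0.0]))
        assert res.empty and len(res) == 0

    def test_single_surviving_row(self):
        res = select_features(self._wm([0.0, 0.5, 0.0]))
        assert res.selected.tolist() == [1] and not res.empty

    def test_order_preserved_and_relative_threshold(self):
        res = select_features(self._wm([1.0, 1e-9, 0.5, 2.0]), tolerance=1e-6)
        assert res.selected.tolist() == [0, 2, 3]

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValueError):
            select_features(self._wm([1.0]), tolerance=-0.1)


def test_support_size_shrinks_along_the_penalty_grid(rng):
    """Mean support size is non-increasing (statistically) in the penalty,
    across the nine-point grid, averaged over seeds."""
    fracs = (0.001, 0.005, 0.01, 0.05, 0.1, 0.15, 0.2, 0.3, 0.5)
    sizes = np.zeros(len(fracs))
    n_seeds = 5
    for s in range(n_seeds):
        r = np.random.default_rng(s)
        X = r.standard_normal((40, 30))
        Y = r.standard_normal((40, 3))
        lam_max = l21_lambda_max(X, Y)
        for i, f in enumerate(fracs):
            w = solve_l21(X, Y, f * lam_max, rel_tol=1e-10, max_iter=5000)
            sizes[i] += len(select_features(w)) / n_seeds
    assert (np.diff(sizes) <= 1e-9).all()
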