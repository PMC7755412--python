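"""Quasi-Newton and momentum-GD solvers plus convergence-rate diagnostics."""

import numpy as np
import pytest

from qsne import (
    LbfgsConfig,
    OptimizerTrace,
    fit_convergence_exponent,
    iterations_for_equal_progress,
    lbfgs_minimize,
    momentum_gd_minimize,
    two_loop_direction,
)
from qsne.exceptions import (
    DimensionMismatchError,
    DisjointTraceError,
    InsufficientDataError,
    NotFiniteError,
)


def quadratic(A):
    A = np.asarray(A, dtype=float)

    def fun(x):
        return 0.5 * float(x @ A @ x), A @ x

    return fun


def dense_bfgs_inverse(s_list, y_list):
    """Explicitly accumulated inverse-Hessian oracle for the two-loop recursion."""
    n = s_list[0].size
    s_new, y_new = s_list[-1], y_list[-1]
    gamma = float(s_new @ y_new) / float(y_new @ y_new)
    H = gamma * np.eye(n)
    for s, y in zip(s_list, y_list):
        rho = 1.0 / float(s @ y)
        V = np.eye(n) - rho * np.outer(s, y)
        H = V @ H @ V.T + rho * np.outer(s, s)
    return H


class TestTwoLoopDirection:
    def test_empty_history_negative_gradient(self, rng):
        g = rng.normal(size=6)
        d = two_loop_direction([], [], g)
        # proportional to -g
        cos = d @ (-g) / (np.linalg.norm(d) * np.linalg.norm(g))
        assert cos == pytest.approx(1.0, abs=1e-12)

    def test_matches_dense_bfgs_oracle(self, rng):
        """Two-loop recursion equals the explicitly formed BFGS inverse Hessian."""
        A = np.diag([1.0, 3.0, 7.0, 20.0])
        fun = quadratic(A)
        x = rng.normal(size=4)
        s_list, y_list = [], []
        for _ in range(4):
            _, g = fun(x)
            d = two_loop_direction(s_list, y_list, g)
            t = 0.4
            xn = x + t * d
            _, gn = fun(xn)
            s_list.append(xn - x)
            y_list.append(gn - g)
            x = xn
        _, g = fun(x)
        d = two_loop_direction(s_list, y_list, g)
        H = dense_bfgs_inverse(s_list, y_list)
        np.testing.assert_allclose(d, -H @ g, atol=1e-8)

    def test_descent_property(self, rng):
        """d'g < 0 for any history with positive curvature."""
        for _ in range(10):
            n = 5
            g = rng.normal(size=n)
            s_list = [rng.normal(size=n) for _ in range(3)]
            y_list = []
            for s in s_list:
                y = rng.normal(size=n)
                if s @ y <= 0:
                    y = -y
                y_list.append(y)
            d = two_loop_direction(s_list, y_list, g)
            assert d @ g < 0

    def test_dimension_mismatch(self, rng):
        with pytest.raises(DimensionMismatchError):
            two_loop_direction([rng.normal(size=3)], [rng.normal(size=4)], rng.normal(size=3))


class TestLbfgsMinimize:
    def test_sphere_converges_fast(self, rng):
        def fun(x):
            return float(x @ x), 2 * x

        x, trace = lbfgs_minimize(fun, rng.normal(size=5) * 3)
        assert trace.objective[-1] <= 1e-10
        assert trace.iterations[-1] <= 3

    def test_ill_conditioned_quadratic_beats_gd(self):
        """rank-5 L-BFGS on a kappa=1e4 10-D quadratic vs best-fixed-rate GD."""
        lam = np.logspace(0, 4, 10)
        A = np.diag(lam)
        fun = quadratic(A)
        x0 = np.ones(10)
        x, tr = lbfgs_minimize(
            fun, x0, LbfgsConfig(rank=5, max_iter=2000, grad_tol=1e-8, obj_rel_tol=0.0)
        )
        assert tr.grad_norm[-1] <= 1e-8
        # gradient descent at its best fixed rate 2/(lmin+lmax)
        lr = 2.0 / (lam.min() + lam.max())
        xg, trg = momentum_gd_minimize(
            fun, x0, learning_rate=lr, momentum=0.0, max_iter=200000, grad_tol=1e-8
        )
        assert tr.iterations[-1] <= trg.iterations[-1]

    def test_rosenbrock(self):
        def rosen(x):
            a, b = x
            f = (1 - a) ** 2 + 100 * (b - a * a) ** 2
            g = np.array(
                [-2 * (1 - a) - 400 * a * (b - a * a), 200 * (b - a * a)]
            )
            return float(f), g

        x, tr = lbfgs_minimize(
            rosen, np.array([-1.2, 1.0]), LbfgsConfig(max_iter=500, obj_rel_tol=0.0)
        )
        np.testing.assert_allclose(x, [1.0, 1.0], atol=1e-6)

    def test_monotone_objective(self, rng):
        A = np.diag([1.0, 5.0, 9.0])
        x, tr = lbfgs_minimize(quadratic(A), rng.normal(size=3))
        assert np.all(np.diff(tr.objective) <= 1e-15)

    def test_nonfinite_start_rejected(self):
        def fun(x):
            return np.nan, x

        with pytest.raises(NotFiniteError):
            lbfgs_minimize(fun, np.ones(2))

    def test_deterministic(self, rng):
        x0 = rng.normal(size=4)
        A = np.diag([1.0, 2.0, 3.0, 4.0])
        x1, t1 = lbfgs_minimize(quadratic(A), x0)
        x2, t2 = lbfgs_minimize(quadratic(A), x0)
        np.testing.assert_array_equal(x1, x2)
        np.testing.assert_array_equal(t1.objective, t2.objective)

    def test_quadratic_terminates_within_dimension(self, rng):
        """Full-rank L-BFGS solves an n-D quadratic in about n iterations."""
        n = 6
        lam = np.linspace(1.0, 4.0, n)
        x, tr = lbfgs_minimize(
            quadratic(np.diag(lam)),
            rng.normal(size=n),
            LbfgsConfig(rank=n + 2, max_iter=100, grad_tol=1e-8, obj_rel_tol=0.0),
        )
        # backtracking (not exact) line search: allow a small constant slack
        assert tr.iterations[-1] <= 2 * n + 2
        assert tr.objective[-1] <= 1e-8


class TestMomentumGd:
    def test_exact_one_step(self):
        def fun(x):
            return 0.5 * float(x @ x), x

        x, tr = momentum_gd_minimize(
            fun, np.array([3.0]), learning_rate=1.0, momentum=0.0, max_iter=5,
            grad_tol=1e-15,
        )
        assert abs(x[0]) <= 1e-15
        assert tr.objective[1] == pytest.approx(0.0, abs=1e-30)

    def test_trace_bookkeeping(self, rng):
        A = np.diag([1.0, 2.0])
        x, tr = momentum_gd_minimize(
            quadratic(A), rng.normal(size=2), learning_rate=0.1, momentum=0.5,
            max_iter=37,
        )
        assert len(tr.iterations) <= 38
        assert np.all(np.diff(tr.iterations) == 1)
        assert np.all(np.diff(tr.fevals) > 0)

    def test_linear_convergence_on_quadratic(self, rng):
        """log(excess) vs iteration is affine for heavy-ball on a quadratic."""
        A = np.diag([1.0, 2.0, 4.0])
        lr = 0.2
        x, tr = momentum_gd_minimize(
            quadratic(A), rng.normal(size=3), learning_rate=lr, momentum=0.3,
            max_iter=300,
        )
        excess = np.minimum.accumulate(tr.objective)
        keep = excess > 1e-12
        k = tr.iterations[keep][10:]
        y = np.log(excess[keep][10:])
        slope, intercept = np.polyfit(k, y, 1)
        resid = y - (slope * k + intercept)
        r2 = 1 - resid.var() / y.var()
        assert r2 > 0.99

    def test_divergence_flag(self):
        def fun(x):  # gradient pointing away: objective always increases
            return float(x @ x), -2 * x

        with pytest.warns(UserWarning):
            x, tr = momentum_gd_minimize(
                fun, np.ones(2), learning_rate=0.5, momentum=0.0, max_iter=500
            )
        assert tr.diverged

    def test_invalid_hyperparameters(self):
        def fun(x):
            return float(x @ x), 2 * x

        with pytest.raises(ValueError):
            momentum_gd_minimize(fun, np.ones(2), learning_rate=-1.0)
        with pytest.raises(ValueError):
            momentum_gd_minimize(fun, np.ones(2), momentum=1.0)


class TestEqualProgress:
    def test_identity_pairs(self):
        tr = OptimizerTrace.from_objectives(np.exp(-np.arange(10.0)))
        pairs = iterations_for_equal_progress(tr, tr)
        assert pairs == [(k, k) for k in range(1, 10)]

    def test_twice_as_fast(self):
        obj_a = np.exp(-2.0 * np.arange(11.0))
        obj_b = np.exp(-1.0 * np.arange(21.0))
        tr_a = OptimizerTrace.from_objectives(obj_a)
        tr_b = OptimizerTrace.from_objectives(obj_b)
        pairs = iterations_for_equal_progress(tr_a, tr_b)
        assert pairs == [(k, 2 * k) for k in range(1, 11)]

    def test_quadratic_vs_linear_decay_slope(self):
        ks = np.arange(0, 6)
        tr_a = OptimizerTrace.from_objectives(np.exp(-(ks.astype(float) ** 2)))
        tr_b = OptimizerTrace.from_objectives(np.exp(-np.arange(0.0, 26.0)))
        pairs = iterations_for_equal_progress(tr_a, tr_b)
        slope = fit_convergence_exponent(pairs)
        assert slope == pytest.approx(2.0, abs=0.1)

    def test_disjoint_ranges_rejected(self):
        tr_a = OptimizerTrace.from_objectives([10.0, 9.0, 8.0])
        tr_b = OptimizerTrace.from_objectives([3.0, 2.0, 1.0])
        with pytest.raises(DisjointTraceError):
            iterations_for_equal_progress(tr_a, tr_b)


class TestConvergenceExponent:
    def test_identity_slope(self):
        ks = np.arange(1, 20)
        assert fit_convergence_exponent(list(zip(ks, ks))) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_quadratic_slope(self):
        ks = np.arange(1, 20)
        assert fit_convergence_exponent(list(zip(ks, ks**2))) == pytest.approx(
            2.0, abs=1e-12
        )

    def test_noisy_quadratic_slope(self):
        rng = np.random.default_rng(42)
        ks = np.arange(1, 31)
        noisy = ks**2 * np.exp(rng.normal(scale=0.05, size=ks.size))
        slope = fit_convergence_exponent(list(zip(ks, noisy)))
        assert 1.8 <= slope <= 2.2

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientDataError):
            fit_convergence_exponent([(1, 1), (2, 2), (3, 3), (4, 4)])
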