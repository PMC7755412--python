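"""Optimizers for the embedding objective and convergence-rate diagnostics.

The primary solver is a limited-memory BFGS quasi-Newton scheme: curvature is
estimated from the last ``rank`` (step, gradient-change) pairs via the
two-loop recursion, giving a Newton-like search direction whose natural step
length is 1. A backtracking Armijo line search guards each step, so accepted
iterations never increase the objective. A classical momentum (heavy-ball)
gradient descent is provided as the linear-rate baseline.

Both solvers record an :class:`OptimizerTrace`; :func:`iterations_for_equal_progress`
and :func:`fit_convergence_exponent` compare two traces to estimate the order
of convergence of one method relative to the other.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

from .exceptions import (
    DimensionMismatchError,
    DisjointTraceError,
    InsufficientDataError,
    NotFiniteError,
)

__all__ = [
    "LbfgsConfig",
    "OptimizerTrace",
    "two_loop_direction",
    "lbfgs_minimize",
    "momentum_gd_minimize",
    "iterations_for_equal_progress",
    "fit_convergence_exponent",
]

Objective = Callable[[np.ndarray], Tuple[float, np.ndarray]]


@dataclass
class LbfgsConfig:
    """Settings for :func:`lbfgs_minimize`.

    ``rank`` is the history length of the inverse-Hessian approximation (the
    "Hessian rank" hr). The line search is backtracking Armijo with constant
    ``c1``, and iteration stops on a small gradient max-norm, on a relative
    objective decrease below ``obj_rel_tol`` over ``patience`` iterations, or
    at ``max_iter``.
    """

    rank: int = 11
    max_iter: int = 1000
    grad_tol: float = 1e-7
    obj_rel_tol: float = 1e-9
    patience: int = 10
    c1: float = 1e-4
    backtrack: float = 0.5
    max_backtracks: int = 30
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError("rank must be >= 1")
        if self.grad_tol < 0 or self.obj_rel_tol < 0:
            raise ValueError("tolerances must be non-negative")


@dataclass
class OptimizerTrace:
    """Per-iteration record of an optimization run.

    Iteration 0 is the starting point; subsequent entries are accepted steps.
    """

    iterations: np.ndarray
    objective: np.ndarray
    grad_norm: np.ndarray
    step: np.ndarray
    fevals: np.ndarray
    diverged: bool = False
    converged_by: str = field(default="max_iter")

    @classmethod
    def from_objectives(cls, objective: Sequence[float]) -> "OptimizerTrace":
        """Build a minimal trace from an objective sequence (iteration 0 first)."""
        obj = np.asarray(objective, dtype=float)
        n = obj.size
        z = np.zeros(n)
        return cls(
            iterations=np.arange(n),
            objective=obj,
            grad_norm=z.copy(),
            step=z.copy(),
            fevals=np.arange(n, dtype=float),
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "iter": self.iterations,
                "objective": self.objective,
                "grad_norm": self.grad_norm,
                "step": self.step,
                "fevals": self.fevals,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


class _TraceBuilder:
    def __init__(self) -> None:
        self.rows: List[Tuple[int, float, float, float, int]] = []

    def add(self, it: int, obj: float, gnorm: float, step: float, fevals: int) -> None:
        self.rows.append((it, obj, gnorm, step, fevals))

    def build(self, diverged: bool = False, converged_by: str = "max_iter") -> OptimizerTrace:
        a = np.array(self.rows, dtype=float)
        return OptimizerTrace(
            iterations=a[:, 0].astype(int),
            objective=a[:, 1],
            grad_norm=a[:, 2],
            step=a[:, 3],
            fevals=a[:, 4].astype(int),
            diverged=diverged,
            converged_by=converged_by,
        )


def two_loop_direction(
    s_history: Sequence[np.ndarray],
    y_history: Sequence[np.ndarray],
    g: np.ndarray,
    curvature_eps: float = 1e-12,
) -> np.ndarray:
    """L-BFGS two-loop recursion: the quasi-Newton direction -H~ g.

    Histories are ordered oldest first. Pairs without sufficient positive
    curvature (s.y <= curvature_eps ||s|| ||y||) are skipped to preserve
    positive definiteness; the initial scaling is gamma = s.y / y.y from the
    newest retained pair. With no usable history the direction is -g scaled
    to unit max-norm, so the very first trial step moves coordinates by O(1)
    regardless of the gradient's magnitude (the line search then adjusts).
    """
    g = np.asarray(g, dtype=float).ravel()
    if len(s_history) != len(y_history):
        raise DimensionMismatchError("step and gradient-difference histories differ in length")
    pairs = []
    for s, y in zip(s_history, y_history):
        s = np.asarray(s, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if s.shape != g.shape or y.shape != g.shape:
            raise DimensionMismatchError("history vectors must match the gradient length")
        sy = float(s @ y)
        if sy > curvature_eps * np.linalg.norm(s) * np.linalg.norm(y):
            pairs.append((s, y, sy))
    if not pairs:
        gmax = np.max(np.abs(g)) if g.size else 0.0
        return -g / gmax if gmax > 0 else -g

    q = g.copy()
    alphas = []
    for s, y, sy in reversed(pairs):
        rho = 1.0 / sy
        alpha = rho * (s @ q)
        q -= alpha * y
        alphas.append((alpha, rho))
    s_new, y_new, sy_new = pairs[-1]
    gamma = sy_new / float(y_new @ y_new)
    r = gamma * q
    for (s, y, sy), (alpha, rho) in zip(pairs, reversed(alphas)):
        beta = rho * (y @ r)
        r += (alpha - beta) * s
    return -r


def _max_norm(g: np.ndarray) -> float:
    return float(np.max(np.abs(g))) if g.size else 0.0


def lbfgs_minimize(
    fun: Objective,
    x0: np.ndarray,
    config: Optional[LbfgsConfig] = None,
) -> Tuple[np.ndarray, OptimizerTrace]:
    """Minimize ``fun`` (returning (value, gradient)) by L-BFGS.

    Returns the best point found and the per-iteration trace. Accepted steps
    satisfy the Armijo condition, so the traced objective never increases.
    On line-search failure a steepest-descent fallback step is attempted; if
    that also fails the run stops with a warning.
    """
    cfg = config or LbfgsConfig()
    x = np.asarray(x0, dtype=float).ravel().copy()
    f, g = fun(x)
    g = np.asarray(g, dtype=float).ravel()
    if not (np.isfinite(f) and np.all(np.isfinite(g))):
        raise NotFiniteError("objective or gradient non-finite at the initial point")

    fevals = 1
    trace = _TraceBuilder()
    trace.add(0, f, _max_norm(g), 0.0, fevals)
    S: List[np.ndarray] = []
    Yd: List[np.ndarray] = []
    objs = [f]
    stop_reason = "max_iter"

    for it in range(1, cfg.max_iter + 1):
        if _max_norm(g) <= cfg.grad_tol:
            stop_reason = "grad_tol"
            break

        d = two_loop_direction(S, Yd, g)
        gd = float(g @ d)
        if gd >= 0:  # not a descent direction; reset
            d = -g
            gd = float(g @ d)

        def _backtrack(d, gd, t0):
            t = t0
            for _ in range(cfg.max_backtracks + 1):
                xn = x + t * d
                fn, gn = fun(xn)
                nonlocal_fev[0] += 1
                if np.isfinite(fn) and fn <= f + cfg.c1 * t * gd:
                    return t, xn, fn, np.asarray(gn, dtype=float).ravel()
                t *= cfg.backtrack
            return None

        nonlocal_fev = [fevals]
        result = _backtrack(d, gd, 1.0)
        if result is None:
            # quasi-Newton step rejected everywhere: steepest-descent fallback
            warnings.warn(
                f"line search failed at iteration {it}; falling back to "
                "steepest descent",
                stacklevel=2,
            )
            d = -g
            gd = float(g @ d)
            result = _backtrack(d, gd, 1.0 / max(1.0, _max_norm(g)))
        fevals = nonlocal_fev[0]
        if result is None:
            stop_reason = "line_search_failure"
            break

        t, xn, fn, gn = result
        s = xn - x
        yv = gn - g
        x, f, g = xn, fn, gn
        S.append(s)
        Yd.append(yv)
        if len(S) > cfg.rank:
            S.pop(0)
            Yd.pop(0)

        objs.append(f)
        trace.add(it, f, _max_norm(g), t, fevals)

        if len(objs) > cfg.patience:
            ref = objs[-cfg.patience - 1]
            if (ref - f) <= cfg.obj_rel_tol * max(1.0, abs(ref)):
                stop_reason = "obj_rel_tol"
                break

    return x, trace.build(converged_by=stop_reason)


def momentum_gd_minimize(
    fun: Objective,
    x0: np.ndarray,
    learning_rate: float = 200.0,
    momentum: float = 0.8,
    max_iter: int = 1000,
    grad_tol: float = 0.0,
    divergence_patience: int = 50,
) -> Tuple[np.ndarray, OptimizerTrace]:
    """Heavy-ball gradient descent: v <- momentum*v - lr*g; x <- x + v.

    The trace records the same fields as :func:`lbfgs_minimize` so the two
    methods can be compared level-by-level. If the objective increases for
    ``divergence_patience`` consecutive iterations the run stops and the
    trace is flagged as diverged.
    """
    if learning_rate <= 0:
        raise ValueError("learning_rate must be > 0")
    if not (0.0 <= momentum < 1.0):
        raise ValueError("momentum must be in [0, 1)")
    x = np.asarray(x0, dtype=float).ravel().copy()
    f, g = fun(x)
    g = np.asarray(g, dtype=float).ravel()
    if not (np.isfinite(f) and np.all(np.isfinite(g))):
        raise NotFiniteError("objective or gradient non-finite at the initial point")

    fevals = 1
    trace = _TraceBuilder()
    trace.add(0, f, _max_norm(g), 0.0, fevals)
    v = np.zeros_like(x)
    rising = 0
    diverged = False
    stop_reason = "max_iter"

    for it in range(1, max_iter + 1):
        if grad_tol > 0 and _max_norm(g) <= grad_tol:
            stop_reason = "grad_tol"
            break
        v = momentum * v - learning_rate * g
        x = x + v
        fn, g = fun(x)
        g = np.asarray(g, dtype=float).ravel()
        fevals += 1
        trace.add(it, fn, _max_norm(g), _max_norm(v), fevals)
        rising = rising + 1 if fn > f else 0
        f = fn
        if rising >= divergence_patience:
            warnings.warn(
                "momentum gradient descent diverged: objective increased for "
                f"{divergence_patience} consecutive iterations",
                stacklevel=2,
            )
            diverged = True
            stop_reason = "diverged"
            break

    return x, trace.build(diverged=diverged, converged_by=stop_reason)


def iterations_for_equal_progress(
    trace_a: OptimizerTrace, trace_b: OptimizerTrace
) -> List[Tuple[int, int]]:
    """Pair each iteration of ``trace_a`` with the first iteration of
    ``trace_b`` reaching an objective at least as low.

    Only objective levels inside the overlap of the two achieved ranges are
    paired. Running minima are used, so non-monotone traces are handled.
    """
    oa = np.minimum.accumulate(np.asarray(trace_a.objective, dtype=float))
    ob = np.minimum.accumulate(np.asarray(trace_b.objective, dtype=float))
    lo = max(oa[-1], ob[-1])
    hi = min(oa[0], ob[0])
    if lo > hi:
        raise DisjointTraceError("the two traces share no common objective range")
    ia = np.asarray(trace_a.iterations)
    ib = np.asarray(trace_b.iterations)
    pairs: List[Tuple[int, int]] = []
    for k in range(1, oa.size):
        level = oa[k]
        if level > hi or level < lo:
            continue
        j = int(np.argmax(ob <= level))  # first index reaching the level
        pairs.append((int(ia[k]), int(ib[j])))
    return pairs


def fit_convergence_exponent(
    pairs: Sequence[Tuple[float, float]],
    n_initial: Optional[int] = None,
) -> float:
    """Least-squares slope of log(iter_b) on log(iter_a).

    A slope of 1 means the two methods progress at proportional iteration
    counts; a slope of 2 means method a needs only ~sqrt as many iterations
    (quadratic versus linear convergence). ``n_initial`` restricts the fit to
    the first pairs (the initial phase of the optimization).
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise DimensionMismatchError("pairs must be a sequence of (iter_a, iter_b)")
    if n_initial is not None:
        arr = arr[:n_initial]
    arr = arr[(arr[:, 0] > 0) & (arr[:, 1] > 0)]
    if arr.shape[0] < 5:
        raise InsufficientDataError(
            f"need at least 5 positive pairs to fit an exponent, got {arr.shape[0]}"
        )
    la, lb = np.log(arr[:, 0]), np.log(arr[:, 1])
    slope = np.polyfit(la, lb, 1)[0]
    return float(slope)
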