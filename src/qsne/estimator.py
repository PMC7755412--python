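"""Scikit-learn-style estimator wrapping the full pipeline."""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
from sklearn.base import BaseEstimator

from .affinities import build_affinities, pairwise_sq_distances
from .autoperplexity import (
    affinities_from_solution,
    entropy_curves,
    locate_insensitive_optimum,
    tune_per_sample,
)
from .data import as_values
from .exceptions import PerplexityRangeError
from .objective import kl_objective, make_tsne_problem
from .optimizers import LbfgsConfig, lbfgs_minimize, momentum_gd_minimize
from .quality import evaluate_quality

__all__ = ["QSNE"]


class QSNE(BaseEstimator):
    """Exact t-SNE with a quasi-Newton optimizer and automatic perplexity.

    Embeds a sample-by-feature matrix into ``n_components`` dimensions by
    minimizing KL(P || Q) between the calibrated Gaussian input-neighbor
    distribution P and the Student-t output distribution Q. The optimizer is
    a limited-memory BFGS scheme (rank ``rank`` inverse-Hessian
    approximation) with backtracking line search; a classical momentum
    gradient descent is available as a baseline.

    Parameters
    ----------
    n_components : int, default 2
        Embedding dimension e.
    perplexity : float, default 30.0
        Fixed target perplexity (effective number of neighbors). Ignored
        when ``perplexity_range`` is set.
    perplexity_range : (float, float), optional
        Enables automatic selection: the flattest (least sensitive) pivot
        perplexity is located in this range, then each sample's perplexity
        is refined within ``tune_window`` around it.
    tune_window : (float, float), default (0.5, 2.0)
        Multiplicative per-sample tuning window around the pivot (auto mode).
    optimizer : {"lbfgs", "gd"}, default "lbfgs"
    rank : int, default 11
        History length (Hessian-approximation rank) of the L-BFGS optimizer.
    max_iter, grad_tol, obj_rel_tol
        Optimizer budget and stopping tolerances.
    learning_rate, momentum
        Momentum gradient-descent settings (optimizer="gd").
    init : {"random", "pca"}, default "random"
        Random Gaussian (SD 1e-4) or PCA initialization of the embedding.
    early_exaggeration : bool, default False
        If True, multiply P by ``exaggeration_factor`` for the first
        ``exaggeration_iter`` iterations (classical scheme; off by default).
    sigma_grid_size : int, default 64
        Bandwidth grid resolution for the entropy staircase (auto mode).
    random_state : int, Generator or None
        Seed for all randomness (embedding initialization).

    Attributes
    ----------
    embedding_ : (m, n_components) optimized coordinates.
    kl_divergence_ : final joint KL objective value (nats).
    sigma_ : (m,) calibrated per-sample bandwidths.
    entropy_ : (m,) per-sample neighborhood entropies H(P_i*) (nats).
    effective_perplexity_ : (m,) exp(entropy_).
    pivot_perplexity_ : located pivot (auto mode only, else None).
    quality_ : :class:`~qsne.quality.QualityReport` for the embedding.
    trace_ : :class:`~qsne.optimizers.OptimizerTrace` of the run.
    """

    def __init__(
        self,
        n_components: int = 2,
        perplexity: float = 30.0,
        perplexity_range: Optional[Tuple[float, float]] = None,
        tune_window: Tuple[float, float] = (0.5, 2.0),
        optimizer: str = "lbfgs",
        rank: int = 11,
        max_iter: int = 1000,
        grad_tol: float = 1e-7,
        obj_rel_tol: float = 1e-9,
        learning_rate: float = 200.0,
        momentum: float = 0.8,
        init: str = "random",
        early_exaggeration: bool = False,
        exaggeration_factor: float = 12.0,
        exaggeration_iter: int = 250,
        sigma_grid_size: int = 64,
        random_state=None,
        verbose: int = 0,
    ):
        self.n_components = n_components
        self.perplexity = perplexity
        self.perplexity_range = perplexity_range
        self.tune_window = tune_window
        self.optimizer = optimizer
        self.rank = rank
        self.max_iter = max_iter
        self.grad_tol = grad_tol
        self.obj_rel_tol = obj_rel_tol
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.init = init
        self.early_exaggeration = early_exaggeration
        self.exaggeration_factor = exaggeration_factor
        self.exaggeration_iter = exaggeration_iter
        self.sigma_grid_size = sigma_grid_size
        self.random_state = random_state
        self.verbose = verbose

    def _initial_embedding(self, V: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        m = V.shape[0]
        if self.init == "random":
            return rng.normal(scale=1e-4, size=(m, self.n_components))
        if self.init == "pca":
            from sklearn.decomposition import PCA

            Y0 = PCA(n_components=self.n_components, svd_solver="full").fit_transform(V)
            s = Y0[:, 0].std()
            return Y0 / s * 1e-4 if s > 0 else Y0
        raise ValueError(f"unknown init scheme {self.init!r}")

    def fit(self, X, y=None):
        """Compute the embedding of X; returns self."""
        self.fit_transform(X)
        return self

    def fit_transform(self, X, y=None) -> np.ndarray:
        """Compute and return the (m, n_components) embedding of X."""
        V = as_values(X)
        m = V.shape[0]
        rng = np.random.default_rng(self.random_state)
        D2 = pairwise_sq_distances(V)

        if self.perplexity_range is not None:
            curve = entropy_curves(V, sigma_grid_size=self.sigma_grid_size, D2=D2)
            pivot = locate_insensitive_optimum(curve, tuple(self.perplexity_range))
            sol = tune_per_sample(
                V, pivot, tuple(self.tune_window), curve=curve, D2=D2
            )
            model = affinities_from_solution(V, sol, D2=D2)
            self.pivot_perplexity_ = float(pivot)
        else:
            if not (1.0 < self.perplexity < m - 1):
                raise PerplexityRangeError(
                    f"perplexity must lie in (1, m-1) = (1, {m - 1}), got "
                    f"{self.perplexity}"
                )
            model = build_affinities(V, float(self.perplexity), D2=D2)
            self.pivot_perplexity_ = None

        P = model.joint
        Y0 = self._initial_embedding(V, rng)
        Y, trace = self._optimize(P, Y0)

        self.n_features_in_ = V.shape[1]
        self.affinity_model_ = model
        self.sigma_ = model.sigma
        self.entropy_ = model.entropy
        self.effective_perplexity_ = model.effective_perplexity
        self.embedding_ = Y
        self.trace_ = trace
        self.kl_divergence_ = kl_objective(P, Y)
        self.quality_ = evaluate_quality(model.entropy, model.cond_rows, Y)
        return Y

    def _optimize(self, P: np.ndarray, Y0: np.ndarray):
        m = P.shape[0]
        e = self.n_components
        x0 = Y0.ravel()

        if self.optimizer == "lbfgs":
            cfg = LbfgsConfig(
                rank=self.rank,
                max_iter=self.max_iter,
                grad_tol=self.grad_tol,
                obj_rel_tol=self.obj_rel_tol,
            )
            if self.early_exaggeration:
                ex_cfg = LbfgsConfig(
                    rank=self.rank,
                    max_iter=min(self.exaggeration_iter, self.max_iter),
                    grad_tol=self.grad_tol,
                    obj_rel_tol=self.obj_rel_tol,
                )
                fun_ex = make_tsne_problem(P * self.exaggeration_factor, e)
                x0, _ = lbfgs_minimize(fun_ex, x0, ex_cfg)
            x, trace = lbfgs_minimize(make_tsne_problem(P, e), x0, cfg)
        elif self.optimizer == "gd":
            if self.early_exaggeration:
                fun_ex = make_tsne_problem(P * self.exaggeration_factor, e)
                x0, _ = momentum_gd_minimize(
                    fun_ex,
                    x0,
                    learning_rate=self.learning_rate,
                    momentum=self.momentum,
                    max_iter=min(self.exaggeration_iter, self.max_iter),
                )
            x, trace = momentum_gd_minimize(
                make_tsne_problem(P, e),
                x0,
                learning_rate=self.learning_rate,
                momentum=self.momentum,
                max_iter=self.max_iter,
                grad_tol=self.grad_tol,
            )
        else:
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        return x.reshape(m, e), trace
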