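"""The t-SNE objective: KL(P || Q) under a Student-t output kernel.

Q is defined from the embedding Y by the heavy-tailed kernel
w_ij = (1 + ||y_i - y_j||^2)^-1 (one degree of freedom), normalized over all
ordered pairs. The objective is C = sum_ij p_ij log(p_ij / q_ij), with the
convention that terms with p_ij = 0 contribute nothing; its exact gradient is
dC/dy_i = 4 sum_j (p_ij - q_ij) w_ij (y_i - y_j).

Everything here is dense O(m^2): the point is the exact objective, not an
approximation of it.
"""

from __future__ import annotations

from typing import Callable, Tuple

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .exceptions import DimensionMismatchError, InsufficientDataError, NotFiniteError

__all__ = [
    "output_affinities",
    "kl_objective",
    "kl_gradient",
    "kl_objective_and_gradient",
    "make_tsne_problem",
]

_Q_FLOOR = 1e-300


def _embedding_array(Y) -> np.ndarray:
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if Y.ndim != 2:
        raise DimensionMismatchError("embedding must be a 2-D array")
    if Y.shape[0] < 2:
        raise InsufficientDataError("embedding needs at least 2 samples")
    if not np.all(np.isfinite(Y)):
        raise NotFiniteError("embedding contains non-finite coordinates")
    return Y


def output_affinities(Y) -> Tuple[np.ndarray, np.ndarray]:
    """Student-t output distribution Q and its unnormalized kernel W.

    Returns
    -------
    Q : (m, m) matrix summing to 1 over all ordered pairs, zero diagonal.
    W : (m, m) kernel (1 + ||y_i - y_j||^2)^-1 with zero diagonal.
    """
    Y = _embedding_array(Y)
    D2 = squareform(pdist(Y, metric="sqeuclidean"))
    W = 1.0 / (1.0 + D2)
    np.fill_diagonal(W, 0.0)
    Q = W / W.sum()
    return Q, W


def _check_pair(P: np.ndarray, Y: np.ndarray) -> None:
    if P.shape[0] != P.shape[1] or P.shape[0] != Y.shape[0]:
        raise DimensionMismatchError(
            f"joint distribution {P.shape} does not match embedding with "
            f"{Y.shape[0]} samples"
        )


def kl_objective(P, Y) -> float:
    """C = KL(P || Q(Y)) in nats; zero iff Q matches P entrywise."""
    P = np.asarray(P, dtype=float)
    Y = _embedding_array(Y)
    _check_pair(P, Y)
    Q, _ = output_affinities(Y)
    mask = P > 0
    return float(
        np.sum(P[mask] * (np.log(P[mask]) - np.log(np.maximum(Q[mask], _Q_FLOOR))))
    )


def kl_gradient(P, Y) -> np.ndarray:
    """Exact gradient of :func:`kl_objective` with respect to Y (m-by-e)."""
    _, G = kl_objective_and_gradient(P, Y)
    return G


def kl_objective_and_gradient(P, Y) -> Tuple[float, np.ndarray]:
    """Objective and gradient in one pass (shared kernel evaluation)."""
    P = np.asarray(P, dtype=float)
    Y = _embedding_array(Y)
    _check_pair(P, Y)
    Q, W = output_affinities(Y)
    mask = P > 0
    C = float(
        np.sum(P[mask] * (np.log(P[mask]) - np.log(np.maximum(Q[mask], _Q_FLOOR))))
    )
    M = (P - Q) * W
    G = 4.0 * (M.sum(axis=1)[:, None] * Y - M @ Y)
    return C, G


def make_tsne_problem(P, n_components: int) -> Callable[[np.ndarray], Tuple[float, np.ndarray]]:
    """Wrap the objective as a flat-vector callable for generic optimizers."""
    P = np.asarray(P, dtype=float)
    m = P.shape[0]

    def fun(x: np.ndarray) -> Tuple[float, np.ndarray]:
        Y = x.reshape(m, n_components)
        C, G = kl_objective_and_gradient(P, Y)
        return C, G.ravel()

    return fun
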