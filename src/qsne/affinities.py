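"""High-dimensional neighbor distributions for t-SNE.

Each sample i gets a Gaussian kernel of bandwidth sigma_i over its squared
Euclidean distances to the other samples. The bandwidth is calibrated so that
the perplexity exp(H(P_i)) of the conditional distribution P_i matches a
target, and the conditional rows are symmetrized into the joint distribution
p_ij = (p_{j|i} + p_{i|j}) / (2m).

Entropies are in nats throughout; perplexity == exp(entropy).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple, Union

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .data import as_values
from .exceptions import (
    BracketingError,
    DegenerateDataError,
    DimensionMismatchError,
    NormalizationError,
    NotFiniteError,
    PerplexityRangeError,
)

__all__ = [
    "AffinityModel",
    "pairwise_sq_distances",
    "row_entropy_at_bandwidth",
    "bandwidth_for_perplexity",
    "bandwidths_for_perplexities",
    "conditionals_to_joint",
    "conditional_rows_at_bandwidths",
    "build_affinities",
]

# probabilities are floored here before taking logs
_P_FLOOR = 1e-300


@dataclass
class AffinityModel:
    """Calibrated input-space neighbor model.

    Attributes
    ----------
    sigma : (m,) per-sample Gaussian bandwidths sigma_i > 0.
    cond_rows : (m, m) conditional probabilities p_{j|i}, zero diagonal,
        each row summing to 1.
    joint : (m, m) symmetric joint distribution p_ij, total mass 1.
    entropy : (m,) per-sample neighborhood entropies H(P_i) in nats.
    perplexity_target : scalar target perplexity, or (m,) per-sample targets.
    """

    sigma: np.ndarray
    cond_rows: np.ndarray
    joint: np.ndarray
    entropy: np.ndarray
    perplexity_target: Union[float, np.ndarray]

    @property
    def effective_perplexity(self) -> np.ndarray:
        """exp(H(P_i)) for each sample."""
        return np.exp(self.entropy)


def pairwise_sq_distances(X) -> np.ndarray:
    """Symmetric m-by-m matrix of squared Euclidean distances.

    Raises :class:`NotFiniteError` on non-finite input.
    """
    V = as_values(X)
    D2 = squareform(pdist(V, metric="sqeuclidean"))
    np.maximum(D2, 0.0, out=D2)
    return D2


def _entropy_from_scaled(b: np.ndarray, axis: int = -1) -> Tuple[np.ndarray, np.ndarray]:
    """Entropy and probabilities from shifted scaled exponents b >= 0.

    ``b`` holds d^2/(2 sigma^2) minus its row minimum, with +inf marking
    excluded (self or infinitely distant) entries.
    """
    w = np.exp(-b)
    z = w.sum(axis=axis, keepdims=True)
    p = w / z
    h = -np.sum(p * np.log(np.maximum(p, _P_FLOOR)), axis=axis)
    return h, p


def row_entropy_at_bandwidth(sq_dists_row, sigma: float) -> Tuple[float, np.ndarray]:
    """Neighborhood entropy and conditional probabilities for one sample.

    Parameters
    ----------
    sq_dists_row
        Squared distances to the other m-1 samples (self excluded). Entries
        may be +inf (zero weight) but at least one must be finite.
    sigma
        Gaussian bandwidth, > 0.

    Returns
    -------
    H : float
        Entropy in nats, in [0, log(m-1)].
    p_row : ndarray
        Probabilities proportional to exp(-d^2 / (2 sigma^2)), summing to 1.
    """
    r = np.asarray(sq_dists_row, dtype=float).ravel()
    if not sigma > 0:
        raise PerplexityRangeError(f"sigma must be > 0, got {sigma}")
    if r.size < 1:
        raise DegenerateDataError("empty distance row")
    if np.any(np.isnan(r)) or np.any(r < 0):
        raise NotFiniteError("squared distances must be non-negative and not NaN")
    finite = np.isfinite(r)
    if not finite.any():
        raise DegenerateDataError("all distances are infinite")
    a = r / (2.0 * sigma * sigma)
    b = a - a[finite].min()
    h, p = _entropy_from_scaled(b)
    return float(h), p


def _row_perplexity(r: np.ndarray, finite: np.ndarray, sigma: float) -> float:
    a = r / (2.0 * sigma * sigma)
    b = a - a[finite].min()
    h, _ = _entropy_from_scaled(b)
    return float(np.exp(h))


def bandwidth_for_perplexity(
    sq_dists_row,
    perplexity: float,
    tol: float = 1e-5,
    max_iter: int = 64,
) -> float:
    """Bandwidth sigma such that exp(H(sigma)) matches ``perplexity``.

    Brackets the monotone perplexity curve by doubling/halving sigma from the
    median distance, then bisects in log-sigma until
    ``|exp(H) - perplexity| <= tol * perplexity``.
    """
    r = np.asarray(sq_dists_row, dtype=float).ravel()
    n = r.size
    if not (1.0 < perplexity <= n):
        raise PerplexityRangeError(
            f"perplexity must lie in (1, {n}] for {n} neighbors, got {perplexity}"
        )
    finite = np.isfinite(r)
    if not finite.any():
        raise DegenerateDataError("all distances are infinite")
    if np.max(r[finite]) == 0:
        # duplicate point: uniform row and H = log(m-1) at any bandwidth
        warnings.warn(
            "all neighbor distances are zero; conditional row is uniform at "
            "any bandwidth",
            stacklevel=2,
        )
        return 1.0
    dmed = float(np.median(np.sqrt(r[finite])))
    sigma0 = dmed if dmed > 0 else 1.0

    f0 = _row_perplexity(r, finite, sigma0)
    if abs(f0 - perplexity) <= tol * perplexity:
        return sigma0

    # bracket by doubling or halving
    lo = hi = sigma0
    if f0 < perplexity:
        for _ in range(max_iter):
            lo, hi = hi, hi * 2.0
            fhi = _row_perplexity(r, finite, hi)
            if abs(fhi - perplexity) <= tol * perplexity:
                return hi
            if fhi >= perplexity:
                break
        else:
            raise BracketingError(
                f"could not bracket perplexity {perplexity} within {max_iter} "
                "doublings"
            )
    else:
        for _ in range(max_iter):
            hi, lo = lo, lo / 2.0
            flo = _row_perplexity(r, finite, lo)
            if abs(flo - perplexity) <= tol * perplexity:
                return lo
            if flo <= perplexity:
                break
        else:
            raise BracketingError(
                f"could not bracket perplexity {perplexity} within {max_iter} "
                "halvings"
            )

    ulo, uhi = np.log(lo), np.log(hi)
    mid = sigma0
    for _ in range(max_iter):
        umid = 0.5 * (ulo + uhi)
        mid = float(np.exp(umid))
        fm = _row_perplexity(r, finite, mid)
        if abs(fm - perplexity) <= tol * perplexity:
            return mid
        if fm < perplexity:
            ulo = umid
        else:
            uhi = umid
    return mid


def _offdiag_scaled(D2: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Shifted scaled exponents with +inf on the diagonal."""
    a = D2 / (2.0 * sigma[:, None] ** 2)
    np.fill_diagonal(a, np.inf)
    amin = np.min(a, axis=1)
    return a - amin[:, None]


def conditional_rows_at_bandwidths(
    D2: np.ndarray, sigma: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Conditional probability rows and entropies at given per-sample sigmas.

    Returns ``(entropy, cond_rows)`` with ``cond_rows[i, i] == 0`` and each
    row summing to 1.
    """
    sigma = np.asarray(sigma, dtype=float).ravel()
    if sigma.shape[0] != D2.shape[0]:
        raise DimensionMismatchError(
            f"{sigma.shape[0]} bandwidths for {D2.shape[0]} samples"
        )
    if np.any(sigma <= 0):
        raise PerplexityRangeError("all bandwidths must be > 0")
    b = _offdiag_scaled(D2, sigma)
    h, p = _entropy_from_scaled(b, axis=1)
    return h, p


def _perplexities_at(D2: np.ndarray, idx: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Perplexities for selected rows at per-row sigmas (vectorized)."""
    a = D2[idx] / (2.0 * sigma[:, None] ** 2)
    a[np.arange(idx.size), idx] = np.inf
    amin = np.min(a, axis=1)
    h, _ = _entropy_from_scaled(a - amin[:, None], axis=1)
    return np.exp(h)


def bandwidths_for_perplexities(
    D2: np.ndarray,
    perplexity,
    tol: float = 1e-5,
    max_iter: int = 64,
) -> np.ndarray:
    """Vectorized bandwidth calibration for all samples at once.

    ``perplexity`` is a scalar or an (m,) vector of per-sample targets; the
    same bracketing-expansion plus log-space bisection as
    :func:`bandwidth_for_perplexity` runs for every row simultaneously.
    """
    m = D2.shape[0]
    target = np.broadcast_to(np.asarray(perplexity, dtype=float), (m,)).copy()
    if np.any(target <= 1.0) or np.any(target > m - 1):
        raise PerplexityRangeError(
            f"per-sample perplexities must lie in (1, {m - 1}]"
        )
    off = D2 + np.where(np.eye(m, dtype=bool), np.nan, 0.0)
    dmed = np.sqrt(np.nanmedian(off, axis=1))
    degenerate = np.nanmax(off, axis=1) == 0
    if np.any(degenerate):
        # duplicate points: uniform rows and H = log(m-1) at any bandwidth
        warnings.warn(
            "some samples have all-zero neighbor distances; their rows are "
            "uniform at any bandwidth",
            stacklevel=2,
        )
    sigma0 = np.where(dmed > 0, dmed, 1.0)

    all_idx = np.arange(m)
    perp0 = _perplexities_at(D2, all_idx, sigma0)
    done = (np.abs(perp0 - target) <= tol * target) | degenerate
    sigma = sigma0.copy()

    ulo = np.log(sigma0)
    uhi = np.log(sigma0)
    # expand brackets upward where perplexity is too small
    need_up = (~done) & (perp0 < target)
    step = np.log(2.0)
    active = np.flatnonzero(need_up)
    for _ in range(max_iter):
        if active.size == 0:
            break
        uhi[active] += step
        perp = _perplexities_at(D2, active, np.exp(uhi[active]))
        ok = np.abs(perp - target[active]) <= tol * target[active]
        ulo[active[ok]] = uhi[active[ok]]  # collapse bracket: already solved
        reached = (perp >= target[active]) | ok
        ulo[active[~reached]] = uhi[active[~reached]]
        active = active[~reached]
    if active.size:
        raise BracketingError("failed to bracket target perplexity from above")
    # expand brackets downward where perplexity is too large
    need_dn = (~done) & (perp0 > target)
    active = np.flatnonzero(need_dn)
    for _ in range(max_iter):
        if active.size == 0:
            break
        ulo[active] -= step
        perp = _perplexities_at(D2, active, np.exp(ulo[active]))
        ok = np.abs(perp - target[active]) <= tol * target[active]
        uhi[active[ok]] = ulo[active[ok]]  # collapse bracket: already solved
        reached = (perp <= target[active]) | ok
        uhi[active[~reached]] = ulo[active[~reached]]
        active = active[~reached]
    if active.size:
        raise BracketingError("failed to bracket target perplexity from below")

    active = np.flatnonzero(~done)
    for _ in range(max_iter):
        if active.size == 0:
            break
        umid = 0.5 * (ulo[active] + uhi[active])
        perp = _perplexities_at(D2, active, np.exp(umid))
        sigma[active] = np.exp(umid)
        ok = np.abs(perp - target[active]) <= tol * target[active]
        low = perp < target[active]
        ulo[active[low & ~ok]] = umid[low & ~ok]
        uhi[active[~low & ~ok]] = umid[~low & ~ok]
        active = active[~ok]
    return sigma


def conditionals_to_joint(cond_rows: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    """Symmetrize conditional rows into the joint: p_ij = (p_{j|i}+p_{i|j})/(2m)."""
    C = np.asarray(cond_rows, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise DimensionMismatchError("conditional rows must form a square matrix")
    m = C.shape[0]
    if np.any(np.abs(np.diagonal(C)) > tol):
        raise NormalizationError("self-probabilities p_{i|i} must be zero")
    sums = C.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > tol):
        bad = int(np.argmax(np.abs(sums - 1.0)))
        raise NormalizationError(
            f"conditional row {bad} sums to {sums[bad]:.6g}, expected 1"
        )
    P = (C + C.T) / (2.0 * m)
    return P


def build_affinities(
    X,
    perplexity,
    tol: float = 1e-5,
    max_iter: int = 64,
    D2: Optional[np.ndarray] = None,
) -> AffinityModel:
    """Calibrate bandwidths to ``perplexity`` and build the full affinity model.

    ``perplexity`` may be a scalar (classic fixed-perplexity t-SNE) or an
    (m,) vector of per-sample targets.
    """
    if D2 is None:
        D2 = pairwise_sq_distances(X)
    sigma = bandwidths_for_perplexities(D2, perplexity, tol=tol, max_iter=max_iter)
    entropy, cond = conditional_rows_at_bandwidths(D2, sigma)
    joint = conditionals_to_joint(cond)
    return AffinityModel(
        sigma=sigma,
        cond_rows=cond,
        joint=joint,
        entropy=entropy,
        perplexity_target=perplexity,
    )
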