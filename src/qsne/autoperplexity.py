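"""Automatic perplexity and bandwidth selection from entropy staircases.

For every sample the neighborhood entropy H(P_i) rises monotonically from 0
to log(m-1) as the bandwidth sigma_i grows. Where the data have discrete
scales (clusters within clusters) the curve is a staircase: flat plateaus are
bandwidth ranges over which the neighborhood structure is insensitive, and
the sensitivity |dH/d log sigma| is near zero there. Interesting perplexities
sit on those plateaus — small bandwidth perturbations do not change the
neighbor distribution, so the embedding is stable to the parameter choice.

The selector works in three stages:

1. :func:`entropy_curves` traces H_i over a log-spaced sigma grid and
   differentiates it to get per-sample sensitivities.
2. :func:`locate_insensitive_optimum` golden-sections a user-given perplexity
   range, minimizing the median per-sample sensitivity, and returns a single
   pivot perplexity.
3. :func:`tune_per_sample` refines each sample's own perplexity within a
   multiplicative window (default [1/2, 2]) around the pivot, minimizing that
   sample's sensitivity — different regions of the space may settle on
   different scales.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .affinities import (
    AffinityModel,
    bandwidths_for_perplexities,
    conditional_rows_at_bandwidths,
    conditionals_to_joint,
    pairwise_sq_distances,
)
from .data import as_values
from .exceptions import DegenerateDataError, PerplexityRangeError

__all__ = [
    "EntropyCurve",
    "PerplexitySolution",
    "entropy_curves",
    "locate_insensitive_optimum",
    "tune_per_sample",
    "affinities_from_solution",
    "scan_report",
    "plot_staircase",
]

_INVPHI = (np.sqrt(5.0) - 1.0) / 2.0


@dataclass
class EntropyCurve:
    """Per-sample entropy staircase over a shared bandwidth grid.

    Attributes
    ----------
    sigma_grid : (G,) increasing, log-spaced bandwidths.
    H : (m, G) per-sample entropies in nats.
    sensitivity : (m, G) centered finite-difference estimates of
        dH/d(log sigma), non-negative up to numerical noise.
    """

    sigma_grid: np.ndarray
    H: np.ndarray
    sensitivity: np.ndarray

    @property
    def log_sigma(self) -> np.ndarray:
        return np.log(self.sigma_grid)

    @property
    def perplexity(self) -> np.ndarray:
        """exp(H): per-sample effective perplexity at each grid bandwidth."""
        return np.exp(self.H)

    def _monotone_H(self) -> np.ndarray:
        return np.maximum.accumulate(self.H, axis=1)

    def log_sigma_at_perplexity(self, pi) -> np.ndarray:
        """Per-sample log-bandwidth where exp(H_i) = pi (grid interpolation).

        ``pi`` may be a scalar (shared target) or an (m,) vector of
        per-sample targets.
        """
        Hm = self._monotone_H()
        m = Hm.shape[0]
        h = np.broadcast_to(np.log(np.asarray(pi, dtype=float)), (m,))
        lg = self.log_sigma
        G = lg.size
        k = np.clip((Hm < h[:, None]).sum(axis=1), 1, G - 1)
        rows = np.arange(m)
        h0 = Hm[rows, k - 1]
        h1 = Hm[rows, k]
        w = np.where(h1 > h0, (h - h0) / np.where(h1 > h0, h1 - h0, 1.0), 0.5)
        w = np.clip(w, 0.0, 1.0)
        return lg[k - 1] + w * (lg[k] - lg[k - 1])

    def sensitivity_at_log_sigma(self, log_sigma: np.ndarray) -> np.ndarray:
        """Per-sample |dH/d log sigma| interpolated at given log-bandwidths."""
        lg = self.log_sigma
        G = lg.size
        pos = np.clip(np.searchsorted(lg, log_sigma, side="right"), 1, G - 1)
        rows = np.arange(self.sensitivity.shape[0])
        x0, x1 = lg[pos - 1], lg[pos]
        s0 = self.sensitivity[rows, pos - 1]
        s1 = self.sensitivity[rows, pos]
        w = np.clip((log_sigma - x0) / (x1 - x0), 0.0, 1.0)
        return np.abs(s0 + w * (s1 - s0))

    def sensitivity_at_perplexity(self, pi) -> np.ndarray:
        """Per-sample sensitivity at the bandwidth matching ``pi``.

        ``pi`` may be a scalar or an (m,) vector of per-sample perplexities.
        """
        return self.sensitivity_at_log_sigma(self.log_sigma_at_perplexity(pi))


@dataclass
class PerplexitySolution:
    """Per-sample optimized bandwidths and effective perplexities.

    sigma_star[i] > 0 is the selected bandwidth, H_star[i] the entropy
    H(P_i*) there, and pi_star[i] = exp(H_star[i]) the effective perplexity.
    """

    sigma_star: np.ndarray
    pi_star: np.ndarray
    H_star: np.ndarray
    pivot: Optional[float] = None
    window: Optional[Tuple[float, float]] = None


def entropy_curves(
    X,
    sigma_grid_size: int = 64,
    sigma_range: Optional[Tuple[float, float]] = None,
    D2: Optional[np.ndarray] = None,
) -> EntropyCurve:
    """Trace per-sample entropy and sensitivity over a log-spaced sigma grid.

    The default grid spans ``[1e-3, 1e3]`` times the median pairwise distance,
    which covers all distance scales present in the data.
    """
    if sigma_grid_size < 16:
        raise PerplexityRangeError("sigma_grid_size must be >= 16")
    if D2 is None:
        D2 = pairwise_sq_distances(as_values(X))
    m = D2.shape[0]
    iu = np.triu_indices(m, k=1)
    if np.max(D2[iu]) == 0.0:
        raise DegenerateDataError("all samples are identical; no distance scales")
    if sigma_range is None:
        dmed = float(np.median(np.sqrt(D2[iu])))
        if dmed == 0.0:
            dmed = float(np.sqrt(np.max(D2[iu])))
        sigma_range = (1e-3 * dmed, 1e3 * dmed)
    lo, hi = sigma_range
    if not (0 < lo < hi):
        raise PerplexityRangeError("sigma_range must satisfy 0 < lo < hi")
    grid = np.exp(np.linspace(np.log(lo), np.log(hi), sigma_grid_size))

    H = np.empty((m, sigma_grid_size))
    for j, s in enumerate(grid):
        h, _ = conditional_rows_at_bandwidths(D2, np.full(m, s))
        H[:, j] = h
    sens = np.gradient(H, np.log(grid), axis=1)
    return EntropyCurve(sigma_grid=grid, H=H, sensitivity=sens)


def _aggregate_sensitivity(curve: EntropyCurve, log_pi: float) -> float:
    return float(np.median(curve.sensitivity_at_perplexity(np.exp(log_pi))))


def locate_insensitive_optimum(
    curve: EntropyCurve,
    perplexity_range: Tuple[float, float],
    tol: float = 1e-2,
    max_evals: int = 50,
    n_scan: int = 17,
) -> float:
    """Perplexity in the given range where the staircase is flattest.

    Minimizes the median per-sample sensitivity |dH_i/d log sigma_i| over the
    range by a coarse log-spaced scan followed by golden-section refinement.
    An exactly flat aggregate returns the geometric midpoint of the range; a
    non-unimodal aggregate returns the best scan point with a warning.
    """
    # largest admissible perplexity: m-1, or what the traced entropies attain
    bound = max(curve.H.shape[0] - 1, float(np.exp(curve.H.max())))
    pi_lo, pi_hi = perplexity_range
    if not (1.0 < pi_lo < pi_hi <= bound):
        raise PerplexityRangeError(
            f"perplexity range must satisfy 1 < lo < hi <= {bound:g}, got "
            f"({pi_lo}, {pi_hi})"
        )
    a0, b0 = np.log(pi_lo), np.log(pi_hi)
    scan = np.linspace(a0, b0, n_scan)
    vals = np.array([_aggregate_sensitivity(curve, u) for u in scan])
    evals = n_scan

    spread = vals.max() - vals.min()
    if spread <= 1e-9 * max(vals.max(), 1e-12):
        return float(np.exp(0.5 * (a0 + b0)))  # flat: geometric midpoint

    # the range is assumed to hold a single sensitivity minimum; warn if a
    # second local minimum competes with the global one (within 10% of the
    # scanned spread), in which case the best scan point is returned as-is
    j = int(np.argmin(vals))
    is_locmin = np.zeros(n_scan, dtype=bool)
    is_locmin[1:-1] = (vals[1:-1] <= vals[:-2]) & (vals[1:-1] <= vals[2:])
    is_locmin[0] = vals[0] <= vals[1]
    is_locmin[-1] = vals[-1] <= vals[-2]
    competing = np.flatnonzero(
        is_locmin & (vals <= vals[j] + 0.1 * spread)
    )
    if np.any(np.abs(competing - j) > 1):
        warnings.warn(
            "aggregate sensitivity has multiple comparable minima over the "
            "requested range; returning the best scanned perplexity",
            stacklevel=2,
        )
        return float(np.exp(scan[j]))

    a = scan[max(j - 1, 0)]
    b = scan[min(j + 1, n_scan - 1)]
    while (b - a) > tol and evals + 2 <= max_evals:
        c = b - _INVPHI * (b - a)
        dd = a + _INVPHI * (b - a)
        fc = _aggregate_sensitivity(curve, c)
        fd = _aggregate_sensitivity(curve, dd)
        evals += 2
        if fc <= fd:
            b = dd
        else:
            a = c
    return float(np.exp(0.5 * (a + b)))


def tune_per_sample(
    X,
    pivot_perplexity: float,
    factor_window: Tuple[float, float] = (0.5, 2.0),
    curve: Optional[EntropyCurve] = None,
    sigma_grid_size: int = 64,
    tol: float = 1e-2,
    max_evals: int = 50,
    D2: Optional[np.ndarray] = None,
) -> PerplexitySolution:
    """Refine each sample's perplexity within a factor window around a pivot.

    Each sample independently golden-sections its own sensitivity over
    ``[w_lo * pivot, w_hi * pivot]`` (clipped to the admissible (1, m-1)),
    then the matching bandwidth sigma_i* is solved exactly by bisection and
    the entropy H(P_i*) recomputed there.
    """
    V = as_values(X)
    m = V.shape[0]
    w_lo, w_hi = factor_window
    if not (0 < w_lo <= w_hi):
        raise PerplexityRangeError(
            f"factor window must satisfy 0 < lo <= hi, got ({w_lo}, {w_hi})"
        )
    if not (1.0 < pivot_perplexity < m - 1):
        raise PerplexityRangeError(
            f"pivot perplexity must lie in (1, {m - 1}), got {pivot_perplexity}"
        )
    if D2 is None:
        D2 = pairwise_sq_distances(V)

    lo = max(w_lo * pivot_perplexity, 1.0 + 1e-6)
    hi = min(w_hi * pivot_perplexity, (m - 1) * (1.0 - 1e-9))
    if lo >= hi:
        targets = np.full(m, np.clip(pivot_perplexity, 1.0 + 1e-6, (m - 1) * (1 - 1e-9)))
    else:
        if curve is None:
            curve = entropy_curves(V, sigma_grid_size=sigma_grid_size, D2=D2)
        a = np.full(m, np.log(lo))
        b = np.full(m, np.log(hi))

        def f(u: np.ndarray) -> np.ndarray:
            # per-sample sensitivity at each sample's own candidate perplexity
            return curve.sensitivity_at_perplexity(np.exp(u))

        evals = 0
        while float(np.max(b - a)) > tol and evals + 2 <= max_evals:
            c = b - _INVPHI * (b - a)
            d = a + _INVPHI * (b - a)
            fc = f(c)
            fd = f(d)
            evals += 2
            shrink_right = fc <= fd
            b = np.where(shrink_right, d, b)
            a = np.where(shrink_right, a, c)
        targets = np.exp(0.5 * (a + b))

    sigma_star = bandwidths_for_perplexities(D2, targets)
    H_star, _ = conditional_rows_at_bandwidths(D2, sigma_star)
    return PerplexitySolution(
        sigma_star=sigma_star,
        pi_star=np.exp(H_star),
        H_star=H_star,
        pivot=float(pivot_perplexity),
        window=(float(w_lo), float(w_hi)),
    )


def affinities_from_solution(X, sol: PerplexitySolution, D2: Optional[np.ndarray] = None) -> AffinityModel:
    """Build the affinity model at the per-sample optimized bandwidths."""
    V = as_values(X)
    sigma = np.asarray(sol.sigma_star, dtype=float).ravel()
    if np.any(sigma <= 0):
        raise PerplexityRangeError("all optimized bandwidths must be > 0")
    if D2 is None:
        D2 = pairwise_sq_distances(V)
    entropy, cond = conditional_rows_at_bandwidths(D2, sigma)
    joint = conditionals_to_joint(cond)
    return AffinityModel(
        sigma=sigma,
        cond_rows=cond,
        joint=joint,
        entropy=entropy,
        perplexity_target=np.asarray(sol.pi_star, dtype=float),
    )


def scan_report(curve: EntropyCurve):
    """Tabulate the staircase: sigma grid, H quantiles, aggregate sensitivity."""
    import pandas as pd

    q25, q50, q75 = np.percentile(curve.H, [25, 50, 75], axis=0)
    agg = np.median(np.abs(curve.sensitivity), axis=0)
    return pd.DataFrame(
        {
            "sigma": curve.sigma_grid,
            "H_q25": q25,
            "H_median": q50,
            "H_q75": q75,
            "perplexity_median": np.exp(q50),
            "aggregate_sensitivity": agg,
        }
    )


def plot_staircase(curve: EntropyCurve, solution: Optional[PerplexitySolution] = None, path=None):
    """Perplexity-versus-bandwidth staircase plot (PNG/SVG by file suffix)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    med = np.exp(np.median(curve.H, axis=0))
    step = max(1, curve.H.shape[0] // 500)
    for i in range(0, curve.H.shape[0], step):
        ax.plot(curve.sigma_grid, np.exp(curve.H[i]), color="C0", alpha=0.03, lw=0.5)
    ax.plot(curve.sigma_grid, med, color="C0", lw=2, label="median perplexity")
    if solution is not None:
        ax.plot(
            solution.sigma_star,
            solution.pi_star,
            ".",
            color="C2",
            ms=3,
            alpha=0.5,
            label="tuned per sample",
        )
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel(r"bandwidth $\sigma$")
    ax.set_ylabel(r"effective perplexity $\exp H$")
    ax.legend(loc="upper left")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
        return None
    return fig
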