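"""Embedding-fidelity metrics.

Two complementary views of how much neighbor-relationship information an
embedding preserves:

* the normalized information-loss statistic
  ``q = 1 - sum_i H(P_i*) / (sum_i H(P_i*) + sum_i KL(P_i* || Qhat_i))``,
  a free side product of the mapping. H(P_i*) is the bits (nats) needed to
  encode sample i's neighbor relations in the source space, and the
  cross-entropy H + KL the bits needed when encoding through the embedding
  model; q is the extra fraction — 0 when the embedding reproduces every
  conditional distribution, approaching 1 as all information is lost. Because
  the statistic is a ratio it is independent of the logarithm base. Note the
  two namings: ``q_lost`` = q (fraction lost), ``retained_fraction`` = 1 - q.

* the Jaccard n-nearest-neighbor retention: the mean over samples of the
  Jaccard index between each sample's n nearest neighbors before and after
  projection. Small n probes local structure, large n global structure. It
  is the expensive, model-free cross-check of q.

``Qhat_i`` is the row-normalized (conditional) Student-t kernel around sample
i in the embedding, so that it is a proper distribution comparable with the
conditional P_i* per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .data import as_values
from .exceptions import (
    DegenerateDataError,
    DimensionMismatchError,
    PerplexityRangeError,
)
from .objective import _embedding_array, output_affinities

__all__ = [
    "QualityReport",
    "per_sample_kl",
    "quality_q",
    "jaccard_retention",
    "evaluate_quality",
    "retention_vs_information_curve",
]

_P_FLOOR = 1e-300


@dataclass
class QualityReport:
    """Per-sample entropies/divergences and the scalar quality statistic."""

    H_star: np.ndarray
    kl_star: np.ndarray
    q_lost: float
    jaccard: Optional[List[Tuple[int, float]]] = field(default=None)

    @property
    def retained_fraction(self) -> float:
        """Fraction of neighbor information retained, 1 - q."""
        return 1.0 - self.q_lost

    def to_dict(self, per_sample: bool = False) -> dict:
        d = {
            "q_lost": self.q_lost,
            "retained_fraction": self.retained_fraction,
            "sum_H_star": float(np.sum(self.H_star)),
            "sum_kl_star": float(np.sum(self.kl_star)),
        }
        if self.jaccard is not None:
            d["jaccard"] = [[int(n), float(v)] for n, v in self.jaccard]
        if per_sample:
            d["per_sample"] = {
                "H_star": self.H_star.tolist(),
                "kl_star": self.kl_star.tolist(),
            }
        return d


def per_sample_kl(P_cond_star, Y) -> np.ndarray:
    """KL(P_i* || Qhat_i) for every sample, in nats.

    ``P_cond_star`` holds the conditional rows at the optimized bandwidths;
    ``Qhat_i`` is the row-normalized Student-t kernel around sample i in the
    embedding (zero self-weight).
    """
    P = np.asarray(P_cond_star, dtype=float)
    Y = _embedding_array(Y)
    if P.ndim != 2 or P.shape[0] != P.shape[1] or P.shape[0] != Y.shape[0]:
        raise DimensionMismatchError(
            f"conditional rows {P.shape} do not match embedding with "
            f"{Y.shape[0]} samples"
        )
    _, W = output_affinities(Y)
    Qhat = W / W.sum(axis=1, keepdims=True)
    ratio = np.where(P > 0, P / np.maximum(Qhat, _P_FLOOR), 1.0)
    kl = np.sum(np.where(P > 0, P * np.log(ratio), 0.0), axis=1)
    return np.maximum(kl, 0.0)


def quality_q(H_star, kl_star) -> float:
    """The information-loss statistic q = 1 - sum H / (sum H + sum KL)."""
    H = np.asarray(H_star, dtype=float).ravel()
    K = np.asarray(kl_star, dtype=float).ravel()
    if H.shape != K.shape:
        raise DimensionMismatchError("H_star and kl_star must have equal length")
    if np.any(H < 0) or np.any(K < 0):
        raise PerplexityRangeError("entropies and divergences must be non-negative")
    sh = float(np.sum(H))
    sk = float(np.sum(K))
    if sh == 0.0 and sk == 0.0:
        raise DegenerateDataError(
            "quality statistic undefined: all entropies and divergences are zero"
        )
    return 1.0 - sh / (sh + sk)


def _neighbor_indicator(D2: np.ndarray, n: int) -> np.ndarray:
    """Boolean m-by-m indicator of each row's n nearest neighbors.

    Ties are broken by sample index (stable sort), so the result is fully
    deterministic.
    """
    D = D2.copy()
    np.fill_diagonal(D, np.inf)
    order = np.argsort(D, axis=1, kind="stable")[:, :n]
    ind = np.zeros(D.shape, dtype=bool)
    np.put_along_axis(ind, order, True, axis=1)
    return ind


def jaccard_retention(X, Y, n: int) -> float:
    """Mean Jaccard index of the n-nearest-neighbor sets of X and of Y."""
    from .affinities import pairwise_sq_distances

    VX = as_values(X)
    VY = _embedding_array(Y)
    m = VX.shape[0]
    if VY.shape[0] != m:
        raise DimensionMismatchError("X and Y must have the same number of samples")
    if not (1 <= n <= m - 1):
        raise PerplexityRangeError(f"n must lie in [1, {m - 1}], got {n}")
    A = _neighbor_indicator(pairwise_sq_distances(VX), n)
    B = _neighbor_indicator(pairwise_sq_distances(VY), n)
    inter = np.sum(A & B, axis=1)
    union = 2 * n - inter
    return float(np.mean(inter / union))


def evaluate_quality(
    H_star,
    cond_rows,
    Y,
    X=None,
    jaccard_n: Optional[Sequence[int]] = None,
) -> QualityReport:
    """Assemble a :class:`QualityReport` for an embedding.

    ``H_star`` and ``cond_rows`` come from the calibrated affinity model
    (fixed or per-sample-tuned); the Jaccard curve is computed only when both
    ``X`` and ``jaccard_n`` are given.
    """
    kl = per_sample_kl(cond_rows, Y)
    q = quality_q(H_star, kl)
    jac = None
    if jaccard_n is not None:
        if X is None:
            raise DimensionMismatchError("X is required to compute Jaccard retention")
        jac = [(int(n), jaccard_retention(X, Y, int(n))) for n in jaccard_n]
    return QualityReport(
        H_star=np.asarray(H_star, dtype=float).ravel(),
        kl_star=kl,
        q_lost=q,
        jaccard=jac,
    )


def retention_vs_information_curve(
    k_list: Sequence[int],
    perplexity_list: Sequence[float],
    n_list: Sequence[int],
    m: int = 1000,
    ambient_dim: int = 10,
    seed: int = 0,
    n_components: int = 2,
    max_iter: int = 1000,
    rank: int = 11,
):
    """Sweep inherent dimension and perplexity on embedded Gaussian data.

    For each (k, perplexity) the full pipeline runs — generate data of
    inherent dimension k, calibrate bandwidths, embed with the quasi-Newton
    optimizer — and both fidelity metrics are recorded for each neighborhood
    size n. Returns a tidy DataFrame with one row per (k, perplexity, n).
    """
    import pandas as pd

    from .affinities import build_affinities, pairwise_sq_distances
    from .objective import make_tsne_problem
    from .optimizers import LbfgsConfig, lbfgs_minimize
    from .synthetic import EmbeddedGaussianSpec, embedded_lowdim_gaussian

    rows = []
    for k in k_list:
        data = embedded_lowdim_gaussian(
            EmbeddedGaussianSpec(ambient_dim=ambient_dim, inherent_dim=int(k), m=m, seed=seed)
        )
        V = data.values
        D2 = pairwise_sq_distances(V)
        for pi in perplexity_list:
            model = build_affinities(V, float(pi), D2=D2)
            rng = np.random.default_rng(seed)
            Y0 = rng.normal(scale=1e-4, size=(m, n_components))
            fun = make_tsne_problem(model.joint, n_components)
            x, _ = lbfgs_minimize(
                fun, Y0.ravel(), LbfgsConfig(rank=rank, max_iter=max_iter)
            )
            Y = x.reshape(m, n_components)
            kl = per_sample_kl(model.cond_rows, Y)
            q = quality_q(model.entropy, kl)
            for n in n_list:
                rows.append(
                    {
                        "k": int(k),
                        "perplexity": float(pi),
                        "n": int(n),
                        "jaccard": jaccard_retention(V, Y, int(n)),
                        "q_lost": q,
                        "retained_fraction": 1.0 - q,
                    }
                )
    return pd.DataFrame(rows)
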