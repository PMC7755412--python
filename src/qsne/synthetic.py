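"""Seeded synthetic benchmarks.

Two generators, both pure functions of their spec (seed included):

* :func:`hierarchical_gaussian` — 10-D data with three nested scales: cluster
  centers (SD 1), subcluster centers around them (SD 0.25) and per-sample
  noise (SD 0.01), balanced membership (default 1000 samples = 5 clusters x
  5 subclusters x 40 samples). The three well-separated scales produce a
  clean entropy staircase, making this the reference input for the automatic
  perplexity selector.

* :func:`embedded_lowdim_gaussian` — m standard-normal samples of inherent
  dimension k, rotated into a 10-D ambient space through a random orthonormal
  frame, so the data have exactly k nonzero singular values. Sweeping k
  probes how much information a 2-D embedding can retain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .data import DataMatrix
from .exceptions import PerplexityRangeError

__all__ = [
    "HierarchicalSpec",
    "EmbeddedGaussianSpec",
    "hierarchical_gaussian",
    "embedded_lowdim_gaussian",
]


@dataclass
class HierarchicalSpec:
    """Parameters of the nested-Gaussian benchmark."""

    dim: int = 10
    n_clusters: int = 5
    n_sub: int = 5
    m: int = 1000
    sd_cluster: float = 1.0
    sd_sub: float = 0.25
    sd_sample: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        groups = self.n_clusters * self.n_sub
        if self.m % groups != 0:
            raise PerplexityRangeError(
                f"m={self.m} is not divisible by n_clusters*n_sub={groups}; "
                f"choose m as a multiple of {groups} for balanced groups"
            )
        for name in ("sd_cluster", "sd_sub", "sd_sample"):
            if getattr(self, name) < 0:
                raise PerplexityRangeError(f"{name} must be non-negative")


@dataclass
class EmbeddedGaussianSpec:
    """Parameters of the inherent-dimension benchmark."""

    ambient_dim: int = 10
    inherent_dim: int = 2
    m: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.inherent_dim <= self.ambient_dim):
            raise PerplexityRangeError(
                f"inherent_dim must lie in [1, ambient_dim={self.ambient_dim}], "
                f"got {self.inherent_dim}"
            )


def hierarchical_gaussian(
    spec: Optional[HierarchicalSpec] = None,
    return_centers: bool = False,
    **overrides,
) -> Tuple[DataMatrix, pd.DataFrame]:
    """Generate the nested-Gaussian benchmark.

    Returns ``(data, labels)`` where ``labels`` has integer columns
    ``cluster`` (0..n_clusters-1) and ``subcluster`` (0..n_sub-1, within the
    cluster). With ``return_centers=True`` a third element is appended: a
    dict with the drawn ``cluster_centers`` (n_clusters, dim) and
    ``subcluster_centers`` (n_clusters, n_sub, dim).
    """
    if spec is None:
        spec = HierarchicalSpec(**overrides)
    elif overrides:
        raise TypeError("pass either a spec or keyword overrides, not both")
    rng = np.random.default_rng(spec.seed)
    centers = rng.normal(0.0, spec.sd_cluster, size=(spec.n_clusters, spec.dim))
    subcenters = centers[:, None, :] + rng.normal(
        0.0, spec.sd_sub, size=(spec.n_clusters, spec.n_sub, spec.dim)
    )
    n_per = spec.m // (spec.n_clusters * spec.n_sub)
    flat_centers = subcenters.reshape(-1, spec.dim)
    X = np.repeat(flat_centers, n_per, axis=0) + rng.normal(
        0.0, spec.sd_sample, size=(spec.m, spec.dim)
    )
    cluster = np.repeat(np.arange(spec.n_clusters), spec.n_sub * n_per)
    sub = np.tile(np.repeat(np.arange(spec.n_sub), n_per), spec.n_clusters)
    labels = pd.DataFrame({"cluster": cluster, "subcluster": sub})
    data = DataMatrix(X, row_ids=[f"s{i}" for i in range(spec.m)])
    if return_centers:
        return data, labels, {
            "cluster_centers": centers,
            "subcluster_centers": subcenters,
        }
    return data, labels


def embedded_lowdim_gaussian(
    spec: Optional[EmbeddedGaussianSpec] = None, **overrides
) -> DataMatrix:
    """Standard-normal data of inherent dimension k embedded in ambient_dim-D.

    Scores are drawn i.i.d. N(0, 1) in k dimensions and mapped through a
    seeded random orthonormal k-frame, so the centered data matrix has
    exactly k nonzero singular values.
    """
    if spec is None:
        spec = EmbeddedGaussianSpec(**overrides)
    elif overrides:
        raise TypeError("pass either a spec or keyword overrides, not both")
    rng = np.random.default_rng(spec.seed)
    scores = rng.standard_normal((spec.m, spec.inherent_dim))
    frame = rng.standard_normal((spec.ambient_dim, spec.inherent_dim))
    Q, _ = np.linalg.qr(frame)
    X = scores @ Q.T
    return DataMatrix(X, row_ids=[f"s{i}" for i in range(spec.m)])
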