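"""In-memory sample-by-feature container shared by all modules."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .exceptions import InsufficientDataError, NotFiniteError

__all__ = ["DataMatrix", "as_values"]


@dataclass
class DataMatrix:
    """A numeric matrix of m samples (rows) by d features (columns).

    Parameters
    ----------
    values
        Real matrix, samples in rows. Coerced to float64.
    row_ids
        Optional sample labels, one per row.
    col_ids
        Optional feature names, one per column.
    """

    values: np.ndarray
    row_ids: Optional[Sequence[str]] = None
    col_ids: Optional[Sequence[str]] = field(default=None)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise InsufficientDataError(
                f"expected a 2-D sample-by-feature matrix, got ndim={v.ndim}"
            )
        m, d = v.shape
        if m < 2:
            raise InsufficientDataError(f"need at least 2 samples, got m={m}")
        if d < 1:
            raise InsufficientDataError(f"need at least 1 feature, got d={d}")
        if not np.all(np.isfinite(v)):
            raise NotFiniteError("data matrix contains non-finite entries")
        if self.row_ids is not None and len(self.row_ids) != m:
            raise InsufficientDataError(
                f"{len(self.row_ids)} row labels for {m} rows"
            )
        if self.col_ids is not None and len(self.col_ids) != d:
            raise InsufficientDataError(
                f"{len(self.col_ids)} column labels for {d} columns"
            )
        self.values = v

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def __array__(self, dtype=None, copy=None):
        if dtype is None:
            return self.values
        return self.values.astype(dtype)


def as_values(X) -> np.ndarray:
    """Return the float64 ndarray behind ``X`` (DataMatrix or array-like)."""
    if isinstance(X, DataMatrix):
        return X.values
    v = np.asarray(X, dtype=float)
    if v.ndim != 2:
        raise InsufficientDataError("expected a 2-D sample-by-feature matrix")
    if not np.all(np.isfinite(v)):
        raise NotFiniteError("data matrix contains non-finite entries")
    return v
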