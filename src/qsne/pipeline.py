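"""End-to-end runs: configuration, artifact writing, reproducibility.

:func:`run_qsne` is the programmatic equivalent of ``qsne embed``: it reads a
matrix, fits a :class:`~qsne.estimator.QSNE` model, and writes the embedding,
a JSON report and (optionally) the optimizer trace. Outputs are deterministic
functions of (input, config, seed): rerunning produces byte-identical files.
On any failure, partially written outputs are removed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np

from . import __version__
from .data import DataMatrix
from .estimator import QSNE
from .exceptions import PerplexityRangeError, QsneError
from .io import read_matrix, write_embedding

__all__ = ["RunConfig", "run_qsne"]

logger = logging.getLogger("qsne")


@dataclass
class RunConfig:
    """Everything needed to reproduce one embedding run."""

    input_path: str
    embedding_path: str
    report_path: Optional[str] = None
    trace_path: Optional[str] = None
    mode: str = "fixed"  # "fixed" | "auto"
    perplexity: Optional[float] = 30.0
    perplexity_range: Optional[Tuple[float, float]] = None
    tune_window: Tuple[float, float] = (0.5, 2.0)
    optimizer: str = "lbfgs"
    rank: int = 11
    max_iter: int = 1000
    n_components: int = 2
    init: str = "random"
    seed: int = 0
    sep: Optional[str] = None
    learning_rate: float = 200.0
    momentum: float = 0.8
    verbose: int = 0
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.mode == "fixed":
            if self.perplexity is None or self.perplexity_range is not None:
                raise PerplexityRangeError(
                    "fixed mode requires a perplexity and no range"
                )
        elif self.mode == "auto":
            if self.perplexity_range is None:
                raise PerplexityRangeError("auto mode requires a perplexity range")
        else:
            raise PerplexityRangeError(f"unknown mode {self.mode!r}")

    def echo(self) -> dict:
        d = {
            "input": str(self.input_path),
            "mode": self.mode,
            "perplexity": self.perplexity if self.mode == "fixed" else None,
            "perplexity_range": list(self.perplexity_range)
            if self.perplexity_range
            else None,
            "tune_window": list(self.tune_window),
            "optimizer": self.optimizer,
            "rank": self.rank,
            "max_iter": self.max_iter,
            "n_components": self.n_components,
            "init": self.init,
            "seed": self.seed,
        }
        return d


def _quantiles(v: np.ndarray) -> dict:
    q = np.percentile(v, [0, 25, 50, 75, 100])
    return {
        "min": float(q[0]),
        "q25": float(q[1]),
        "median": float(q[2]),
        "q75": float(q[3]),
        "max": float(q[4]),
    }


def run_qsne(config: RunConfig, data: Optional[DataMatrix] = None) -> dict:
    """Execute one embedding run; returns the report dict, artifacts on disk.

    Any stage failure is re-raised with the stage name prepended and all
    outputs created so far are deleted.
    """
    config.validate()
    created: list = []
    stage = "read"
    try:
        t0 = time.perf_counter()
        if data is None:
            data = read_matrix(config.input_path, sep=config.sep)
        logger.info("read: %d x %d matrix (%.2fs)", data.n_samples, data.n_features,
                    time.perf_counter() - t0)

        stage = "embed"
        t0 = time.perf_counter()
        model = QSNE(
            n_components=config.n_components,
            perplexity=config.perplexity if config.mode == "fixed" else 30.0,
            perplexity_range=config.perplexity_range if config.mode == "auto" else None,
            tune_window=config.tune_window,
            optimizer=config.optimizer,
            rank=config.rank,
            max_iter=config.max_iter,
            init=config.init,
            learning_rate=config.learning_rate,
            momentum=config.momentum,
            random_state=config.seed,
            verbose=config.verbose,
        )
        Y = model.fit_transform(data.values)
        logger.info(
            "embed: %d iterations, C=%.6f (%.2fs)",
            int(model.trace_.iterations[-1]),
            model.kl_divergence_,
            time.perf_counter() - t0,
        )

        stage = "write-embedding"
        write_embedding(config.embedding_path, Y, row_ids=data.row_ids)
        created.append(config.embedding_path)

        stage = "report"
        report = {
            "version": __version__,
            "seed": config.seed,
            "config": config.echo(),
            "m": data.n_samples,
            "d": data.n_features,
            "kl_divergence": model.kl_divergence_,
            "iterations": int(model.trace_.iterations[-1]),
            "converged_by": model.trace_.converged_by,
            "pivot_perplexity": model.pivot_perplexity_,
            "effective_perplexity": _quantiles(model.effective_perplexity_),
            "sigma": _quantiles(model.sigma_),
        }
        report.update(model.quality_.to_dict())
        if config.report_path:
            with open(config.report_path, "w", encoding="utf-8") as fh:
                json.dump(report, fh, indent=2, sort_keys=True)
                fh.write("\n")
            created.append(config.report_path)

        if config.trace_path:
            stage = "trace"
            model.trace_.to_tsv(config.trace_path)
            created.append(config.trace_path)
        return report
    except Exception as exc:
        for p in created:
            try:
                Path(p).unlink()
            except OSError:
                pass
        if isinstance(exc, QsneError):
            raise type(exc)(f"[stage: {stage}] {exc}") from exc
        raise
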