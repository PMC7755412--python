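"""Delimited-text matrix input and output.

Input matrices are TSV or CSV (UTF-8, '.' decimal). A single header row and a
row-label column are auto-detected — the first row is a header if any of its
cells is non-numeric, the first column holds labels if any body cell in it is
non-numeric — and both detections can be overridden. Parse failures name the
offending line and column (1-based, file coordinates).
"""

from __future__ import annotations

import csv
import io as _io
import os
from typing import List, Optional, Union

import numpy as np

from .data import DataMatrix
from .exceptions import MatrixParseError

__all__ = ["read_matrix", "write_matrix", "write_embedding"]

_AUTO = "auto"


def _is_number(tok: str) -> bool:
    try:
        v = float(tok)
    except ValueError:
        return False
    return np.isfinite(v)


def _sniff_sep(path: str, first_line: str) -> str:
    ext = os.path.splitext(str(path))[1].lower()
    if ext == ".csv":
        return ","
    if ext in (".tsv", ".tab", ".txt"):
        return "\t"
    if "\t" in first_line:
        return "\t"
    if "," in first_line:
        return ","
    return "\t"


def read_matrix(
    path,
    sep: Optional[str] = None,
    header: Union[str, bool] = _AUTO,
    row_labels: Union[str, bool] = _AUTO,
) -> DataMatrix:
    """Read a samples-in-rows numeric matrix from delimited text.

    Parameters
    ----------
    path : file path.
    sep : field delimiter; inferred from the extension/content when None.
    header : True, False, or "auto" (first row non-numeric => header).
    row_labels : True, False, or "auto" (first column non-numeric => labels).
    """
    with open(path, "r", encoding="utf-8", newline="") as fh:
        text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip() != ""]
    if not lines:
        raise MatrixParseError(f"{path}: file is empty")
    if sep is None:
        sep = _sniff_sep(path, lines[0])
    rows: List[List[str]] = list(csv.reader(_io.StringIO("\n".join(lines)), delimiter=sep))

    width = len(rows[0])
    for k, r in enumerate(rows, start=1):
        if len(r) != width:
            raise MatrixParseError(
                f"{path}: ragged row at line {k}: {len(r)} fields, expected {width}"
            )

    if header == _AUTO:
        has_header = any(not _is_number(tok) for tok in rows[0][1:]) or (
            width == 1 and not _is_number(rows[0][0])
        )
    else:
        has_header = bool(header)
    body_start = 1 if has_header else 0
    body = rows[body_start:]
    if len(body) < 2:
        raise MatrixParseError(f"{path}: need at least 2 data rows, got {len(body)}")

    if row_labels == _AUTO:
        has_labels = any(not _is_number(r[0]) for r in body)
    else:
        has_labels = bool(row_labels)
    col_start = 1 if has_labels else 0
    if width - col_start < 1:
        raise MatrixParseError(f"{path}: no numeric columns found")

    ids = [r[0] for r in body] if has_labels else None
    col_ids = rows[0][col_start:] if has_header else None

    values = np.empty((len(body), width - col_start))
    for i, r in enumerate(body):
        for j, tok in enumerate(r[col_start:]):
            try:
                v = float(tok)
            except ValueError:
                raise MatrixParseError(
                    f"{path}: non-numeric cell {tok!r} at line "
                    f"{body_start + i + 1}, column {col_start + j + 1}"
                ) from None
            if not np.isfinite(v):
                raise MatrixParseError(
                    f"{path}: non-finite cell {tok!r} at line "
                    f"{body_start + i + 1}, column {col_start + j + 1}"
                )
            values[i, j] = v
    return DataMatrix(values, row_ids=ids, col_ids=col_ids)


def write_matrix(path, data: DataMatrix, sep: str = "\t") -> None:
    """Write a DataMatrix with optional header row and row-label column."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter=sep, lineterminator="\n")
        ncol = data.values.shape[1]
        cols = list(data.col_ids) if data.col_ids is not None else [
            f"f{j}" for j in range(ncol)
        ]
        if data.row_ids is not None:
            w.writerow(["id"] + cols)
            for rid, row in zip(data.row_ids, data.values):
                w.writerow([rid] + [f"{v:.10g}" for v in row])
        else:
            w.writerow(cols)
            for row in data.values:
                w.writerow([f"{v:.10g}" for v in row])


def write_embedding(path, Y: np.ndarray, row_ids=None, sep: str = "\t") -> None:
    """Write an m-by-e embedding as TSV, preserving row labels when given."""
    Y = np.asarray(Y, dtype=float)
    cols = [f"dim{j + 1}" for j in range(Y.shape[1])]
    write_matrix(path, DataMatrix(Y, row_ids=row_ids, col_ids=cols), sep=sep)
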