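"""Reading and writing point-set tables, mean imputation, min–max normalization.

The on-disk format is the de-facto standard of the 2-D shape benchmarks:
one point per line, whitespace- or comma-delimited feature columns, with an
optional integer ground-truth label column. Missing values are marked by a
configurable token (``"?"`` by default) and carried in memory as NaN until
imputation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "PointSet",
    "PreprocessReport",
    "read_points",
    "impute_mean",
    "minmax_normalize",
    "write_labels",
    "read_labels",
    "write_report",
]


@dataclass
class PointSet:
    """An n×d numeric sample matrix with optional ground-truth labels.

    Missing cells are represented as NaN; downstream density computations
    require a fully observed matrix (run :func:`impute_mean` first).
    """

    X: np.ndarray
    y_true: np.ndarray | None = None
    feature_names: list[str] | None = None
    source: str = ""

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        n, d = self.X.shape
        if n < 1 or d < 1:
            raise ValueError("PointSet requires n >= 1 and d >= 1")
        if self.y_true is not None:
            self.y_true = np.asarray(self.y_true, dtype=int)
            if self.y_true.shape != (n,):
                raise ValueError("y_true must have length n")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.X).any())


@dataclass
class PreprocessReport:
    """Bookkeeping from imputation / normalization.

    ``imputed_count[j]`` is the number of cells filled in feature j;
    ``min_j``/``max_j`` are the per-feature extremes used by the min–max map;
    ``constant_features`` lists features with max == min (mapped to 0).
    """

    imputed_count: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    min_j: np.ndarray = field(default_factory=lambda: np.zeros(0))
    max_j: np.ndarray = field(default_factory=lambda: np.zeros(0))
    constant_features: list[int] = field(default_factory=list)


def _resolve_label_column(label_column: int | str | None, ncols: int) -> int | None:
    if label_column is None or label_column == "none":
        return None
    if label_column == "first":
        return 0
    if label_column == "last":
        return ncols - 1
    idx = int(label_column)
    if not -ncols <= idx < ncols:
        raise ValueError(f"label column {idx} out of range for {ncols} columns")
    return idx % ncols


def read_points(
    path: str | Path,
    delimiter: str | None = None,
    label_column: int | str | None = "none",
    missing_token: str = "?",
) -> PointSet:
    """Parse a delimited text table into a :class:`PointSet`.

    Parameters
    ----------
    delimiter:
        Column separator; ``None`` splits on any whitespace.
    label_column:
        ``"none"``/``None``, ``"first"``, ``"last"`` or an integer column
        index naming the ground-truth label column.
    missing_token:
        Cell content treated as a missing value (stored as NaN).
    """
    path = Path(path)
    rows: list[list[str]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            cells = line.split(delimiter) if delimiter else line.split()
            if rows and len(cells) != len(rows[0]):
                raise ValueError(
                    f"{path}:{lineno}: ragged row ({len(cells)} columns, expected {len(rows[0])})"
                )
            rows.append(cells)
    if not rows:
        raise ValueError(f"{path}: empty file")
    ncols = len(rows[0])
    lab = _resolve_label_column(label_column, ncols)
    if lab is not None and ncols < 2:
        raise ValueError("cannot split a label column from a single-column file")

    y: list[int] | None = [] if lab is not None else None
    data = np.empty((len(rows), ncols - (lab is not None)), dtype=float)
    for r, cells in enumerate(rows):
        c_out = 0
        for c, cell in enumerate(cells):
            if lab is not None and c == lab:
                try:
                    y.append(int(float(cell)))  # type: ignore[union-attr]
                except ValueError as exc:
                    raise ValueError(f"{path}: non-integer label {cell!r} in row {r + 1}") from exc
                continue
            if cell == missing_token:
                data[r, c_out] = math.nan
            else:
                try:
                    data[r, c_out] = float(cell)
                except ValueError as exc:
                    raise ValueError(f"{path}: non-numeric cell {cell!r} in row {r + 1}") from exc
            c_out += 1
    return PointSet(
        X=data,
        y_true=np.asarray(y, dtype=int) if y is not None else None,
        source=str(path),
    )


def impute_mean(P: PointSet) -> tuple[PointSet, PreprocessReport]:
    """Replace every missing cell by the mean of its feature's observed values.

    A feature with no observed value at all is an error: there is nothing to
    average.
    """
    X = P.X.copy()
    missing = np.isnan(X)
    if missing.all(axis=0).any():
        bad = np.flatnonzero(missing.all(axis=0)).tolist()
        raise ValueError(f"features entirely missing, cannot impute: {bad}")
    counts = missing.sum(axis=0).astype(int)
    if counts.any():
        col_means = np.nanmean(P.X, axis=0)
        X[missing] = np.broadcast_to(col_means, X.shape)[missing]
    report = PreprocessReport(
        imputed_count=counts,
        min_j=np.nanmin(P.X, axis=0),
        max_j=np.nanmax(P.X, axis=0),
    )
    return replace(P, X=X), report


def minmax_normalize(P: PointSet) -> tuple[PointSet, PreprocessReport]:
    """Map each feature affinely onto [0, 1].

    x'_ij = (x_ij − min_j) / (max_j − min_j).  A constant feature (max_j ==
    min_j) would divide by zero; it carries no information, so it is mapped
    to 0 everywhere and recorded in ``constant_features``.
    """
    if P.has_missing:
        raise ValueError("normalize requires a fully observed matrix; impute first")
    mins = P.X.min(axis=0)
    maxs = P.X.max(axis=0)
    span = maxs - mins
    constant = np.flatnonzero(span == 0)
    safe_span = np.where(span == 0, 1.0, span)
    X = (P.X - mins) / safe_span
    X[:, constant] = 0.0
    report = PreprocessReport(
        imputed_count=np.zeros(P.d, dtype=int),
        min_j=mins,
        max_j=maxs,
        constant_features=constant.tolist(),
    )
    return replace(P, X=X), report


def write_labels(labels: Sequence[int] | np.ndarray, path: str | Path) -> None:
    """Write one integer label per line."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("refusing to write an empty label list")
    Path(path).write_text("\n".join(str(int(v)) for v in labels) + "\n")


def read_labels(path: str | Path) -> np.ndarray:
    """Read a labels file written by :func:`write_labels`."""
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty labels file")
    return np.asarray([int(ln) for ln in lines], dtype=int)


def write_report(meta: dict, path: str | Path) -> None:
    """Serialize run metadata (and an optional metric table) as key/value text.

    Nested dicts become an indented ``key: value`` block, which covers the
    metric table (ami/ari/fmi) without a bespoke format.
    """
    lines: list[str] = []
    for key, value in meta.items():
        if isinstance(value, dict):
            lines.append(f"{key}:")
            for k2, v2 in value.items():
                lines.append(f"  {k2}: {v2}")
        else:
            lines.append(f"{key}: {value}")
    Path(path).write_text("\n".join(lines) + "\n")
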