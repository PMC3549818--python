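"""Raw matrix preprocessing: interpolation, zero filtering, standardization.

The pipeline order is fixed: ``interpolate_missing`` -> ``filter_zero_rows``
-> ``standardize``.  Zero counting happens on raw (interpolated) values,
since the zero-abundance filter is a statement about raw counts, not about
centred values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import StandardSeries

__all__ = [
    "TimeSeriesMatrix",
    "interpolate_missing",
    "filter_zero_rows",
    "standardize",
    "read_matrix",
    "write_matrix",
]

#: markers treated as missing when reading delimited text
MISSING_MARKERS = ("", "NA", "NaN")


@dataclass(frozen=True)
class TimeSeriesMatrix:
    """An m x n labeled real matrix with an explicit missing-value mask.

    Rows are series (taxa, genes, phrases, ...), columns are time points.
    Missing entries are flagged in ``missing_mask`` and hold NaN in
    ``values`` — never a silent zero.
    """

    values: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        mask = self.missing_mask
        mask = np.isnan(values) if mask is None else np.asarray(mask, dtype=bool)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "missing_mask", mask)
        object.__setattr__(self, "row_labels", tuple(map(str, self.row_labels)))
        object.__setattr__(self, "col_labels", tuple(map(str, self.col_labels)))
        m, n = values.shape
        if m < 1 or n < 2:
            raise ValueError(f"matrix must be at least 1 x 2, got {m} x {n}")
        if len(self.row_labels) != m or len(self.col_labels) != n:
            raise ValueError("label counts do not match matrix shape")
        if len(set(self.row_labels)) != m or len(set(self.col_labels)) != n:
            raise ValueError("row and column labels must be unique")
        if mask.shape != values.shape:
            raise ValueError("missing_mask shape does not match values")
        if np.any(np.isnan(values) & ~mask):
            raise ValueError("NaN present in values but not flagged missing")
        if not np.all(np.isfinite(values[~mask])):
            raise ValueError("non-finite observed values present")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        vals = self.values.copy()
        vals[self.missing_mask] = np.nan
        return pd.DataFrame(vals, index=list(self.row_labels), columns=list(self.col_labels))


def interpolate_missing(matrix: TimeSeriesMatrix) -> TimeSeriesMatrix:
    """Fill missing entries from the nearest observed temporal neighbours.

    Interior gaps are filled by linear interpolation between the nearest
    observed value on each side (for a single-point gap this is exactly the
    average of the two nearest time points); a missing run touching either
    boundary is filled with the single nearest observed value.  Idempotent:
    a matrix with no missing entries is returned unchanged in value.

    Raises
    ------
    ValueError
        Naming the offending row, if it has fewer than 2 observed values.
    """
    observed = (~matrix.missing_mask).sum(axis=1)
    bad = np.flatnonzero(observed < 2)
    if bad.size:
        names = ", ".join(matrix.row_labels[i] for i in bad)
        raise ValueError(f"rows with < 2 observed values cannot be interpolated: {names}")
    frame = matrix.to_frame()
    filled = frame.interpolate(method="linear", axis=1, limit_direction="both")
    return TimeSeriesMatrix(
        values=filled.to_numpy(),
        row_labels=matrix.row_labels,
        col_labels=matrix.col_labels,
        missing_mask=np.zeros(matrix.shape, dtype=bool),
    )


def filter_zero_rows(
    matrix: TimeSeriesMatrix, max_zero_fraction: float = 0.25
) -> tuple[TimeSeriesMatrix, list[str]]:
    """Drop rows whose fraction of exact zeros exceeds ``max_zero_fraction``.

    The comparison is strict: a row at exactly the threshold is retained.
    Returns the filtered matrix and the removed labels, for logging.
    """
    if matrix.missing_mask.any():
        raise ValueError("filter_zero_rows requires an interpolated (complete) matrix")
    n = matrix.shape[1]
    zero_frac = (matrix.values == 0.0).sum(axis=1) / n
    keep = zero_frac <= max_zero_fraction
    removed = [lab for lab, k in zip(matrix.row_labels, keep) if not k]
    if not keep.any():
        raise ValueError("zero-fraction filter removed every row")
    kept = TimeSeriesMatrix(
        values=matrix.values[keep],
        row_labels=tuple(lab for lab, k in zip(matrix.row_labels, keep) if k),
        col_labels=matrix.col_labels,
        missing_mask=matrix.missing_mask[keep],
    )
    return kept, removed


def standardize(matrix: TimeSeriesMatrix) -> list[StandardSeries]:
    """Center each row and scale by its population (1/n) standard deviation.

    The population divisor makes a series' squared values sum to n, so a
    self-comparison yields LSA exactly 1 and Cauchy-Schwarz caps |LSA| at 1.

    Raises
    ------
    ValueError
        Naming the offending row, if any row is constant (zero variance).
    """
    if matrix.missing_mask.any():
        raise ValueError("standardize requires an interpolated (complete) matrix")
    means = matrix.values.mean(axis=1, keepdims=True)
    stds = matrix.values.std(axis=1, keepdims=True)  # ddof=0
    flat = np.flatnonzero(stds.ravel() == 0.0)
    if flat.size:
        names = ", ".join(matrix.row_labels[i] for i in flat)
        raise ValueError(f"constant rows have zero variance and cannot be standardized: {names}")
    z = (matrix.values - means) / stds
    # exact re-centering guards against catastrophic cancellation upstream
    z -= z.mean(axis=1, keepdims=True)
    return [StandardSeries(row, label) for row, label in zip(z, matrix.row_labels)]


def read_matrix(
    path: str | Path, delimiter: str = "\t", missing_markers: tuple[str, ...] = MISSING_MARKERS
) -> TimeSeriesMatrix:
    """Read a delimited matrix: first column = series label, header = time points."""
    frame = pd.read_csv(
        path,
        sep=delimiter,
        index_col=0,
        na_values=list(missing_markers),
        keep_default_na=False,
    )
    if frame.shape[0] < 1 or frame.shape[1] < 2:
        raise ValueError(f"{path}: need at least 1 series x 2 time points, got {frame.shape}")
    values = frame.to_numpy(dtype=float)
    return TimeSeriesMatrix(
        values=values,
        row_labels=tuple(map(str, frame.index)),
        col_labels=tuple(map(str, frame.columns)),
        missing_mask=np.isnan(values),
    )


def write_matrix(matrix: TimeSeriesMatrix, path: str | Path, delimiter: str = "\t") -> None:
    """Write the matrix in the same layout ``read_matrix`` expects."""
    matrix.to_frame().to_csv(path, sep=delimiter, na_rep="NA")
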