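"""Per-subject and group-mean absolute-Pearson connectivity matrices.

Functional connectivity between two regions is the Pearson correlation of
their BOLD time series; because the analysis studies the absolute variation
in coupling, the matrices store ``|r|``.  The diagonal is stored as 0 so
that downstream averaging, filtering and degree sums never count
self-connections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .regions import REGION_NAMES

__all__ = [
    "ConnectivityMatrix",
    "pearson_abs_matrix",
    "group_mean_matrix",
    "edge_vector",
    "edge_index_pairs",
]


@dataclass
class ConnectivityMatrix:
    """Symmetric ``|r|`` matrix over named regions, zero diagonal.

    ``tag`` carries the subject id (per-subject matrices) or the group
    label (group means); ``n`` is the number of subjects averaged (1 for a
    single subject).
    """

    values: np.ndarray
    region_names: tuple[str, ...] = field(default=REGION_NAMES)
    tag: str | None = None
    n: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        p = len(self.region_names)
        if self.values.shape != (p, p):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {p} region names"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        if np.any(np.diag(self.values) != 0.0):
            raise ValueError("diagonal must be zero by convention")
        if self.values.min() < 0.0 or self.values.max() > 1.0:
            raise ValueError("absolute correlations must lie in [0, 1]")

    @property
    def n_regions(self) -> int:
        return len(self.region_names)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.region_names, columns=self.region_names)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, float_format="%.17g")

    @classmethod
    def from_csv(cls, path, tag: str | None = None, n: int = 1) -> "ConnectivityMatrix":
        frame = pd.read_csv(path, index_col=0, float_precision="round_trip")
        values = frame.to_numpy(dtype=float)
        # mirror the upper triangle so stored rounding can never break symmetry
        values = np.triu(values, 1)
        values = values + values.T
        return cls(values=values, region_names=tuple(frame.columns), tag=tag, n=n)


def edge_index_pairs(p: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical upper-triangle (i < j) edge indexing: p*(p-1)/2 edges."""
    return np.triu_indices(p, k=1)


def edge_vector(matrix: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    """Flatten a symmetric matrix to its canonical upper-triangle edge vector."""
    values = matrix.values if isinstance(matrix, ConnectivityMatrix) else np.asarray(matrix)
    iu, ju = edge_index_pairs(values.shape[0])
    return values[iu, ju]


def pearson_abs_matrix(
    timeseries: np.ndarray,
    region_names: tuple[str, ...] | None = None,
    subject_id: str | None = None,
) -> ConnectivityMatrix:
    """Absolute Pearson correlation matrix of a [T x p] time-series table.

    Parameters
    ----------
    timeseries:
        Array with time points in rows and regions in columns; T >= 3 and
        every column must have nonzero variance.
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2:
        raise ValueError("timeseries must be a 2-D [T x regions] array")
    names = tuple(region_names) if region_names is not None else REGION_NAMES[: ts.shape[1]]
    if ts.shape[1] != len(names):
        raise ValueError("number of columns does not match region names")
    if ts.shape[0] < 3:
        raise ValueError(f"need at least 3 time points, got {ts.shape[0]}")
    sd = ts.std(axis=0)
    if np.any(sd == 0.0):
        bad = [names[k] for k in np.flatnonzero(sd == 0.0)]
        raise ValueError(f"constant time series for region(s): {', '.join(bad)}")
    corr = np.corrcoef(ts, rowvar=False)
    values = np.abs(corr)
    np.clip(values, 0.0, 1.0, out=values)
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 0.0)
    return ConnectivityMatrix(values=values, region_names=names, tag=subject_id, n=1)


def group_mean_matrix(
    matrices: list[ConnectivityMatrix], group: str | None = None
) -> ConnectivityMatrix:
    """Elementwise mean of per-subject matrices sharing one region ordering."""
    if len(matrices) == 0:
        raise ValueError("need at least one matrix to average")
    names = matrices[0].region_names
    for m in matrices[1:]:
        if m.region_names != names:
            raise ValueError(
                "region orderings differ between matrices; no silent reordering is done"
            )
    mean = np.mean([m.values for m in matrices], axis=0)
    np.fill_diagonal(mean, 0.0)
    return ConnectivityMatrix(values=mean, region_names=names, tag=group, n=len(matrices))
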