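"""Metabolic connectivity: across-subject interregional Pearson correlation.

The connectivity metric is the Pearson correlation of regional uptake
computed across the subjects of one group — one matrix per group, not per
subject.  With the standard non-cerebellar AAL parcellation the matrix is
90 x 90 with M = N(N-1)/2 = 4005 distinct edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .series import SubjectSeries

__all__ = ["ConnectivityMatrix", "pearson_connectivity", "fisher_z", "correlation_matrix"]


def correlation_matrix(values: np.ndarray) -> np.ndarray:
    """Pearson correlation between columns of a subjects x regions array.

    Hot path for the permutation loops: standardizes columns once and takes
    one matrix product.  Columns with zero variance yield NaN rows/columns.
    """
    x = np.asarray(values, dtype=float)
    n = x.shape[0]
    xc = x - x.mean(axis=0)
    norm = np.sqrt(np.einsum("ij,ij->j", xc, xc))
    with np.errstate(invalid="ignore", divide="ignore"):
        xs = xc / norm
    r = xs.T @ xs
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    if n < 2:
        r[:] = np.nan
    return r


@dataclass
class ConnectivityMatrix:
    """Symmetric region x region correlation matrix for one group."""

    values: np.ndarray
    region_ids: np.ndarray
    n_subjects: int
    group_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.region_ids = np.asarray(self.region_ids, dtype=int)
        n = self.values.shape[0]
        if self.values.shape != (n, n) or n != self.region_ids.size:
            raise ValueError("matrix shape does not match region list")
        if not np.allclose(self.values, self.values.T, atol=1e-12, equal_nan=True):
            raise ValueError("connectivity matrix must be symmetric")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_edges(self) -> int:
        n = self.n_regions
        return n * (n - 1) // 2

    def edge_values(self) -> np.ndarray:
        """Upper-triangle correlations in canonical (i, j), i < j order."""
        iu = np.triu_indices(self.n_regions, k=1)
        return self.values[iu]

    # ------------------------------------------------------------------ I/O
    def to_tsv(self, path: str | Path) -> None:
        frame = pd.DataFrame(self.values, index=self.region_ids, columns=self.region_ids)
        frame.to_csv(path, sep="\t", index_label="region")

    @classmethod
    def from_tsv(cls, path: str | Path, n_subjects: int = 0, group_label: str = "") -> "ConnectivityMatrix":
        frame = pd.read_csv(path, sep="\t", index_col="region")
        return cls(
            values=frame.to_numpy(),
            region_ids=frame.columns.astype(int).to_numpy(),
            n_subjects=n_subjects,
            group_label=group_label,
        )

    def to_edge_list(self) -> pd.DataFrame:
        i, j = np.triu_indices(self.n_regions, k=1)
        return pd.DataFrame(
            {
                "region_i": self.region_ids[i],
                "region_j": self.region_ids[j],
                "r": self.values[i, j],
            }
        )


def pearson_connectivity(series: SubjectSeries) -> ConnectivityMatrix:
    """Across-subject Pearson correlation between all region pairs.

    Raises
    ------
    ValueError
        With fewer than 3 subjects, or when a region column has zero
        variance (degenerate input: the region is constant across subjects).
    """
    if series.n_subjects < 3:
        raise ValueError("need at least 3 subjects for a correlation matrix")
    values = series.values
    variances = values.var(axis=0)
    if np.any(variances == 0):
        bad = series.region_ids[variances == 0]
        raise ValueError(f"zero-variance region column(s): {bad.tolist()}")
    return ConnectivityMatrix(
        values=correlation_matrix(values),
        region_ids=series.region_ids,
        n_subjects=series.n_subjects,
        group_label=series.group_label,
    )


def fisher_z(matrix: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    """Entrywise Fisher z-transform atanh(r); the diagonal is NaN.

    A variance-stabilized scale for comparing correlations; undefined at
    |r| = 1, which signals a degenerate (duplicated-column) correlation.
    """
    values = matrix.values if isinstance(matrix, ConnectivityMatrix) else np.asarray(matrix)
    off = ~np.eye(values.shape[0], dtype=bool)
    if np.any(np.abs(values[off]) >= 1.0):
        raise ValueError("degenerate correlation: |r| = 1 off the diagonal")
    z = np.full_like(values, np.nan, dtype=float)
    z[off] = np.arctanh(values[off])
    return z
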