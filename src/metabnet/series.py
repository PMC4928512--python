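"""Subject-series uptake tables: the unit of group resampling.

One :class:`SubjectSeries` holds a group's subjects x regions table of mean
normalized uptake.  Interregional correlation is computed across subjects
(down the rows), so the table is the exchangeable unit that permutation
tests shuffle.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SubjectSeries"]


@dataclass
class SubjectSeries:
    """A group's subjects x regions table of mean normalized uptake.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by subject identifier, columns by integer region code
        in the fixed atlas order.  Must be free of missing values.
    group_label : str
        Cohort name (e.g. ``"EAD"``, ``"young"``).
    """

    data: pd.DataFrame
    group_label: str = ""

    def __post_init__(self) -> None:
        if self.data.ndim != 2 or self.data.shape[1] == 0:
            raise ValueError("subject series needs at least one region column")
        if self.data.isna().any().any():
            raise ValueError("subject series contains missing values")
        self.data = self.data.astype(float)
        self.data.columns = [int(c) for c in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def region_ids(self) -> np.ndarray:
        return np.asarray(self.data.columns, dtype=int)

    @property
    def subject_ids(self) -> list:
        return self.data.index.tolist()

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]

    def same_regions(self, other: "SubjectSeries") -> bool:
        return bool(np.array_equal(self.region_ids, other.region_ids))

    def region_means(self) -> pd.Series:
        """Per-region mean uptake across subjects (node 'metabolic level')."""
        return self.data.mean(axis=0)

    # ------------------------------------------------------------------ I/O
    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.insert(0, "subject_id", self.data.index)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, group_label: str = "") -> "SubjectSeries":
        table = pd.read_csv(path, sep="\t")
        table = table.set_index("subject_id")
        return cls(data=table, group_label=group_label or Path(path).stem)

    @classmethod
    def from_array(
        cls,
        values: np.ndarray,
        region_ids=None,
        subject_ids=None,
        group_label: str = "",
    ) -> "SubjectSeries":
        values = np.asarray(values, dtype=float)
        n, r = values.shape
        if region_ids is None:
            region_ids = np.arange(1, r + 1)
        if subject_ids is None:
            subject_ids = [f"{group_label or 'subj'}_{i:03d}" for i in range(n)]
        frame = pd.DataFrame(values, index=subject_ids, columns=list(region_ids))
        return cls(data=frame, group_label=group_label)
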