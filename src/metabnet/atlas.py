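"""Region parcellations for ROI-based uptake extraction.

A :class:`RegionAtlas` couples an integer label volume (0 = background) with
an ordered label table.  The packaged table follows the AAL-116 parcellation;
removing the cerebellar labels (``Cerebelum_*`` and ``Vermis_*``) leaves the
90 cerebral regions on which connectivity matrices are built.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RegionAtlas",
    "load_label_table",
    "load_aal_table",
    "load_aal_centroids",
    "exclude_cerebellum",
]

_CEREBELLAR_PREFIXES = ("Cerebelum", "Vermis")


@dataclass
class RegionAtlas:
    """An ordered region label table, optionally with a label volume.

    Parameters
    ----------
    label_table : pandas.DataFrame
        Columns ``code`` (int, nonzero), ``name`` (str) and ``cerebellar``
        (0/1).  Row order fixes the region order of every downstream matrix.
    label_volume : numpy.ndarray or None
        3-D integer array of region codes; 0 marks background voxels.
    """

    label_table: pd.DataFrame
    label_volume: np.ndarray | None = None
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        required = {"code", "name", "cerebellar"}
        missing = required - set(self.label_table.columns)
        if missing:
            raise ValueError(f"label table missing columns: {sorted(missing)}")
        if self.label_table.empty:
            raise ValueError("empty parcellation")
        codes = self.label_table["code"].to_numpy()
        if (codes == 0).any():
            raise ValueError("region code 0 is reserved for background")
        if len(np.unique(codes)) != len(codes):
            raise ValueError("duplicate region codes in label table")
        if self.label_volume is not None:
            vol_codes = np.unique(self.label_volume)
            vol_codes = vol_codes[vol_codes != 0]
            unknown = np.setdiff1d(vol_codes, codes)
            if unknown.size:
                raise ValueError(
                    f"label volume contains codes absent from table: {unknown[:5]}"
                )

    @property
    def codes(self) -> np.ndarray:
        return self.label_table["code"].to_numpy()

    @property
    def names(self) -> list[str]:
        return self.label_table["name"].tolist()

    @property
    def n_regions(self) -> int:
        return len(self.label_table)

    def cerebellar_codes(self) -> np.ndarray:
        mask = self.label_table["cerebellar"].astype(bool)
        return self.label_table.loc[mask, "code"].to_numpy()

    def with_volume(self, label_volume: np.ndarray, affine: np.ndarray | None = None) -> "RegionAtlas":
        return RegionAtlas(
            label_table=self.label_table,
            label_volume=np.asarray(label_volume),
            affine=np.eye(4) if affine is None else affine,
        )


def load_label_table(path: str | Path) -> pd.DataFrame:
    """Read a region label table from TSV (columns code, name, cerebellar)."""
    table = pd.read_csv(path, sep="\t")
    table["code"] = table["code"].astype(int)
    table["cerebellar"] = table["cerebellar"].astype(int)
    return table


def _packaged(name: str):
    return resources.files("metabnet.data").joinpath(name)


def load_aal_table() -> pd.DataFrame:
    """The packaged AAL-116 label table, ordered by ascending code."""
    with resources.as_file(_packaged("aal116_labels.tsv")) as p:
        table = load_label_table(p)
    return table.sort_values("code", ignore_index=True)


def load_aal_centroids() -> pd.DataFrame:
    """Synthetic stand-in centroids for the 90 non-cerebellar AAL regions.

    The packaged coordinates are deterministic pseudo-MNI positions
    (hemisphere sign is respected, locations are randomized once); they serve
    viewer-file export only and carry no anatomical meaning.
    """
    with resources.as_file(_packaged("aal90_centroids_synthetic.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def flag_cerebellar_by_name(table: pd.DataFrame) -> pd.DataFrame:
    """Set the cerebellar flag from the standard AAL name prefixes."""
    out = table.copy()
    out["cerebellar"] = (
        out["name"].str.startswith(_CEREBELLAR_PREFIXES).astype(int)
    )
    return out


def exclude_cerebellum(atlas: RegionAtlas) -> RegionAtlas:
    """Restrict an atlas to its non-cerebellar regions, preserving order.

    On the packaged AAL-116 table this leaves exactly the 90 cerebral
    regions used for connectivity analysis.

    Raises
    ------
    ValueError
        If every region is flagged cerebellar ("empty parcellation").
    """
    keep = ~atlas.label_table["cerebellar"].astype(bool)
    if not keep.any():
        raise ValueError("empty parcellation: all regions are cerebellar")
    table = atlas.label_table.loc[keep].reset_index(drop=True)
    volume = atlas.label_volume
    if volume is not None:
        dropped = atlas.label_table.loc[~keep, "code"].to_numpy()
        volume = np.where(np.isin(volume, dropped), 0, volume)
    return RegionAtlas(label_table=table, label_volume=volume, affine=atlas.affine)
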