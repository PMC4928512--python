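"""PET volume preprocessing: smoothing, reference normalization, ROI means.

Implements the image-side front end: volumes are assumed already registered
to the atlas space (spatial normalization is out of scope).  The standard
order is Gaussian smoothing (16-mm FWHM by default), division by the mean
cerebellar intensity, then reduction to per-region mean uptake.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .atlas import RegionAtlas
from .series import SubjectSeries

__all__ = [
    "IntensityVolume",
    "fwhm_to_sigma",
    "smooth_volume",
    "normalize_by_cerebellum",
    "extract_roi_means",
    "build_subject_series",
]

logger = logging.getLogger(__name__)

#: FWHM = sigma * 2*sqrt(2 ln 2) for a Gaussian kernel.
_FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass
class IntensityVolume:
    """A 3-D PET intensity grid with voxel geometry."""

    voxels: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("intensity volume must be 3-D")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("intensity volume contains non-finite values")
        if any(s <= 0 for s in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.voxels.shape

    def to_nifti(self, path: str | Path) -> None:
        img = nib.Nifti1Image(self.voxels.astype(np.float32), self.affine)
        img.header.set_zooms(self.voxel_size_mm)
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "IntensityVolume":
        img = nib.load(str(path))
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(
            voxels=np.asarray(img.get_fdata(), dtype=float),
            voxel_size_mm=zooms,
            affine=np.asarray(img.affine),
        )


def fwhm_to_sigma(fwhm_mm: float, voxel_size_mm) -> np.ndarray:
    """Per-axis Gaussian sigma in voxel units for an isotropic FWHM in mm."""
    if fwhm_mm <= 0:
        raise ValueError("fwhm must be positive")
    voxel = np.asarray(voxel_size_mm, dtype=float)
    return (fwhm_mm / _FWHM_PER_SIGMA) / voxel


def smooth_volume(vol: IntensityVolume, fwhm_mm: float = 16.0) -> IntensityVolume:
    """Convolve with an isotropic Gaussian kernel of the given FWHM.

    Boundary handling is constant-zero padding, the usual convention for
    brain-masked volumes; total intensity is conserved up to what leaks
    across the grid boundary.
    """
    sigma = fwhm_to_sigma(fwhm_mm, vol.voxel_size_mm)
    smoothed = ndimage.gaussian_filter(vol.voxels, sigma=sigma, mode="constant", cval=0.0)
    return IntensityVolume(smoothed, vol.voxel_size_mm, vol.affine)


def _cerebellar_mask(atlas: RegionAtlas) -> np.ndarray:
    if atlas.label_volume is None:
        raise ValueError("atlas has no label volume")
    codes = atlas.cerebellar_codes()
    if codes.size == 0:
        raise ValueError("invalid reference region: no cerebellar labels in table")
    return np.isin(atlas.label_volume, codes)


def normalize_by_cerebellum(vol: IntensityVolume, atlas: RegionAtlas) -> IntensityVolume:
    """Divide every voxel by the mean intensity over cerebellar voxels.

    The cerebellum serves as reference region because it is the area least
    affected in Alzheimer's disease; after normalization its mean is 1.
    """
    mask = _cerebellar_mask(atlas)
    if atlas.label_volume.shape != vol.shape:
        raise ValueError("atlas and volume dimensions differ")
    if not mask.any():
        raise ValueError("invalid reference region: no cerebellar voxels")
    reference = float(vol.voxels[mask].mean())
    if reference <= 0:
        raise ValueError("invalid reference region: cerebellar mean <= 0")
    return IntensityVolume(vol.voxels / reference, vol.voxel_size_mm, vol.affine)


def extract_roi_means(vol: IntensityVolume, atlas: RegionAtlas) -> np.ndarray:
    """Mean intensity per atlas region, in atlas order.

    Regions with no voxels in the label volume yield NaN and a warning; they
    signal a mismatched or toy atlas rather than a recoverable state.
    """
    if atlas.label_volume is None:
        raise ValueError("atlas has no label volume")
    if atlas.label_volume.shape != vol.shape:
        raise ValueError("atlas and volume dimensions differ")
    codes = atlas.codes
    sums = ndimage.sum_labels(vol.voxels, labels=atlas.label_volume, index=codes)
    counts = ndimage.sum_labels(
        np.ones_like(vol.voxels), labels=atlas.label_volume, index=codes
    )
    empty = counts == 0
    if empty.any():
        logger.warning(
            "regions with no voxels: %s", codes[empty].tolist()
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(empty, np.nan, sums / np.maximum(counts, 1))
    return means


def build_subject_series(
    volumes: list[IntensityVolume],
    atlas: RegionAtlas,
    group_label: str = "",
    subject_ids=None,
    smooth_fwhm_mm: float | None = None,
    normalize: bool = True,
    drop_cerebellar: bool = True,
) -> SubjectSeries:
    """Reduce a list of registered volumes to a subjects x regions table.

    Each volume is optionally smoothed, normalized by the cerebellar mean,
    and reduced to per-region means; rows follow the input subject order,
    columns the atlas region order.  Pass the full atlas (cerebellar labels
    included) so the reference region is available; with ``drop_cerebellar``
    the returned table keeps only the cerebral regions, the columns the
    connectivity analysis uses.
    """
    if not volumes:
        raise ValueError("need at least one volume")
    shape = volumes[0].shape
    rows = []
    for vol in volumes:
        if vol.shape != shape:
            raise ValueError("inconsistent volume dimensions across subjects")
        if smooth_fwhm_mm is not None:
            vol = smooth_volume(vol, smooth_fwhm_mm)
        if normalize:
            vol = normalize_by_cerebellum(vol, atlas)
        rows.append(extract_roi_means(vol, atlas))
    values = np.vstack(rows)
    keep = np.ones(atlas.n_regions, dtype=bool)
    if drop_cerebellar:
        keep = ~atlas.label_table["cerebellar"].astype(bool).to_numpy()
    return SubjectSeries.from_array(
        values[:, keep],
        region_ids=atlas.codes[keep],
        subject_ids=subject_ids,
        group_label=group_label,
    )
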