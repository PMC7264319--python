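"""Lesion volume container and NIfTI-1 I/O.

A :class:`LesionVolume` bundles the three things every stage of the
pipeline needs for one metastasis: the scalar intensity array, the binary
lesion mask of identical shape, and the voxel spacing in millimetres.
Axis order is (z, y, x); axis 0 is the axial (slice) axis.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["LesionVolume", "save_nifti", "load_nifti", "load_lesion"]


@dataclass
class LesionVolume:
    """One lesion: intensities, binary mask, and voxel spacing (mm)."""

    intensities: np.ndarray
    mask: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3D array")
        if self.intensities.shape != self.mask.shape:
            raise ValueError(
                f"shape mismatch: intensities {self.intensities.shape} "
                f"vs mask {self.mask.shape}"
            )
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be three positive lengths")
        if not self.mask.any():
            raise ValueError("mask is empty")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def n_mask_voxels(self) -> int:
        return int(self.mask.sum())

    def masked_values(self) -> np.ndarray:
        """In-mask intensities as a flat array."""
        return self.intensities[self.mask]

    def copy_with(self, intensities=None, mask=None) -> "LesionVolume":
        return LesionVolume(
            intensities=self.intensities if intensities is None else intensities,
            mask=self.mask if mask is None else mask,
            spacing_mm=self.spacing_mm,
        )


def _affine_from_spacing(spacing_mm) -> np.ndarray:
    # array axes (z, y, x) map to world (x, y, z) reversed; a plain diagonal
    # scaling is enough for synthetic volumes with no meaningful orientation.
    aff = np.diag([spacing_mm[2], spacing_mm[1], spacing_mm[0], 1.0])
    return aff


def save_nifti(array: np.ndarray, spacing_mm, path) -> None:
    """Write ``array`` as NIfTI-1.

    ``.nii.gz`` output is gzipped with mtime pinned to zero so that two
    runs with the same seed produce byte-identical files.
    """
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(array), _affine_from_spacing(spacing_mm))
    img.header.set_zooms((spacing_mm[2], spacing_mm[1], spacing_mm[0]))
    if path.name.endswith(".gz"):
        payload = img.to_bytes()
        path.write_bytes(gzip.compress(payload, compresslevel=6, mtime=0))
    else:
        nib.save(img, str(path))


def load_nifti(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a NIfTI volume, returning (array, spacing_mm) in (z, y, x) order."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return data, spacing


def load_lesion(volume_path, mask_path, canonical: bool = False) -> LesionVolume:
    """Load an intensity volume and its binary mask into a LesionVolume.

    ``canonical=True`` reorients both images to the closest RAS
    orientation first — a no-op for the synthetic volumes written by this
    package, but a necessary hook for real scans with arbitrary affines.
    """
    if canonical:
        vol_img = nib.as_closest_canonical(nib.load(str(volume_path)))
        mask_img = nib.as_closest_canonical(nib.load(str(mask_path)))
        intens = np.asarray(vol_img.dataobj)
        mask = np.asarray(mask_img.dataobj)
        zooms = vol_img.header.get_zooms()[:3]
        spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
        if mask.shape != intens.shape:
            raise ValueError(
                f"mask shape {mask.shape} does not match volume {intens.shape}"
            )
        return LesionVolume(intensities=intens, mask=mask > 0, spacing_mm=spacing)
    intens, spacing = load_nifti(volume_path)
    mask, _ = load_nifti(mask_path)
    if mask.shape != intens.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match volume {intens.shape} "
            f"({mask_path})"
        )
    return LesionVolume(intensities=intens, mask=mask > 0, spacing_mm=spacing)
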