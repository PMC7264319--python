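"""Per-lesion preprocessing: bias correction, cropping, normalisation.

The chain applied before feature extraction is fixed:

    correct_bias -> crop_to_roi -> normalize_zscore

Bias correction divides by a Gaussian low-pass estimate of the smooth
multiplicative intensity field (FWHM default 60 mm) and rescales so the
masked mean is preserved. This is a deliberately simple surrogate for
histogram-sharpening nonuniformity correction: the synthetic bias is
smooth and multiplicative, which is exactly the regime a low-pass
estimate recovers. Normalisation statistics are computed over the whole
cropped volume, not the mask alone.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .volume import LesionVolume

__all__ = [
    "correct_bias",
    "crop_to_roi",
    "normalize_zscore",
    "preprocess_lesion",
    "FWHM_TO_SIGMA",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def correct_bias(volume: LesionVolume, smoothing_fwhm_mm: float = 60.0) -> LesionVolume:
    """Divide out a Gaussian low-pass estimate of the multiplicative bias.

    Intensities are shifted to be strictly positive before division, and
    the output is rescaled so the in-mask mean equals the input's.
    """
    x = volume.intensities
    if not np.any(x):
        raise ValueError("cannot bias-correct an all-zero volume")
    offset = 0.0
    xmin = x.min()
    if xmin <= 0:
        offset = -xmin + 1e-3 * max(1.0, float(np.ptp(x)))
    shifted = x + offset
    sigma_vox = [
        smoothing_fwhm_mm * FWHM_TO_SIGMA / s for s in volume.spacing_mm
    ]
    field = ndimage.gaussian_filter(shifted, sigma=sigma_vox, mode="reflect")
    corrected = shifted / field
    target_mean = shifted[volume.mask].mean()
    corrected *= target_mean / corrected[volume.mask].mean()
    return volume.copy_with(intensities=corrected - offset)


def crop_to_roi(volume: LesionVolume, margin_voxels: int = 2) -> LesionVolume:
    """Crop to the mask bounding box dilated by ``margin_voxels``.

    The margin is clipped at the volume bounds; the mask voxel count is
    unchanged by construction.
    """
    if margin_voxels < 0:
        raise ValueError("margin must be >= 0")
    if not volume.mask.any():
        raise ValueError("cannot crop: mask is empty")
    slices = []
    for axis in range(3):
        other = tuple(a for a in range(3) if a != axis)
        profile = volume.mask.any(axis=other)
        nz = np.nonzero(profile)[0]
        lo = max(int(nz[0]) - margin_voxels, 0)
        hi = min(int(nz[-1]) + margin_voxels + 1, volume.shape[axis])
        slices.append(slice(lo, hi))
    slices = tuple(slices)
    return LesionVolume(
        intensities=volume.intensities[slices].copy(),
        mask=volume.mask[slices].copy(),
        spacing_mm=volume.spacing_mm,
    )


def normalize_zscore(volume: LesionVolume, lesion_id: str = "") -> LesionVolume:
    """Standardise the whole cropped volume to zero mean, unit variance."""
    x = volume.intensities
    mu = x.mean()
    sd = x.std()
    if sd == 0:
        tag = f" (lesion {lesion_id})" if lesion_id else ""
        raise ValueError(f"zero intensity variance, cannot normalise{tag}")
    return volume.copy_with(intensities=(x - mu) / sd)


def preprocess_lesion(
    volume: LesionVolume,
    bias_fwhm_mm: float = 60.0,
    margin_voxels: int = 2,
    apply_bias_correction: bool = True,
    lesion_id: str = "",
) -> LesionVolume:
    """Full fixed-order chain: bias correction, crop, z-score normalise."""
    if apply_bias_correction:
        volume = correct_bias(volume, bias_fwhm_mm)
    volume = crop_to_roi(volume, margin_voxels)
    return normalize_zscore(volume, lesion_id=lesion_id)
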