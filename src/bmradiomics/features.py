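"""The 1209-entry radiomic feature vector and cohort-level extraction.

Per lesion the descriptor is, in fixed registry order:

* 6 first-order histogram statistics of the raw (preprocessed) ROI;
* 25 second-order texture statistics of the raw ROI — 14 Haralick GLCM
  features plus 11 gray-level run-length features;
* for each of the 38 RFS filter-bank response maps, the same 6 + 25
  features computed within the lesion mask (1178 higher-order features).

Total: 6 + 25 + 38 x 31 = 1209. Response maps are z-scored within the
mask and re-quantized per map before their second-order features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .filters import FilterBank, apply_filter_bank, build_rfs_bank
from .preprocessing import preprocess_lesion
from .texture import (
    DIRECTIONS_3D_13,
    FIRST_ORDER_NAMES,
    GLRLM_NAMES,
    HARALICK_NAMES,
    compute_glcm,
    compute_glrlm,
    first_order_features,
    glrlm_features,
    haralick_features,
    quantize,
)
from .volume import LesionVolume, load_lesion

__all__ = [
    "ExtractionParams",
    "FeatureVector",
    "feature_names",
    "extract_all",
    "extract_cohort",
    "N_FEATURES",
]

N_FEATURES = 1209
MIN_MASK_VOXELS = 8


@dataclass
class ExtractionParams:
    """Knobs of the extraction stage.

    n_levels: gray levels for GLCM/GLRLM quantization (equal-width over
    the in-mask range). n_bins: histogram bins for first-order energy and
    entropy. base_sigma: scale (voxels) of the bank's Gaussian and LoG.
    """

    n_levels: int = 32
    n_bins: int = 64
    base_sigma: float = 10.0
    offsets: tuple = DIRECTIONS_3D_13


@dataclass
class FeatureVector:
    values: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self):
        if len(self.values) != len(self.names):
            raise ValueError("values/names length mismatch")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values))


def _roi_block_names(prefix: str) -> list[str]:
    names = [f"{prefix}fo.{n}" for n in FIRST_ORDER_NAMES]
    names += [f"{prefix}glcm.{n}" for n in HARALICK_NAMES]
    names += [f"{prefix}glrlm.{n}" for n in GLRLM_NAMES]
    return names


def feature_names(bank: FilterBank | None = None) -> tuple[str, ...]:
    """Stable registry of the 1209 feature names."""
    if bank is None:
        bank = build_rfs_bank()
    names = _roi_block_names("")
    for kname in bank.names:
        names += _roi_block_names(f"rfs.{kname}.")
    assert len(names) == N_FEATURES
    return tuple(names)


def _mask_bbox(mask: np.ndarray) -> tuple[slice, ...]:
    slices = []
    for axis in range(mask.ndim):
        other = tuple(a for a in range(mask.ndim) if a != axis)
        nz = np.nonzero(mask.any(axis=other))[0]
        slices.append(slice(int(nz[0]), int(nz[-1]) + 1))
    return tuple(slices)


def _roi_features(volume: LesionVolume, params: ExtractionParams) -> list[float]:
    """6 + 25 features of one masked scalar volume."""
    fo = first_order_features(volume, n_bins=params.n_bins)
    roi = quantize(volume, n_levels=params.n_levels)
    glcm = compute_glcm(roi, params.offsets)
    har = haralick_features(glcm)
    glrlm = compute_glrlm(roi, params.offsets)
    rl = glrlm_features(glrlm)
    return (
        [fo[n] for n in FIRST_ORDER_NAMES]
        + [har[n] for n in HARALICK_NAMES]
        + [rl[n] for n in GLRLM_NAMES]
    )


def _zscore_in_mask(resp: np.ndarray, mask: np.ndarray) -> np.ndarray:
    vals = resp[mask]
    sd = vals.std()
    out = np.zeros_like(resp)
    if sd > 0:
        out[mask] = (vals - vals.mean()) / sd
    return out


def extract_all(
    volume: LesionVolume,
    params: ExtractionParams | None = None,
    bank: FilterBank | None = None,
    lesion_id: str = "",
) -> FeatureVector:
    """Compute the full ordered 1209-feature descriptor of one lesion.

    ``volume`` is expected to be preprocessed (bias-corrected, cropped,
    z-score normalised); the function itself is deterministic.
    """
    params = params or ExtractionParams()
    bank = bank or build_rfs_bank(params.base_sigma)
    if volume.n_mask_voxels < MIN_MASK_VOXELS:
        tag = f" (lesion {lesion_id})" if lesion_id else ""
        raise ValueError(
            f"mask has {volume.n_mask_voxels} voxels; need >= {MIN_MASK_VOXELS}{tag}"
        )

    bbox = _mask_bbox(volume.mask)
    tight = LesionVolume(
        volume.intensities[bbox], volume.mask[bbox], volume.spacing_mm
    )
    values = _roi_features(tight, params)

    responses = apply_filter_bank(volume, bank)
    tight_mask = volume.mask[bbox]
    for idx in range(len(bank)):
        resp = responses[idx][bbox]
        resp_z = _zscore_in_mask(resp, tight_mask)
        rvol = LesionVolume(resp_z, tight_mask, volume.spacing_mm)
        values += _roi_features(rvol, params)

    arr = np.asarray(values, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        bad = [feature_names(bank)[i] for i in np.nonzero(~np.isfinite(arr))[0]]
        raise ValueError(f"non-finite features for lesion {lesion_id!r}: {bad[:5]}")
    return FeatureVector(values=arr, names=feature_names(bank))


META_COLUMNS = ("lesion_id", "patient_id", "label", "diameter_mm")


def extract_cohort(
    records,
    params: ExtractionParams | None = None,
    bias_fwhm_mm: float = 60.0,
    margin_voxels: int = 2,
    apply_bias_correction: bool = True,
    n_jobs: int = 1,
) -> pd.DataFrame:
    """Preprocess and extract features for every lesion of a cohort.

    Returns a DataFrame with lesion_id, patient_id, label, diameter_mm
    followed by the 1209 named feature columns, one row per lesion.
    """
    params = params or ExtractionParams()
    bank = build_rfs_bank(params.base_sigma)
    names = feature_names(bank)

    def one(rec):
        vol = rec.volume
        if vol is None:
            vol = load_lesion(rec.volume_path, rec.mask_path)
        pre = preprocess_lesion(
            vol,
            bias_fwhm_mm=bias_fwhm_mm,
            margin_voxels=margin_voxels,
            apply_bias_correction=apply_bias_correction,
            lesion_id=rec.lesion_id,
        )
        fv = extract_all(pre, params, bank=bank, lesion_id=rec.lesion_id)
        return fv.values

    if n_jobs == 1:
        rows = [one(r) for r in records]
    else:
        rows = Parallel(n_jobs=n_jobs)(delayed(one)(r) for r in records)

    meta = pd.DataFrame(
        {
            "lesion_id": [r.lesion_id for r in records],
            "patient_id": [r.patient_id for r in records],
            "label": [r.label for r in records],
            "diameter_mm": [r.diameter_mm for r in records],
        }
    )
    feats = pd.DataFrame(np.vstack(rows), columns=list(names))
    return pd.concat([meta, feats], axis=1)
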