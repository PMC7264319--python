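"""Synthetic two-class lesion cohort generator.

No imaging data accompany the analysis this package reimplements, so the
cohort is emulated: ~60 patients carrying 1-12 enhancing brain metastases
each (diameters 3-40 mm), where the patient's binary genotype label shifts
the *texture* of the lesion interior — the correlation length and standard
deviation of a stationary random field — and optionally the brightness of
an enhancing rim. Everything downstream (preprocessing, feature
extraction, selection, classification) is exercised against this cohort.

The intralesional field is white Gaussian noise convolved with a Gaussian
kernel whose width is the requested correlation length; only second-order
statistics matter to the texture features, so this simple family suffices.
Each volume is background noise plus the embedded ellipsoidal lesion,
multiplied by a smooth multiplicative bias field emulating coil
nonuniformity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage, optimize

from .volume import LesionVolume, save_nifti

__all__ = [
    "TextureParams",
    "CohortConfig",
    "LesionRecord",
    "texture_field",
    "embed_lesion",
    "generate_cohort",
    "write_manifest",
]

MIN_DIAMETER_MM = 3.0
MAX_DIAMETER_MM = 40.0


@dataclass(frozen=True)
class TextureParams:
    """Class-conditional interior texture of a lesion.

    correlation_length_mm
        Width (Gaussian sigma, mm) of the smoothing kernel applied to white
        noise; larger values give coarser, more slowly varying texture.
    field_sd
        Standard deviation of the interior random field, in the arbitrary
        intensity units of the synthetic scan.
    rim_contrast
        Extra intensity added in the outer shell of the ellipsoid,
        emulating ring enhancement; off by default because a rim shared
        by both classes only adds nuisance variance on top of the
        class-defining interior texture.
    """

    correlation_length_mm: float = 1.5
    field_sd: float = 0.4
    rim_contrast: float = 0.0


@dataclass(frozen=True)
class DistributionSpec:
    """Bounded unimodal distribution summarised by (min, max, mean)."""

    minimum: float
    maximum: float
    mean: float

    def __post_init__(self):
        if not (self.minimum <= self.mean <= self.maximum):
            raise ValueError(
                f"mean {self.mean} outside [{self.minimum}, {self.maximum}]"
            )


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults reproduce the cohort structure of the motivating study: 61
    patients, ~3.4 lesions per patient (hence ~210 lesions), diameters
    3-40 mm with mean ~10.5 mm, and 29/61 of patients mutant. The default
    texture effect doubles the mutant interior correlation length, a
    "strong" but purely textural class difference.
    """

    n_patients: int = 61
    lesions_per_patient: DistributionSpec = field(
        default_factory=lambda: DistributionSpec(1, 12, 3.4)
    )
    diameter_mm: DistributionSpec = field(
        default_factory=lambda: DistributionSpec(MIN_DIAMETER_MM, MAX_DIAMETER_MM, 10.5)
    )
    class_fraction: float = 29 / 61
    texture_class0: TextureParams = field(default_factory=TextureParams)
    texture_class1: TextureParams = field(
        default_factory=lambda: TextureParams(correlation_length_mm=3.0)
    )
    voxel_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    background_sd: float = 0.2
    bias_field_amplitude: float = 0.2
    seed: int = 0

    # fixed scan geometry / intensity scale
    background_level: float = 10.0
    lesion_contrast: float = 2.0
    margin_mm: float = 4.0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not (0.0 <= self.class_fraction <= 1.0):
            raise ValueError("class_fraction must lie in [0, 1]")
        if self.diameter_mm.minimum < MIN_DIAMETER_MM:
            raise ValueError(
                f"diameters below {MIN_DIAMETER_MM} mm are not measurable lesions"
            )
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError("voxel spacing must be positive")

    def texture_for(self, label: int) -> TextureParams:
        return self.texture_class1 if label else self.texture_class0


@dataclass
class LesionRecord:
    """Manifest row for one lesion; volume/mask paths or in-memory arrays."""

    lesion_id: str
    patient_id: str
    label: int
    diameter_mm: float
    volume_path: str = ""
    mask_path: str = ""
    volume: LesionVolume | None = None

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")
        if self.diameter_mm < MIN_DIAMETER_MM:
            raise ValueError(
                f"lesion {self.lesion_id}: diameter {self.diameter_mm} < "
                f"{MIN_DIAMETER_MM} mm"
            )


def texture_field(
    shape,
    correlation_length_mm: float,
    field_sd: float,
    spacing_mm=(1.0, 1.0, 1.0),
    rng=None,
) -> np.ndarray:
    """Zero-mean stationary Gaussian random field with tunable smoothness.

    White noise is convolved with a Gaussian kernel of sigma
    ``correlation_length_mm`` (converted to voxels per axis) and then
    standardised to exactly zero mean and ``field_sd`` standard deviation.
    ``correlation_length_mm == 0`` yields i.i.d. noise.
    """
    shape = tuple(int(s) for s in shape)
    if any(s <= 0 for s in shape):
        raise ValueError(f"shape must be positive, got {shape}")
    if correlation_length_mm < 0 or field_sd < 0:
        raise ValueError("correlation length and field SD must be >= 0")
    rng = np.random.default_rng(rng)
    noise = rng.standard_normal(shape)
    if field_sd == 0:
        return np.zeros(shape)
    if correlation_length_mm > 0:
        sigma_vox = [correlation_length_mm / s for s in spacing_mm]
        noise = ndimage.gaussian_filter(noise, sigma=sigma_vox, mode="reflect")
    sd = noise.std()
    if sd == 0:  # single-voxel field
        return np.zeros(shape)
    return (noise - noise.mean()) / sd * field_sd


def embed_lesion(
    background: np.ndarray,
    center_vox,
    radii_mm,
    spacing_mm,
    texture: TextureParams,
    lesion_contrast: float,
    rng=None,
    rim_fraction: float = 0.75,
) -> tuple[np.ndarray, np.ndarray]:
    """Place an ellipsoidal textured lesion into ``background``.

    The mask is the exact voxel set whose centers fall inside the
    ellipsoid. Interior voxels are *set* to the lesion's base intensity
    (mean background level plus ``lesion_contrast``) plus the class
    texture field — the intralesional random field is the sole source of
    in-mask variability, so the configured texture parameters are the
    texture of the lesion, undiluted by background noise. Voxels in the
    outer shell (normalised radius > ``rim_fraction``) additionally
    receive ``texture.rim_contrast``.

    Returns (volume, mask); the background array is not modified.
    """
    background = np.asarray(background, dtype=np.float64)
    center = np.asarray(center_vox, dtype=np.float64)
    radii_vox = np.asarray(radii_mm, dtype=np.float64) / np.asarray(spacing_mm)
    lo = center - radii_vox
    hi = center + radii_vox
    if (lo < -0.5).any() or (hi > np.asarray(background.shape) - 0.5).any():
        raise ValueError(
            f"ellipsoid (center {center_vox}, radii {radii_mm} mm) does not "
            f"fit inside volume of shape {background.shape}"
        )
    grids = np.ogrid[tuple(slice(0, s) for s in background.shape)]
    rho2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii_vox))
    mask = rho2 <= 1.0
    volume = background.copy()
    tex = texture_field(
        background.shape,
        texture.correlation_length_mm,
        texture.field_sd,
        spacing_mm,
        rng=rng,
    )
    volume[mask] = float(background.mean()) + lesion_contrast + tex[mask]
    rim = mask & (rho2 >= rim_fraction**2)
    volume[rim] += texture.rim_contrast
    return volume, mask


def _lesion_count_pmf(spec: DistributionSpec) -> np.ndarray:
    """Truncated-geometric pmf on {min..max} whose mean matches the spec."""
    ks = np.arange(int(spec.minimum), int(spec.maximum) + 1, dtype=float)
    if len(ks) == 1:
        return np.array([1.0])

    def mean_at(q):  # q = log-ratio parameterisation, monotone in mean
        w = np.exp(-q * (ks - ks[0]))
        return float((ks * w).sum() / w.sum())

    target = min(max(spec.mean, mean_at(10) + 1e-9), mean_at(-10) - 1e-9)
    q = optimize.brentq(lambda q: mean_at(q) - target, -10, 10)
    w = np.exp(-q * (ks - ks[0]))
    return w / w.sum()


def _draw_diameter(spec: DistributionSpec, rng) -> float:
    """Right-skewed bounded diameter draw with the configured mean.

    Scaled Beta with concentration 2.2; the mean is matched exactly by
    construction and the shape mimics the long right tail of clinical
    lesion-size distributions.
    """
    if spec.maximum == spec.minimum:
        return float(spec.minimum)
    m = (spec.mean - spec.minimum) / (spec.maximum - spec.minimum)
    conc = 2.2
    a, b = max(m * conc, 1e-3), max((1 - m) * conc, 1e-3)
    return float(spec.minimum + (spec.maximum - spec.minimum) * rng.beta(a, b))


def _bias_field(shape, amplitude: float, spacing_mm, rng) -> np.ndarray:
    """Smooth multiplicative field in [1-a, 1+a], ~constant gradient scale."""
    if amplitude == 0:
        return np.ones(shape)
    g = rng.standard_normal(shape)
    sigma_vox = [25.0 / s for s in spacing_mm]
    g = ndimage.gaussian_filter(g, sigma=sigma_vox, mode="reflect")
    peak = np.abs(g).max()
    if peak == 0:
        return np.ones(shape)
    return 1.0 + amplitude * g / peak


def generate_cohort(
    config: CohortConfig, out_dir=None
) -> list[LesionRecord]:
    """Draw a full two-class cohort; deterministic given ``config.seed``.

    Labels are assigned per patient (round(class_fraction * n_patients)
    patients are class 1) and shared by all of that patient's lesions.
    When ``out_dir`` is given, volumes and masks are written as
    ``.nii.gz`` plus a ``manifest.csv``; otherwise the records carry
    in-memory :class:`LesionVolume` objects.
    """
    root = np.random.SeedSequence(config.seed)
    ss_structure, ss_lesions = root.spawn(2)
    rng = np.random.default_rng(ss_structure)

    n1 = int(round(config.class_fraction * config.n_patients))
    labels = np.zeros(config.n_patients, dtype=int)
    labels[rng.permutation(config.n_patients)[:n1]] = 1

    pmf = _lesion_count_pmf(config.lesions_per_patient)
    k_lo = int(config.lesions_per_patient.minimum)
    counts = rng.choice(np.arange(k_lo, k_lo + len(pmf)), size=config.n_patients, p=pmf)

    spacing = config.voxel_spacing_mm
    records: list[LesionRecord] = []
    lesion_streams = iter(ss_lesions.spawn(int(counts.sum())))

    if out_dir is not None:
        out_dir = Path(out_dir)
        (out_dir / "volumes").mkdir(parents=True, exist_ok=True)

    idx = 0
    for p in range(config.n_patients):
        patient_id = f"P{p:03d}"
        label = int(labels[p])
        tex = config.texture_for(label)
        for j in range(int(counts[p])):
            idx += 1
            lesion_id = f"L{idx:04d}"
            lrng = np.random.default_rng(next(lesion_streams))
            diameter = _draw_diameter(config.diameter_mm, lrng)
            rmax = diameter / 2.0
            # longest axis = recorded diameter; minor axes 70-100% of it
            radii = np.array([rmax * lrng.uniform(0.7, 1.0) for _ in range(3)])
            radii[lrng.integers(3)] = rmax
            diameter = 2.0 * rmax

            extent = 2 * (rmax + config.margin_mm)
            shape = tuple(
                max(5, int(math.ceil(extent / s))) for s in spacing
            )
            center = tuple((s - 1) / 2.0 for s in shape)

            bg = config.background_level + config.background_sd * lrng.standard_normal(
                shape
            )
            vol, mask = embed_lesion(
                bg, center, radii, spacing, tex, config.lesion_contrast, rng=lrng
            )
            vol = vol * _bias_field(shape, config.bias_field_amplitude, spacing, lrng)

            rec = LesionRecord(
                lesion_id=lesion_id,
                patient_id=patient_id,
                label=label,
                diameter_mm=diameter,
            )
            if out_dir is None:
                rec.volume = LesionVolume(vol, mask, spacing)
            else:
                vpath = out_dir / "volumes" / f"{lesion_id}.nii.gz"
                mpath = out_dir / "volumes" / f"{lesion_id}_mask.nii.gz"
                save_nifti(vol.astype(np.float32), spacing, vpath)
                save_nifti(mask.astype(np.uint8), spacing, mpath)
                rec.volume_path = str(vpath)
                rec.mask_path = str(mpath)
            records.append(rec)

    if out_dir is not None:
        write_manifest(records, out_dir / "manifest.csv")
    return records


def write_manifest(records: list[LesionRecord], path) -> None:
    """Write the cohort manifest CSV (deterministic formatting)."""
    lines = ["lesion_id,patient_id,label,diameter_mm,volume_path,mask_path"]
    for r in records:
        lines.append(
            f"{r.lesion_id},{r.patient_id},{r.label},{r.diameter_mm:.4f},"
            f"{r.volume_path},{r.mask_path}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
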