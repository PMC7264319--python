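"""The 38-filter root filter set (RFS) bank and slice-wise application.

The RFS bank is the classical oriented texture filter set: anisotropic
first-derivative ("edge") and second-derivative ("bar") of-Gaussian
kernels at 6 orientations (30 degree steps) and 3 scales
(sigma_short, sigma_long) = (1, 3), (2, 6), (4, 12) voxels — 36 kernels —
plus one isotropic Gaussian and one Laplacian-of-Gaussian (sigma 10),
38 kernels in all. Derivative and LoG kernels are made exactly zero-sum
and every kernel is L1-normalised (the Gaussian therefore sums to 1).

Filters are 2D by construction and are applied slice-wise along the
axial (first) axis with reflect padding, yielding 38 response volumes of
the input shape. Higher-order radiomic features are then computed on
each response map within the lesion mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume import LesionVolume

__all__ = ["FilterBank", "build_rfs_bank", "apply_filter_bank", "RFS_SUPPORT"]

RFS_SUPPORT = 49  # kernel side length, voxels
RFS_SCALES = ((1.0, 3.0), (2.0, 6.0), (4.0, 12.0))  # (sigma_short, sigma_long)
RFS_N_ORIENTATIONS = 6


@dataclass
class FilterBank:
    """Named 2D kernels in fixed registry order."""

    names: tuple[str, ...]
    kernels: tuple[np.ndarray, ...]
    _fft_cache: dict = field(default_factory=dict, repr=False)

    def __len__(self) -> int:
        return len(self.kernels)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.kernels[self.names.index(name)]


def _oriented_gaussian_derivative(
    sigma_short: float, sigma_long: float, theta: float, order: int, support: int
) -> np.ndarray:
    """Derivative-of-Gaussian kernel elongated along the theta direction.

    The Gaussian envelope has sigma ``sigma_long`` along the orientation
    axis and ``sigma_short`` across it; the derivative (order 1 or 2) is
    taken across the orientation axis.
    """
    half = support // 2
    y, x = np.mgrid[-half : half + 1, -half : half + 1].astype(np.float64)
    # rotate coordinates: u along orientation, v across it
    u = x * np.cos(theta) + y * np.sin(theta)
    v = -x * np.sin(theta) + y * np.cos(theta)
    envelope = np.exp(-(u**2) / (2 * sigma_long**2) - (v**2) / (2 * sigma_short**2))
    if order == 1:
        k = -v / sigma_short**2 * envelope
    elif order == 2:
        k = (v**2 / sigma_short**4 - 1.0 / sigma_short**2) * envelope
    else:
        raise ValueError("order must be 1 or 2")
    k -= k.mean()
    return k / np.abs(k).sum()


def _gaussian_kernel(sigma: float, support: int) -> np.ndarray:
    half = support // 2
    y, x = np.mgrid[-half : half + 1, -half : half + 1].astype(np.float64)
    k = np.exp(-(x**2 + y**2) / (2 * sigma**2))
    return k / k.sum()


def _log_kernel(sigma: float, support: int) -> np.ndarray:
    half = support // 2
    y, x = np.mgrid[-half : half + 1, -half : half + 1].astype(np.float64)
    r2 = x**2 + y**2
    k = (r2 - 2 * sigma**2) / sigma**4 * np.exp(-r2 / (2 * sigma**2))
    k -= k.mean()
    return k / np.abs(k).sum()


def build_rfs_bank(base_sigma_mm: float = 10.0, support: int = RFS_SUPPORT) -> FilterBank:
    """Construct the 38-kernel RFS bank.

    ``base_sigma_mm`` sets the isotropic Gaussian / LoG scale (in voxels
    at the default 1 mm spacing). Kernel order: all edge kernels (scale
    major, orientation minor), all bar kernels, Gaussian, LoG.
    """
    if base_sigma_mm <= 0:
        raise ValueError("base_sigma must be positive")
    names: list[str] = []
    kernels: list[np.ndarray] = []
    for kind, order in (("edge", 1), ("bar", 2)):
        for si, (s_short, s_long) in enumerate(RFS_SCALES):
            for oi in range(RFS_N_ORIENTATIONS):
                theta = oi * np.pi / RFS_N_ORIENTATIONS
                names.append(f"{kind}_s{si}_o{oi}")
                kernels.append(
                    _oriented_gaussian_derivative(
                        s_short, s_long, theta, order, support
                    )
                )
    names.append("gaussian")
    kernels.append(_gaussian_kernel(base_sigma_mm, support))
    names.append("log")
    kernels.append(_log_kernel(base_sigma_mm, support))
    assert len(kernels) == 38
    return FilterBank(names=tuple(names), kernels=tuple(kernels))


def _reflect_pad_inplane(vol: np.ndarray, pad: int) -> np.ndarray:
    """Reflect-pad axes 1 and 2 by ``pad``, chunked so tiny slices work."""
    out = vol
    remaining = pad
    while remaining > 0:
        step = min(remaining, out.shape[1] - 1, out.shape[2] - 1)
        if step <= 0:  # degenerate 1-voxel plane: fall back to edge padding
            out = np.pad(out, ((0, 0), (remaining, remaining), (remaining, remaining)), mode="edge")
            break
        out = np.pad(out, ((0, 0), (step, step), (step, step)), mode="reflect")
        remaining -= step
    return out


def apply_filter_bank(volume: LesionVolume, bank: FilterBank) -> np.ndarray:
    """Convolve every kernel slice-wise; returns (n_kernels, *shape).

    Each 2D kernel is convolved with every axial slice under reflect
    padding; responses keep the input shape and follow the bank's
    registry order. Implemented with one in-plane FFT of the padded
    volume shared across all kernels.
    """
    if len(volume.shape) != 3 or volume.shape[0] < 1:
        raise ValueError("volume must have at least one axial slice")
    support = bank.kernels[0].shape[0]
    half = support // 2
    padded = _reflect_pad_inplane(volume.intensities, half)
    nz, ny, nx = padded.shape
    vf = np.fft.rfft2(padded, axes=(1, 2))

    key = (ny, nx)
    if key not in bank._fft_cache:
        kf = []
        for k in bank.kernels:
            buf = np.zeros((ny, nx))
            buf[:support, :support] = k
            buf = np.roll(buf, (-half, -half), axis=(0, 1))
            kf.append(np.fft.rfft2(buf))
        bank._fft_cache[key] = np.stack(kf)
    kfs = bank._fft_cache[key]

    out = np.empty((len(bank), *volume.shape))
    sl = (slice(None), slice(half, half + volume.shape[1]), slice(half, half + volume.shape[2]))
    for idx in range(len(bank)):
        resp = np.fft.irfft2(vf * kfs[idx][None, :, :], s=(ny, nx), axes=(1, 2))
        out[idx] = resp[sl]
    return out
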