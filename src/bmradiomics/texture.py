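"""First- and second-order texture statistics on masked 3D ROIs.

Second-order features follow the classical texture-analysis literature:
a gray-level co-occurrence matrix (GLCM) accumulated symmetrically over
the 13 unique 3D unit offsets and summarised by the 14 Haralick
statistics, and a gray-level run-length matrix (GLRLM) over the same 13
directions summarised by the 11 standard run-length statistics — 25
texture features per ROI in total.

Conventions used throughout:

* quantization is equal-width over the in-mask intensity range;
* logarithms are base 2 and ``0 * log 0`` terms are dropped;
* statistics that are undefined on a degenerate matrix (e.g. GLCM
  correlation when a marginal SD is zero) are defined as 0;
* GLRLM gray levels are indexed from 1 for the low/high gray-level
  weightings.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .volume import LesionVolume

__all__ = [
    "QuantizedROI",
    "GLCM",
    "GLRLM",
    "DIRECTIONS_3D_13",
    "quantize",
    "first_order_features",
    "compute_glcm",
    "haralick_features",
    "compute_glrlm",
    "glrlm_features",
    "FIRST_ORDER_NAMES",
    "HARALICK_NAMES",
    "GLRLM_NAMES",
]

#: the 13 unique direction vectors of the 26-neighbourhood (one per
#: antipodal pair), in (z, y, x) voxel steps
DIRECTIONS_3D_13: tuple[tuple[int, int, int], ...] = tuple(
    d
    for d in product((-1, 0, 1), repeat=3)
    if d != (0, 0, 0) and d > (0, 0, 0)
)

FIRST_ORDER_NAMES = ("mean", "variance", "skewness", "kurtosis", "energy", "entropy")
HARALICK_NAMES = (
    "asm",
    "contrast",
    "correlation",
    "sum_of_squares",
    "idm",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",
    "imc2",
    "mcc",
)
GLRLM_NAMES = (
    "sre",
    "lre",
    "gln",
    "rln",
    "rp",
    "lgre",
    "hgre",
    "srlge",
    "srhge",
    "lrlge",
    "lrhge",
)


@dataclass
class QuantizedROI:
    """Integer gray levels in [0, n_levels) inside the mask, -1 outside."""

    levels: np.ndarray
    n_levels: int
    mask: np.ndarray


@dataclass
class GLCM:
    counts: np.ndarray  # n_levels x n_levels
    offsets: tuple
    symmetric: bool = True

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass
class GLRLM:
    counts: np.ndarray  # n_levels x max_run
    directions: tuple
    n_voxels: int


def quantize(volume: LesionVolume, n_levels: int = 32) -> QuantizedROI:
    """Equal-width quantization of in-mask intensities to ``n_levels`` bins.

    The in-mask maximum maps to level ``n_levels - 1``; a constant ROI
    maps entirely to level 0.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    vals = volume.masked_values()
    lo, hi = vals.min(), vals.max()
    levels = np.full(volume.shape, -1, dtype=np.int32)
    if hi == lo:
        levels[volume.mask] = 0
    else:
        scaled = (volume.intensities[volume.mask] - lo) / (hi - lo) * n_levels
        levels[volume.mask] = np.minimum(scaled.astype(np.int32), n_levels - 1)
    return QuantizedROI(levels=levels, n_levels=n_levels, mask=volume.mask)


def first_order_features(volume: LesionVolume, n_bins: int = 64) -> dict[str, float]:
    """Histogram statistics of the in-mask intensity distribution.

    Returns mean, population variance, moment skewness and excess
    kurtosis (both 0 for a constant ROI), and histogram energy
    ``sum(p^2)`` and entropy ``-sum(p log2 p)`` over ``n_bins``
    equal-width bins spanning the in-mask range.
    """
    vals = volume.masked_values()
    if vals.size < 2:
        raise ValueError("first-order features need at least 2 in-mask voxels")
    mu = vals.mean()
    centred = vals - mu
    m2 = np.mean(centred**2)
    if m2 == 0:
        skew = kurt = 0.0
    else:
        skew = float(np.mean(centred**3) / m2**1.5)
        kurt = float(np.mean(centred**4) / m2**2 - 3.0)
    if vals.max() == vals.min():
        p = np.array([1.0])
    else:
        hist, _ = np.histogram(vals, bins=n_bins, range=(vals.min(), vals.max()))
        p = hist / hist.sum()
        p = p[p > 0]
    return {
        "mean": float(mu),
        "variance": float(m2),
        "skewness": skew,
        "kurtosis": kurt,
        "energy": float(np.sum(p**2)),
        "entropy": float(-np.sum(p * np.log2(p))),
    }


def _shifted_slices(shape, offset):
    """Slice pair (src, dst) so that a[dst] aligns with a[src] + offset."""
    src, dst = [], []
    for size, d in zip(shape, offset):
        if d >= 0:
            src.append(slice(0, size - d))
            dst.append(slice(d, size))
        else:
            src.append(slice(-d, size))
            dst.append(slice(0, size + d))
    return tuple(src), tuple(dst)


def compute_glcm(roi: QuantizedROI, offsets=DIRECTIONS_3D_13) -> GLCM:
    """Symmetric co-occurrence counts accumulated over ``offsets``.

    A pair contributes only when both voxels are inside the mask; both
    orderings of each pair are counted.
    """
    n = roi.n_levels
    counts = np.zeros(n * n, dtype=np.int64)
    lv = roi.levels
    for off in offsets:
        src, dst = _shifted_slices(lv.shape, off)
        a = lv[src]
        b = lv[dst]
        valid = (a >= 0) & (b >= 0)
        av, bv = a[valid], b[valid]
        counts += np.bincount(av * n + bv, minlength=n * n)
        counts += np.bincount(bv * n + av, minlength=n * n)
    counts = counts.reshape(n, n)
    if counts.sum() == 0:
        raise ValueError("GLCM has no valid in-mask voxel pairs")
    return GLCM(counts=counts, offsets=tuple(offsets), symmetric=True)


def _xlog2x(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def haralick_features(glcm: GLCM) -> dict[str, float]:
    """The 14 classical Haralick statistics of a normalised GLCM."""
    total = glcm.total
    if total <= 0:
        raise ValueError("GLCM total must be positive")
    p = glcm.counts / total
    n = p.shape[0]
    i = np.arange(n)
    ii, jj = np.meshgrid(i, i, indexing="ij")

    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mux = float(np.sum(i * px))
    muy = float(np.sum(i * py))
    sx = float(np.sqrt(np.sum((i - mux) ** 2 * px)))
    sy = float(np.sqrt(np.sum((i - muy) ** 2 * py)))

    asm = float(np.sum(p**2))
    contrast = float(np.sum((ii - jj) ** 2 * p))
    if sx * sy > 0:
        correlation = float((np.sum(ii * jj * p) - mux * muy) / (sx * sy))
    else:
        correlation = 0.0
    sum_of_squares = float(np.sum((ii - mux) ** 2 * p))
    idm = float(np.sum(p / (1.0 + (ii - jj) ** 2)))

    # p_{x+y}: distribution of i+j, k = 0 .. 2n-2
    pxy_sum = np.bincount((ii + jj).ravel(), weights=p.ravel(), minlength=2 * n - 1)
    k_sum = np.arange(2 * n - 1)
    sum_average = float(np.sum(k_sum * pxy_sum))
    sum_variance = float(np.sum((k_sum - sum_average) ** 2 * pxy_sum))
    sum_entropy = float(-np.sum(_xlog2x(pxy_sum)))

    entropy = float(-np.sum(_xlog2x(p)))

    # p_{x-y}: distribution of |i-j|, k = 0 .. n-1
    pxy_diff = np.bincount(np.abs(ii - jj).ravel(), weights=p.ravel(), minlength=n)
    k_diff = np.arange(n)
    mu_diff = float(np.sum(k_diff * pxy_diff))
    difference_variance = float(np.sum((k_diff - mu_diff) ** 2 * pxy_diff))
    difference_entropy = float(-np.sum(_xlog2x(pxy_diff)))

    # information measures of correlation
    outer = np.outer(px, py)
    nz = (p > 0) & (outer > 0)
    hxy1 = float(-np.sum(p[nz] * np.log2(outer[nz])))
    nz2 = outer > 0
    hxy2 = float(-np.sum(outer[nz2] * np.log2(outer[nz2])))
    hx = float(-np.sum(_xlog2x(px)))
    hy = float(-np.sum(_xlog2x(py)))
    denom = max(hx, hy)
    imc1 = float((entropy - hxy1) / denom) if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    mcc = _maximal_correlation_coefficient(p, px, py)

    vals = (
        asm,
        contrast,
        correlation,
        sum_of_squares,
        idm,
        sum_average,
        sum_variance,
        sum_entropy,
        entropy,
        difference_variance,
        difference_entropy,
        imc1,
        imc2,
        mcc,
    )
    return dict(zip(HARALICK_NAMES, vals))


def _maximal_correlation_coefficient(p, px, py) -> float:
    """sqrt of the second-largest eigenvalue of the Haralick Q matrix."""
    active = (px > 0) & (py > 0)
    if active.sum() < 2:
        return 1.0  # single active level: perfectly concentrated matrix
    pa = p[np.ix_(active, active)]
    pxa = px[active]
    pya = py[active]
    q = (pa / pxa[:, None]) @ (pa / pya[:, None]).T
    ev = np.linalg.eigvals(q)
    ev = np.sort(np.real(ev))[::-1]
    second = float(np.clip(ev[1], 0.0, 1.0))
    return float(np.sqrt(second))


def _shift_read(arr, offset, fill):
    """out[x] = arr[x + offset], with ``fill`` outside the array."""
    out = np.full(arr.shape, fill, dtype=arr.dtype)
    src, dst = _shifted_slices(arr.shape, offset)
    out[src] = arr[dst]
    return out


def compute_glrlm(roi: QuantizedROI, directions=DIRECTIONS_3D_13) -> GLRLM:
    """Run-length counts of maximal equal-level runs along each direction.

    Runs are truncated at the mask boundary; every in-mask voxel belongs
    to exactly one run per direction, so ``sum_ij j * counts[i, j]``
    equals the in-mask voxel count times the number of directions.
    """
    if not roi.mask.any():
        raise ValueError("empty mask")
    lv = roi.levels
    in_mask = lv >= 0
    n_voxels = int(in_mask.sum())
    max_run = int(max(lv.shape))
    counts = np.zeros(roi.n_levels * max_run, dtype=np.int64)

    for d in directions:
        nxt = _shift_read(lv, d, -1)
        same_next = in_mask & (nxt == lv) & (nxt >= 0)
        # forward run length by pointer doubling
        run = np.ones(lv.shape, dtype=np.int32)
        cont = same_next.copy()
        m = 1
        while cont.any() and m < max_run:
            step = tuple(m * c for c in d)
            run = run + np.where(cont, _shift_read(run, step, 0), 0)
            cont &= _shift_read(cont, step, False)
            m *= 2
        prev_same = _shift_read(same_next, tuple(-c for c in d), False)
        starts = in_mask & ~prev_same
        lv_s = lv[starts]
        run_s = run[starts] - 1  # 0-based run-length bin
        counts += np.bincount(
            lv_s * max_run + run_s, minlength=roi.n_levels * max_run
        )

    return GLRLM(
        counts=counts.reshape(roi.n_levels, max_run),
        directions=tuple(directions),
        n_voxels=n_voxels,
    )


def glrlm_features(glrlm: GLRLM, n_voxels: int | None = None) -> dict[str, float]:
    """The 11 standard run-length statistics.

    Run percentage divides the run count by (in-mask voxels x number of
    directions), so an ROI of all length-1 runs has RP = 1.
    """
    m = glrlm.counts.astype(np.float64)
    nr = m.sum()
    if nr <= 0:
        raise ValueError("GLRLM has no runs")
    if n_voxels is None:
        n_voxels = glrlm.n_voxels
    n_levels, max_run = m.shape
    g = np.arange(1, n_levels + 1, dtype=np.float64)[:, None]  # gray index from 1
    j = np.arange(1, max_run + 1, dtype=np.float64)[None, :]

    row = m.sum(axis=1)
    col = m.sum(axis=0)
    vals = {
        "sre": np.sum(m / j**2) / nr,
        "lre": np.sum(m * j**2) / nr,
        "gln": np.sum(row**2) / nr,
        "rln": np.sum(col**2) / nr,
        "rp": nr / (n_voxels * len(glrlm.directions)),
        "lgre": np.sum(m / g**2) / nr,
        "hgre": np.sum(m * g**2) / nr,
        "srlge": np.sum(m / (g**2 * j**2)) / nr,
        "srhge": np.sum(m * g**2 / j**2) / nr,
        "lrlge": np.sum(m * j**2 / g**2) / nr,
        "lrhge": np.sum(m * g**2 * j**2) / nr,
    }
    return {k: float(v) for k, v in vals.items()}
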