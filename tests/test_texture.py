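"""Texture statistics against brute-force oracles and hand computations."""

from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bmradiomics import (
    DIRECTIONS_3D_13,
    LesionVolume,
    compute_glcm,
    compute_glrlm,
    first_order_features,
    glrlm_features,
    haralick_features,
    quantize,
)
from bmradiomics.texture import GLCM, GLRLM


def vol_from(levels, mask=None, spacing=(1, 1, 1)):
    arr = np.asarray(levels, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, None, :]
    m = np.ones(arr.shape, bool) if mask is None else np.asarray(mask, bool)
    if m.ndim == 1:
        m = m[None, None, :]
    return LesionVolume(arr, m, spacing)


# ---------------------------------------------------------------------------
# independent oracles


def brute_glcm(levels, mask, offsets, n_levels=None):
    """Triple-loop symmetric pair counting."""
    n = n_levels if n_levels is not None else int(levels.max()) + 1
    counts = np.zeros((n, n), dtype=int)
    shape = levels.shape
    for z, y, x in product(*(range(s) for s in shape)):
        if not mask[z, y, x]:
            continue
        for dz, dy, dx in offsets:
            z2, y2, x2 = z + dz, y + dy, x + dx
            if 0 <= z2 < shape[0] and 0 <= y2 < shape[1] and 0 <= x2 < shape[2]:
                if mask[z2, y2, x2]:
                    a, b = levels[z, y, x], levels[z2, y2, x2]
                    counts[a, b] += 1
                    counts[b, a] += 1
    return counts


def brute_glrlm(levels, mask, directions, max_run):
    """Walk every line in every direction, splitting runs by hand."""
    n = int(levels.max()) + 1
    counts = np.zeros((n, max_run), dtype=int)
    shape = levels.shape

    def in_bounds(p):
        return all(0 <= c < s for c, s in zip(p, shape))

    for d in directions:
        starts = []
        for p in product(*(range(s) for s in shape)):
            prev = tuple(c - dc for c, dc in zip(p, d))
            if not mask[p]:
                continue
            prev_same = (
                in_bounds(prev) and mask[prev] and levels[prev] == levels[p]
            )
            if not prev_same:
                starts.append(p)
        for p in starts:
            run = 1
            cur = p
            while True:
                nxt = tuple(c + dc for c, dc in zip(cur, d))
                if in_bounds(nxt) and mask[nxt] and levels[nxt] == levels[p]:
                    run += 1
                    cur = nxt
                else:
                    break
            counts[levels[p], run - 1] += 1
    return counts


def _random_rois(n_rois=12, seed=0):
    """Small random ROIs (<= 5x5x5, random masks) as a fixed fixture set."""
    rng = np.random.default_rng(seed)
    rois = []
    for _ in range(n_rois):
        shape = tuple(rng.integers(1, 6, size=3))
        levels = rng.integers(0, 4, size=shape)
        mask = rng.random(shape) < 0.8
        if not mask.any():
            mask.flat[0] = True
        rois.append((levels.astype(np.int32), mask))
    return rois


# ---------------------------------------------------------------------------
# quantization


class TestQuantize:
    def test_identity_mapping_when_levels_match(self):
        v = vol_from(np.arange(32))
        q = quantize(v, 32)
        assert np.array_equal(q.levels[0, 0], np.arange(32))

    def test_constant_roi_maps_to_zero(self):
        v = vol_from(np.full(10, 3.0))
        assert np.all(quantize(v, 8).levels[0, 0] == 0)

    def test_two_values_two_levels(self):
        v = vol_from([0.0, 10.0, 0.0, 10.0])
        assert np.array_equal(quantize(v, 2).levels[0, 0], [0, 1, 0, 1])

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError):
            quantize(vol_from([1.0, 2.0]), 1)

    @given(st.integers(2, 16), st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_levels_bounded_and_extremes_hit(self, n_levels, seed):
        rng = np.random.default_rng(seed)
        v = vol_from(rng.normal(size=30))
        q = quantize(v, n_levels)
        in_mask = q.levels[q.mask]
        assert in_mask.min() == 0
        assert in_mask.max() == n_levels - 1 or np.ptp(v.masked_values()) == 0


# ---------------------------------------------------------------------------
# first order


class TestFirstOrder:
    def test_constant_roi_conventions(self):
        f = first_order_features(vol_from(np.full(20, 2.0)))
        assert f["variance"] == 0 and f["skewness"] == 0 and f["kurtosis"] == 0
        assert f["energy"] == 1.0 and f["entropy"] == 0.0

    def test_uniform_histogram_entropy(self):
        # one value per bin: entropy log2(64) = 6 bits, energy 1/64
        vals = np.arange(64) + 0.5
        f = first_order_features(vol_from(vals), n_bins=64)
        assert abs(f["entropy"] - 6.0) < 1e-12
        assert abs(f["energy"] - 1 / 64) < 1e-12

    def test_hand_computed_moments(self):
        f = first_order_features(vol_from([1.0, 2.0, 3.0, 4.0]))
        assert f["mean"] == 2.5
        assert f["variance"] == 1.25

    def test_empty_mask_rejected(self):
        v = vol_from(np.ones(5))
        v2 = LesionVolume(v.intensities, v.mask, (1, 1, 1))
        v2.mask = v2.mask.copy()
        v2.mask[..., 1:] = False
        with pytest.raises(ValueError):
            first_order_features(v2)


# ---------------------------------------------------------------------------
# GLCM


class TestGLCM:
    def test_constant_2x2_single_offset(self):
        v = vol_from(np.zeros((1, 2, 2)))
        g = compute_glcm(quantize(v, 2), offsets=[(0, 1, 0)])
        assert g.counts[0, 0] == 4  # 2 pairs x 2 orderings
        assert g.counts.sum() == 4

    def test_alternating_line(self):
        v = vol_from([0.0, 1.0, 0.0, 1.0])
        g = compute_glcm(quantize(v, 2), offsets=[(0, 0, 1)])
        assert g.counts[0, 1] == 3 and g.counts[1, 0] == 3
        assert g.counts[0, 0] == 0 and g.counts[1, 1] == 0

    def test_no_valid_pairs_rejected(self):
        mask = np.zeros((1, 1, 3), bool)
        mask[0, 0, 0] = mask[0, 0, 2] = True  # no adjacent in-mask pair
        v = vol_from([1.0, 2.0, 3.0], mask=mask[0, 0])
        with pytest.raises(ValueError, match="pair"):
            compute_glcm(quantize(v, 2), offsets=[(0, 0, 1)])

    def test_matches_brute_force_on_small_rois(self):
        for levels, mask in _random_rois():
            v = vol_from(levels.astype(float), mask=mask)
            n_lv = int(levels[mask].max()) + 1 if levels[mask].size else 2
            n_lv = max(n_lv, 2)
            q = quantize(v, n_lv)
            try:
                g = compute_glcm(q, DIRECTIONS_3D_13)
            except ValueError:
                continue  # isolated voxels: oracle would count zero pairs too
            oracle = brute_glcm(q.levels, mask, DIRECTIONS_3D_13, n_levels=q.n_levels)
            assert np.array_equal(g.counts, oracle)

    def test_symmetry_and_conservation(self):
        rng = np.random.default_rng(5)
        v = vol_from(rng.normal(size=(4, 4, 4)))
        g = compute_glcm(quantize(v, 5), DIRECTIONS_3D_13)
        assert np.array_equal(g.counts, g.counts.T)
        oracle = brute_glcm(quantize(v, 5).levels, v.mask, DIRECTIONS_3D_13, n_levels=5)
        assert g.counts.sum() == oracle.sum()


class TestHaralick:
    def test_single_cell_delta(self):
        g = GLCM(counts=np.array([[8, 0], [0, 0]]), offsets=((0, 0, 1),))
        h = haralick_features(g)
        assert h["asm"] == 1.0
        assert h["contrast"] == 0.0
        assert h["entropy"] == 0.0
        assert h["idm"] == 1.0
        assert h["correlation"] == 0.0  # zero marginal SD convention

    def test_hand_computed_uniform_2x2(self):
        g = GLCM(counts=np.full((2, 2), 25), offsets=((0, 0, 1),))
        h = haralick_features(g)
        assert abs(h["contrast"] - 0.5) < 1e-9
        assert abs(h["entropy"] - 2.0) < 1e-9
        assert abs(h["asm"] - 0.25) < 1e-9
        # p_{x+y} = (1/4, 1/2, 1/4): sum average 1, sum entropy 1.5 bits
        assert abs(h["sum_average"] - 1.0) < 1e-9
        assert abs(h["sum_entropy"] - 1.5) < 1e-9
        # independent marginals: correlation and IMC both 0
        assert abs(h["correlation"]) < 1e-9
        assert abs(h["imc1"]) < 1e-9

    def test_bounds_on_random_matrices(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            c = rng.integers(0, 30, size=(6, 6))
            c = c + c.T
            if c.sum() == 0:
                continue
            h = haralick_features(GLCM(counts=c, offsets=((0, 0, 1),)))
            assert 0 < h["asm"] <= 1
            assert h["entropy"] >= 0
            assert 0 <= h["imc2"] <= 1
            assert 0 <= h["mcc"] <= 1 + 1e-9


# ---------------------------------------------------------------------------
# GLRLM


class TestGLRLM:
    def test_two_runs_by_definition(self):
        v = vol_from([1.0, 1.0, 2.0, 2.0, 2.0])
        q = quantize(v, 2)
        g = compute_glrlm(q, directions=[(0, 0, 1)])
        assert g.counts[0, 1] == 1  # level 0 (value 1), run length 2
        assert g.counts[1, 2] == 1  # level 1 (value 2), run length 3
        assert g.counts.sum() == 2

    def test_constant_line_single_run(self):
        v = vol_from(np.full(7, 3.0))
        g = compute_glrlm(quantize(v, 4), directions=[(0, 0, 1)])
        assert g.counts[0, 6] == 1
        assert g.counts.sum() == 1

    def test_run_voxel_conservation(self):
        rng = np.random.default_rng(8)
        v = vol_from(rng.integers(0, 3, size=(4, 5, 3)).astype(float))
        g = compute_glrlm(quantize(v, 3), DIRECTIONS_3D_13)
        j = np.arange(1, g.counts.shape[1] + 1)
        assert (g.counts * j).sum() == v.mask.sum() * len(DIRECTIONS_3D_13)

    def test_matches_brute_force_on_small_rois(self):
        for levels, mask in _random_rois(seed=1):
            v = vol_from(levels.astype(float), mask=mask)
            n_lv = max(int(levels[mask].max()) + 1, 2)
            q = quantize(v, n_lv)
            g = compute_glrlm(q, DIRECTIONS_3D_13)
            oracle = brute_glrlm(q.levels, mask, DIRECTIONS_3D_13, g.counts.shape[1])
            assert np.array_equal(g.counts[: oracle.shape[0]], oracle)


class TestGLRLMFeatures:
    def test_all_unit_runs(self):
        counts = np.zeros((3, 4), dtype=int)
        counts[:, 0] = [2, 3, 1]  # six runs, all length 1
        g = GLRLM(counts=counts, directions=((0, 0, 1),), n_voxels=6)
        f = glrlm_features(g)
        assert f["sre"] == 1.0 and f["lre"] == 1.0 and f["rp"] == 1.0

    def test_single_run_of_two(self):
        counts = np.zeros((1, 2), dtype=int)
        counts[0, 1] = 1
        g = GLRLM(counts=counts, directions=((0, 0, 1),), n_voxels=2)
        f = glrlm_features(g)
        assert f["rp"] == 0.5
        assert f["sre"] == 0.25
        assert f["lre"] == 4.0

    def test_bounds(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 5, size=(4, 6))
        counts[0, 0] += 1
        g = GLRLM(counts=counts, directions=((0, 0, 1),), n_voxels=int((counts * np.arange(1, 7)).sum()))
        f = glrlm_features(g)
        assert f["sre"] <= 1.0 + 1e-12
        assert f["rp"] <= 1.0 + 1e-12


def test_axial_rotation_invariance_of_direction_averaged_features():
    """90-degree rotation about the axial axis: the 13-direction sets are
    closed under it (up to antipodes), so GLCM/GLRLM features are unchanged."""
    rng = np.random.default_rng(11)
    cube = rng.integers(0, 5, size=(6, 6, 6)).astype(float)
    rotated = np.rot90(cube, k=1, axes=(1, 2)).copy()
    feats = []
    for arr in (cube, rotated):
        v = vol_from(arr)
        q = quantize(v, 5)
        h = haralick_features(compute_glcm(q, DIRECTIONS_3D_13))
        rl = glrlm_features(compute_glrlm(q, DIRECTIONS_3D_13))
        feats.append({**h, **rl})
    for key in feats[0]:
        assert np.isclose(feats[0][key], feats[1][key], atol=1e-12), key
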