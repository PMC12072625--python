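"""Segmentation stage: uniformization, local contrast, thresholding,
clustering (with a union-find oracle), diameter, and region assignment."""

import math

import numpy as np
import pytest

from pvsmap import (PVSCluster, SegmentationConfig, VolumeGrid, assign_region,
                    cluster, local_contrast, measure_diameter, segment,
                    uniformize)

SP = (0.8, 0.8, 4.4)


def vol(arr, spacing=SP):
    return VolumeGrid(np.asarray(arr, dtype=float), spacing)


def ones_mask(shape, spacing=SP):
    return VolumeGrid(np.ones(shape, dtype=np.uint8), spacing)


# -- uniformize ---------------------------------------------------------------

def test_uniformize_is_identity_on_flat_image():
    v = vol(np.full((20, 20, 6), 42.0))
    out = uniformize(v, ones_mask(v.shape))
    assert np.allclose(out.values, 42.0, rtol=1e-6)


def test_uniformize_removes_analytic_bias_within_2pct():
    shape = (64, 64, 16)
    ax = [np.linspace(0, 1, n) for n in shape]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    bias = 1 + 0.05 * np.sin(np.pi * gx) * np.cos(np.pi * gy) * np.cos(
        0.5 * np.pi * gz)
    out = uniformize(vol(100.0 * bias), ones_mask(shape))
    assert np.all(np.abs(out.values - 100.0) / 100.0 < 0.02)


def test_uniformize_preserves_masked_median():
    rng = np.random.default_rng(0)
    v = vol(100 + rng.normal(0, 5, size=(24, 24, 8)))
    m = ones_mask(v.shape)
    out = uniformize(v, m)
    assert np.median(out.values) == pytest.approx(np.median(v.values), rel=1e-9)


def test_uniformize_empty_mask_raises():
    v = vol(np.ones((8, 8, 4)))
    with pytest.raises(ValueError, match="mask"):
        uniformize(v, VolumeGrid(np.zeros((8, 8, 4), dtype=np.uint8), SP))


def test_uniformize_off_is_passthrough():
    rng = np.random.default_rng(2)
    v = vol(100 + rng.normal(0, 1, (16, 16, 6)))
    wm = ones_mask(v.shape)
    bg = VolumeGrid(np.zeros(v.shape, dtype=np.uint8), SP)
    cfg_off = SegmentationConfig(uniformize=False)
    cfg_on = SegmentationConfig(uniformize=True)
    # with a flat field the two agree; passthrough means contrast is computed
    # on the raw image
    m_off = segment(v, wm, bg, cfg_off)
    m_on = segment(v, wm, bg, cfg_on)
    assert np.array_equal(m_off.values, m_on.values)


# -- local_contrast -----------------------------------------------------------

def test_constant_image_has_zero_contrast():
    v = vol(np.full((10, 10, 5), 100.0))
    out = local_contrast(v, ones_mask(v.shape))
    assert np.allclose(out.values, 0.0)


def test_single_bright_voxel_26_neighbor_mean():
    """A 160 voxel in a 100 background: difference is 160 - mean(26 x 100) = 60."""
    arr = np.full((7, 7, 7), 100.0)
    arr[3, 3, 3] = 160.0
    out = local_contrast(vol(arr), ones_mask(arr.shape))
    assert out.values[3, 3, 3] == pytest.approx(60.0)
    # neighbors of the bright voxel are dimmer than their surroundings
    assert out.values[3, 3, 2] < 0


def test_dim_voxel_gets_negative_contrast_and_is_never_segmented():
    arr = np.full((7, 7, 7), 100.0)
    arr[3, 3, 3] = 20.0
    wm = ones_mask(arr.shape)
    bg = VolumeGrid(np.zeros(arr.shape, dtype=np.uint8), SP)
    out = local_contrast(vol(arr), wm)
    assert out.values[3, 3, 3] < 0
    mask = segment(vol(arr), wm, bg, SegmentationConfig(uniformize=False))
    assert mask.values[3, 3, 3] == 0


def test_border_neighborhood_is_truncated():
    arr = np.full((5, 5, 5), 100.0)
    arr[0, 0, 0] = 107.0
    out = local_contrast(vol(arr), ones_mask(arr.shape))
    # corner voxel has exactly 7 in-volume neighbors
    assert out.values[0, 0, 0] == pytest.approx(7.0)


def test_inplane_kernel_uses_8_neighbors():
    arr = np.full((7, 7, 3), 100.0)
    arr[3, 3, 1] = 108.0
    out = local_contrast(vol(arr), ones_mask(arr.shape), kernel="inplane8")
    assert out.values[3, 3, 1] == pytest.approx(8.0)


def test_contrast_zero_outside_mask():
    arr = np.full((6, 6, 3), 100.0)
    arr[2, 2, 1] = 200.0
    m = np.zeros_like(arr, dtype=np.uint8)
    m[4:, :, :] = 1
    out = local_contrast(vol(arr), VolumeGrid(m, SP))
    assert out.values[2, 2, 1] == 0.0


# -- segment ------------------------------------------------------------------

def _one_voxel_image(delta):
    """Interior voxel elevated so its 26-neighbour contrast is exactly delta."""
    arr = np.full((7, 7, 7), 100.0)
    arr[3, 3, 3] = 100.0 + delta
    wm = ones_mask(arr.shape)
    bg = VolumeGrid(np.zeros(arr.shape, dtype=np.uint8), SP)
    return vol(arr), wm, bg


def test_threshold_is_strict():
    v, wm, bg = _one_voxel_image(60.0)
    cfg = SegmentationConfig(uniformize=False)
    assert segment(v, wm, bg, cfg).values.sum() == 0
    v, wm, bg = _one_voxel_image(60.0 + 1e-6)
    assert segment(v, wm, bg, cfg).values.sum() == 1


def test_raising_threshold_never_adds_voxels(rng):
    arr = 100 + rng.normal(0, 40, size=(20, 20, 8))
    wm = ones_mask(arr.shape)
    bg = VolumeGrid(np.zeros(arr.shape, dtype=np.uint8), SP)
    prev = None
    for thr in (10, 30, 60, 90, 150):
        m = segment(vol(arr), wm, bg,
                    SegmentationConfig(diff_threshold=thr, uniformize=False))
        n = int(m.values.sum())
        if prev is not None:
            assert n <= prev
        prev = n


def test_shape_mismatch_raises():
    v = vol(np.ones((6, 6, 3)))
    wm = ones_mask((6, 6, 4))
    bg = VolumeGrid(np.zeros((6, 6, 3), dtype=np.uint8), SP)
    with pytest.raises(ValueError, match="mismatch"):
        segment(v, wm, bg)


def test_noiseless_phantom_recovery(small_phantom):
    ph = small_phantom
    mask = segment(ph.t2_like, ph.wm_mask, ph.bg_mask, SegmentationConfig())
    comps = cluster(mask)
    assert len(comps) == len(ph.truth)
    detected_sets = {c.voxel_set for c in comps}
    assert detected_sets == {t.voxel_set for t in ph.truth}


# -- cluster (26-connectivity) ------------------------------------------------

def _mask_from_voxels(voxels, shape):
    m = np.zeros(shape, dtype=np.uint8)
    for v in voxels:
        m[v] = 1
    return VolumeGrid(m, SP)


def test_corner_contact_is_one_cluster():
    m = _mask_from_voxels([(0, 0, 0), (1, 1, 1)], (3, 3, 3))
    comps = cluster(m)
    assert len(comps) == 1 and comps[0].volume_voxels == 2


def test_gap_of_one_voxel_separates_clusters():
    m = _mask_from_voxels([(0, 0, 0), (2, 0, 0)], (4, 3, 3))
    assert len(cluster(m)) == 2


def test_empty_mask_gives_no_clusters():
    assert cluster(_mask_from_voxels([], (4, 4, 4))) == []


def _union_find_components(voxels):
    """Independent oracle: union-find over all 26-neighbour pairs."""
    parent = {v: v for v in voxels}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    vox = list(voxels)
    for i, a in enumerate(vox):
        for b in vox[i + 1:]:
            if max(abs(a[0] - b[0]), abs(a[1] - b[1]), abs(a[2] - b[2])) == 1:
                union(a, b)
    comps = {}
    for v in vox:
        comps.setdefault(find(v), set()).add(v)
    return {frozenset(c) for c in comps.values()}


@pytest.mark.parametrize("seed", range(20))
def test_cluster_matches_union_find_oracle(seed):
    rng = np.random.default_rng(seed)
    shape = (8, 8, 6)
    density = rng.uniform(0.05, 0.4)
    m = rng.random(shape) < density
    voxels = set(map(tuple, np.argwhere(m).tolist()))
    got = {c.voxel_set for c in cluster(VolumeGrid(m.astype(np.uint8), SP))}
    assert got == _union_find_components(voxels)


# -- measure_diameter ---------------------------------------------------------

def test_single_voxel_diameter_closed_form():
    c = PVSCluster(voxels=[(3, 3, 1)])
    d = measure_diameter(c, SP)
    assert d == pytest.approx(2 * math.sqrt(0.8 * 0.8 / math.pi))
    assert d == pytest.approx(0.9027, abs=2e-4)


def test_four_voxel_square_doubles_single_voxel_diameter():
    single = measure_diameter(PVSCluster(voxels=[(0, 0, 0)]), SP)
    square = PVSCluster(voxels=[(0, 0, 0), (0, 1, 0), (1, 0, 0), (1, 1, 0)])
    assert measure_diameter(square, SP) == pytest.approx(2 * single)


def test_diameter_is_max_over_slices():
    c = PVSCluster(voxels=[(5, 5, 0), (5, 5, 1), (5, 6, 1), (6, 5, 1)])
    three = measure_diameter(PVSCluster(voxels=[(0, 0, 0), (0, 1, 0), (1, 0, 0)]), SP)
    assert measure_diameter(c, SP) == pytest.approx(three)


def test_diameter_invariant_to_inplane_translation_and_rotation():
    base = [(2, 3, 1), (3, 3, 1), (3, 4, 1), (4, 4, 1)]
    c = PVSCluster(voxels=base)
    shifted = PVSCluster(voxels=[(i + 7, j + 2, k) for i, j, k in base])
    rotated = PVSCluster(voxels=[(j, 10 - i, k) for i, j, k in base])  # 90 deg
    d = measure_diameter(c, SP)
    assert measure_diameter(shifted, SP) == pytest.approx(d)
    assert measure_diameter(rotated, SP) == pytest.approx(d)


# -- assign_region ------------------------------------------------------------

def _label_vol(arr):
    return VolumeGrid(np.asarray(arr, dtype=np.int32), SP)


def test_region_assignment_majority_tie_and_background():
    labels = np.zeros((4, 4, 1), dtype=np.int32)
    labels[0:2, :, 0] = 5
    labels[2:4, :, 0] = 6
    lm = _label_vol(labels)
    inside = PVSCluster(voxels=[(0, 0, 0), (0, 1, 0)])
    assert assign_region(inside, lm) == 5
    majority = PVSCluster(voxels=[(0, 0, 0), (1, 0, 0), (1, 1, 0), (2, 0, 0)])
    assert assign_region(majority, lm) == 5
    tie = PVSCluster(voxels=[(1, 0, 0), (1, 1, 0), (2, 0, 0), (2, 1, 0)])
    assert assign_region(tie, lm) == 5  # tie breaks to the smaller id
    bg = PVSCluster(voxels=[(0, 0, 0)])
    assert assign_region(bg, _label_vol(np.zeros((2, 2, 1)))) == 0
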