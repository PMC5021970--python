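"""Pixel rules, Otsu, connected components, size filters and gating."""

import numpy as np
import pytest

from mitoganglia.io import ImageStack, VoxelGeometry
from mitoganglia.segmentation import (
    MitoComponent,
    SegmentationSettings,
    filter_components,
    gate_by_ganglion,
    illumination_correct,
    label_components,
    local_rule_mask,
    mito_pixel_mask,
    otsu_from_histogram,
    otsu_threshold,
)

GEOM = VoxelGeometry(0.1, 0.1, 0.18)


def stack16(voxels):
    return ImageStack(np.asarray(voxels, np.uint16), 16, GEOM)


# --- independent 2D filter oracles (replicate padding, explicit kernels) ---

def gaussian_kernel_5x5(sigma=2.0):
    x = np.arange(-2, 3, dtype=float)
    k1 = np.exp(-(x**2) / (2 * sigma**2))
    k1 /= k1.sum()
    return np.outer(k1, k1)


def conv2d_replicate(img, kernel, origin_offset=(0, 0)):
    """Direct 2D correlation with edge-replicate padding.

    ``origin_offset`` shifts the window for even-sized kernels: scipy's
    size-n uniform filter spans offsets [-n//2, n - n//2 - 1].
    """
    kh, kw = kernel.shape
    oy, ox = origin_offset
    top, left = kh // 2 - oy, kw // 2 - ox
    bottom, right = kh - 1 - top, kw - 1 - left
    padded = np.pad(np.asarray(img, float), ((top, bottom), (left, right)), mode="edge")
    out = np.zeros_like(np.asarray(img, float))
    H, W = out.shape
    for dy in range(kh):
        for dx in range(kw):
            out += kernel[dy, dx] * padded[dy : dy + H, dx : dx + W]
    return out


def boxmean_oracle(img, size):
    return conv2d_replicate(img, np.full((size, size), 1.0 / size**2))


class TestLocalRule:
    def test_flat_image_has_no_local_contrast(self):
        assert not local_rule_mask(stack16(np.full((2, 32, 32), 500))).any()
        assert not local_rule_mask(stack16(np.zeros((2, 32, 32)))).any()

    def test_bright_square_matches_convolution_oracle(self):
        img = np.zeros((40, 40))
        img[18:21, 18:21] = 1000
        smooth = conv2d_replicate(img, gaussian_kernel_5x5())
        background = boxmean_oracle(img, 10)
        expected = (smooth >= 1.25 * background) & (smooth > 0)
        mask = local_rule_mask(stack16(img[None]))
        assert np.array_equal(mask[0], expected)
        assert expected.any()  # the oracle itself finds the bright spot

    def test_small_stack_warns_but_computes(self):
        with pytest.warns(UserWarning):
            local_rule_mask(stack16(np.ones((1, 6, 6))))


class TestIlluminationCorrect:
    def test_constant_stack_goes_to_zero(self):
        out = illumination_correct(stack16(np.full((3, 50, 50), 777)))
        assert np.allclose(out, 0)

    def test_planar_ramp_interior_flattened(self):
        nx = 64
        ramp = np.tile(np.arange(nx, dtype=float) * 3, (nx, 1))
        out = illumination_correct(stack16(ramp[None]))
        oracle = np.clip(ramp - boxmean_oracle(ramp, 20), 0, None)
        assert np.allclose(out[0], oracle)
        # interior residual is below one ramp step (edge band excluded)
        assert out[0, 30, 15:-15].max() <= 3.0

    def test_single_bright_voxel_box_arithmetic(self):
        img = np.zeros((64, 64))
        img[32, 32] = 4000
        out = illumination_correct(stack16(img[None]))
        assert out[0, 32, 32] == pytest.approx(4000 - 4000 / 400)


def otsu_oracle_index(counts, centers):
    """Exhaustive between-class-variance maximizer (plain Python loop)."""
    counts = [float(c) for c in counts]
    total = sum(counts)
    best, best_idx = -1.0, None
    for t in range(len(counts)):
        w0 = sum(counts[: t + 1])
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = sum(c * x for c, x in zip(counts[: t + 1], centers[: t + 1])) / w0
        mu1 = sum(c * x for c, x in zip(counts[t + 1 :], centers[t + 1 :])) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
        if sigma_b > best:
            best, best_idx = sigma_b, t
    return best_idx


class TestOtsu:
    def test_two_point_masses(self):
        data = np.concatenate([np.full(1000, 10.0), np.full(1000, 200.0)])
        thr, mask = otsu_threshold(data.reshape(2, 10, 100))
        assert 10 < thr < 200
        assert mask.sum() == 1000

    def test_constant_stack_rejected(self):
        with pytest.raises(ValueError):
            otsu_threshold(np.full((2, 4, 4), 7.0))

    def test_matches_exhaustive_oracle_on_random_histograms(self, rng):
        for _ in range(200):
            n_bins = int(rng.integers(8, 128))
            counts = rng.poisson(40, n_bins)
            centers = np.arange(n_bins, dtype=float)
            assert otsu_from_histogram(counts, centers) == otsu_oracle_index(
                counts, centers
            )

    def test_skimage_cross_check(self, rng):
        # independent reference implementation on the same histogram grid
        from skimage.filters import threshold_otsu

        data = np.concatenate([rng.normal(20, 4, 4000), rng.normal(90, 10, 1000)])
        data = np.clip(data, 0, None).reshape(5, 10, 100)
        thr, _ = otsu_threshold(data, n_bins=256)
        ref = threshold_otsu(data.ravel(), nbins=256)
        assert abs(thr - ref) <= (data.max() - data.min()) / 256


class TestMitoPixelMask:
    def test_conjunction_is_subset_of_both_rules(self, rng):
        vox = rng.integers(0, 1000, size=(4, 32, 32))
        vox[1, 10:14, 10:14] = 60000
        s = stack16(vox)
        mask = mito_pixel_mask(s)
        local = local_rule_mask(s)
        _, global_mask = otsu_threshold(illumination_correct(s))
        assert not (mask & ~local).any()
        assert not (mask & ~global_mask).any()
        assert np.array_equal(mask, local & global_mask)


def flood_fill_count(mask, connectivity):
    """Brute-force component count by BFS flood fill."""
    offsets = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) == (0, 0, 0):
                    continue
                order = abs(dz) + abs(dy) + abs(dx)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dz, dy, dx))
    todo = {tuple(c) for c in np.argwhere(mask)}
    n = 0
    while todo:
        n += 1
        stack = [todo.pop()]
        while stack:
            z, y, x = stack.pop()
            for dz, dy, dx in offsets:
                w = (z + dz, y + dy, x + dx)
                if w in todo:
                    todo.remove(w)
                    stack.append(w)
    return n


class TestComponents:
    def test_corner_sharing_voxels_connectivity(self):
        mask = np.zeros((2, 2, 2), bool)
        mask[0, 0, 0] = mask[1, 1, 1] = True
        assert len(label_components(mask, 26)) == 1
        assert len(label_components(mask, 6)) == 2

    def test_empty_mask(self):
        assert label_components(np.zeros((2, 2, 2), bool)) == []

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_random_sparse_mask_matches_flood_fill(self, rng, connectivity):
        mask = rng.random((6, 14, 14)) < 0.12
        comps = label_components(mask, connectivity)
        assert len(comps) == flood_fill_count(mask, connectivity)
        assert sum(c.voxel_count for c in comps) == mask.sum()

    def test_size_filter_boundaries(self):
        def comp(n):
            # worm along a virtual axis; only the count matters for filtering
            coords = np.stack([np.zeros(n, int), np.zeros(n, int), np.arange(n)], axis=1)
            return MitoComponent(1, coords)

        kept = filter_components([comp(7), comp(8)])
        assert [c.voxel_count for c in kept] == [8]
        kept = filter_components([comp(10**6), comp(10**6 + 1)])
        assert [c.voxel_count for c in kept] == [10**6]


class TestGating:
    def test_intersection_rule(self):
        inside = MitoComponent(1, np.array([[0, 0, 0], [0, 0, 1]]))
        touching = MitoComponent(2, np.array([[0, 1, 0], [0, 2, 0]]))
        outside = MitoComponent(3, np.array([[0, 3, 3]]))
        ganglion = np.zeros((1, 4, 4), bool)
        ganglion[0, :2, :2] = True
        kept = gate_by_ganglion([inside, touching, outside], ganglion)
        assert [c.id for c in kept] == [1, 2]
        assert kept[1].voxel_count == 2  # kept whole, not clipped

    def test_full_grid_is_identity_and_empty_rejected(self):
        comps = [MitoComponent(1, np.array([[0, 0, 0]]))]
        assert gate_by_ganglion(comps, np.ones((1, 2, 2), bool)) == comps
        with pytest.raises(ValueError):
            gate_by_ganglion(comps, np.zeros((1, 2, 2), bool))

    def test_filter_and_gate_commute(self, rng):
        mask = rng.random((5, 20, 20)) < 0.25
        ganglion = np.zeros((5, 20, 20), bool)
        ganglion[:, 5:15, 5:15] = True
        comps = label_components(mask)
        a = gate_by_ganglion(filter_components(comps, 3, 50), ganglion)
        b = filter_components(gate_by_ganglion(comps, ganglion), 3, 50)
        assert [c.id for c in a] == [c.id for c in b]
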