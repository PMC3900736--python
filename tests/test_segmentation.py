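"""Segmentation chain: projections, smoothing, symmetry detector, seeds,
foreground mask, watershed. Oracles are direct per-pixel computations."""

import numpy as np
import pytest
from scipy import ndimage

from symquant.io import ImageStack
from symquant.scenes import SceneSpec, render_scene
from symquant.segmentation import (Projection, SymmetryMap,
                                   detect_seeds, foreground_mask,
                                   project_stack, segment, segment_pipeline,
                                   smooth, symmetry_map, _symmetry_basis)

NOISELESS = dict(noise_model="none", background_level=0.0, cell_cv=0.0)


def _stack(arr):
    return ImageStack(pixels=arr, class_label="A", experiment_id="E1")


def _blob(shape, center, sigma, amp=100.0):
    r = np.arange(shape[0])[:, None] - center[0]
    c = np.arange(shape[1])[None, :] - center[1]
    return amp * np.exp(-(r ** 2 + c ** 2) / (2 * sigma ** 2))


class TestProjection:
    def test_sum_of_constant_layers(self):
        p = project_stack(_stack(np.ones((2, 8, 8))), "sum")
        assert np.all(p.image == 2.0)

    def test_single_layer_identity(self, rng):
        arr = rng.random((1, 9, 9))
        assert np.array_equal(project_stack(_stack(arr)).image, arr[0])

    def test_sum_matches_elementwise_oracle(self, rng):
        arr = rng.random((3, 12, 12))
        p = project_stack(_stack(arr), "sum")
        oracle = np.zeros((12, 12))
        for layer in arr:
            oracle += layer
        assert np.allclose(p.image, oracle, rtol=1e-15)

    def test_max_projection(self, rng):
        arr = rng.random((3, 6, 6))
        assert np.array_equal(project_stack(_stack(arr), "max").image,
                              arr.max(axis=0))


class TestSmooth:
    def test_sigma_zero_identity(self, rng):
        img = Projection(rng.random((10, 10)))
        assert np.array_equal(smooth(img, 0).image, img.image)

    def test_constant_invariance(self):
        img = Projection(np.full((16, 16), 5.0))
        assert np.allclose(smooth(img, 3.0).image, 5.0)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            smooth(Projection(np.ones((4, 4))), -1.0)

    def test_matches_direct_convolution_oracle(self):
        """Separable Gaussian filtering equals a dense direct correlation
        with symmetric padding; blob total preserved to <0.5%."""
        img = _blob((40, 40), (20.0, 20.0), sigma=4.0)
        sigma = 2.0
        out = smooth(Projection(img), sigma).image
        radius = int(4.0 * sigma + 0.5)  # matches the implementation's truncate
        x = np.arange(-radius, radius + 1)
        k1 = np.exp(-x ** 2 / (2 * sigma ** 2))
        k1 /= k1.sum()
        kern = np.outer(k1, k1)
        padded = np.pad(img, radius, mode="symmetric")
        oracle = np.empty_like(img)
        for i in range(img.shape[0]):
            for j in range(img.shape[1]):
                oracle[i, j] = np.sum(
                    padded[i:i + 2 * radius + 1, j:j + 2 * radius + 1] * kern)
        assert np.allclose(out, oracle, atol=1e-10)
        assert abs(out.sum() - img.sum()) / img.sum() < 0.005


class TestSymmetryMap:
    def test_constant_image_is_silent(self):
        sym = symmetry_map(Projection(np.full((32, 32), 9.0)), 2.0, 2.0)
        assert sym.magnitude.max() < 1e-9

    def test_blob_argmax_at_center(self):
        img = _blob((64, 64), (32.0, 32.0), sigma=4.0)
        sym = symmetry_map(Projection(img), 2.0, 2.0)
        r, c = np.unravel_index(np.argmax(sym.magnitude), sym.magnitude.shape)
        assert np.hypot(r - 32, c - 32) <= 1.0

    def test_two_blobs_two_peaks(self):
        img = (_blob((96, 96), (30.0, 30.0), 4.0)
               + _blob((96, 96), (65.0, 62.0), 4.0))
        sym = symmetry_map(Projection(img), 2.0, 2.0)
        seeds = detect_seeds(sym, 0.5, 6.0)
        near = lambda p, q: np.hypot(p[0] - q[0], p[1] - q[1]) <= 1.0
        assert any(near(s, (30, 30)) for s in seeds.seeds)
        assert any(near(s, (65, 62)) for s in seeds.seeds)

    def test_response_matches_bruteforce_correlation_oracle(self, rng):
        """Complex response equals the direct per-pixel correlation of the
        double-angle gradient field with the conjugated order-2 basis."""
        img = _blob((24, 24), (11.0, 13.0), 3.0) + 5 * rng.random((24, 24))
        sigma_g, sigma_w = 1.5, 1.5
        sym = symmetry_map(Projection(img), sigma_g, sigma_w, normalized=False)
        gy = ndimage.gaussian_filter(img, sigma_g, order=(1, 0), mode="reflect")
        gx = ndimage.gaussian_filter(img, sigma_g, order=(0, 1), mode="reflect")
        z = (gx + 1j * gy) ** 2
        b, _ = _symmetry_basis(sigma_w)
        radius = b.shape[0] // 2
        zp = np.pad(z, radius, mode="symmetric")
        oracle = np.empty_like(z)
        for i in range(img.shape[0]):
            for j in range(img.shape[1]):
                patch = zp[i:i + 2 * radius + 1, j:j + 2 * radius + 1]
                oracle[i, j] = np.sum(np.conj(b) * patch)
        assert np.allclose(sym.response, oracle, rtol=1e-10, atol=1e-8)

    def test_translation_equivariance(self):
        img = _blob((64, 64), (25.0, 27.0), 4.0)
        shifted = np.roll(np.roll(img, 5, axis=0), 3, axis=1)
        m1 = symmetry_map(Projection(img), 2.0, 2.0).magnitude
        m2 = symmetry_map(Projection(shifted), 2.0, 2.0).magnitude
        interior = (slice(16, 48), slice(16, 48))
        assert np.allclose(np.roll(np.roll(m1, 5, axis=0), 3, axis=1)[interior],
                           m2[interior], atol=1e-9)

    def test_rotation_invariance_at_center(self):
        img = _blob((65, 65), (32.0, 32.0), 4.0)
        m1 = symmetry_map(Projection(img), 2.0, 2.0).magnitude
        m2 = symmetry_map(Projection(np.rot90(img).copy()), 2.0, 2.0).magnitude
        assert abs(m1[32, 32] - m2[32, 32]) / m1[32, 32] < 0.02

    def test_contrast_invariance_when_normalized(self):
        img = _blob((48, 48), (24.0, 24.0), 4.0) + 1.0
        m1 = symmetry_map(Projection(img), 2.0, 2.0, normalized=True).magnitude
        m2 = symmetry_map(Projection(7.5 * img), 2.0, 2.0,
                          normalized=True).magnitude
        assert np.allclose(m1, m2, atol=1e-9)

    def test_normalized_magnitude_bounded(self):
        img = _blob((48, 48), (20.0, 30.0), 5.0)
        sym = symmetry_map(Projection(img), 2.0, 2.0, normalized=True)
        assert sym.magnitude.max() <= 1.0 + 1e-9

    def test_invalid_sigmas_rejected(self):
        with pytest.raises(ValueError):
            symmetry_map(Projection(np.ones((8, 8))), 0.0, 2.0)
        with pytest.raises(ValueError):
            symmetry_map(Projection(np.ones((8, 8))), 2.0, -1.0)


class TestDetectSeeds:
    @staticmethod
    def _map_from(mag):
        return SymmetryMap(response=mag.astype(complex), magnitude=mag,
                           phase=np.zeros_like(mag), sigma_gradient=1.0,
                           sigma_window=1.0, normalized=True)

    def test_single_global_max(self):
        mag = np.zeros((10, 10))
        mag[4, 6] = 1.0
        seeds = detect_seeds(self._map_from(mag), 0.5, 3.0)
        assert seeds.seeds == [(4, 6)]

    def test_equal_close_peaks_row_major_tiebreak(self):
        mag = np.zeros((10, 10))
        mag[3, 3] = 1.0
        mag[4, 5] = 1.0  # within min_distance of (3,3); same height
        seeds = detect_seeds(self._map_from(mag), 0.5, 4.0)
        assert seeds.seeds == [(3, 3)]

    def test_all_zero_magnitude_empty(self):
        seeds = detect_seeds(self._map_from(np.zeros((8, 8))), 0.5, 2.0)
        assert seeds.seeds == []

    def test_threshold_bounds(self):
        with pytest.raises(ValueError):
            detect_seeds(self._map_from(np.ones((4, 4))), 1.5, 2.0)

    def test_ten_cell_scene_seed_accuracy(self):
        """On a clean 10-cell field the in-mask seeds are exactly the ten
        cell centers (≤2 px each); peaks outside the foreground are culled
        by the mask, which is how the pipeline consumes them."""
        spec = SceneSpec(rows=256, cols=256, n_cells=10, seed=21, **NOISELESS)
        stack, truth = render_scene(spec)
        sm = smooth(project_stack(stack), 2.0)
        sym = symmetry_map(sm, 2.0, 2.0)
        mask = foreground_mask(sm, erode_px=2)
        seeds = [s for s in detect_seeds(sym, 0.3, 4.0).seeds if mask[s]]
        assert len(seeds) == 10
        for r0, c0 in truth.true_centers:
            assert min(np.hypot(r0 - r, c0 - c) for r, c in seeds) <= 2.0


class TestForegroundMask:
    def test_bimodal_separation(self):
        img = np.full((20, 20), 10.0)
        img[:2, :] = 200.0  # 10% bright pixels
        mask = foreground_mask(Projection(img), min_area=5)
        assert np.array_equal(mask, img == 200.0)

    def test_degenerate_image_warns_empty(self):
        with pytest.warns(UserWarning, match="single-valued"):
            mask = foreground_mask(Projection(np.full((8, 8), 3.0)))
        assert not mask.any()

    def test_blob_scene_mask_area_near_truth(self):
        spec = SceneSpec(rows=192, cols=192, n_cells=5, seed=4, **NOISELESS)
        stack, truth = render_scene(spec)
        sm = smooth(project_stack(stack), 2.0)
        mask = foreground_mask(sm, erode_px=2)
        truth_area = (truth.truth_labels.labels > 0).sum()
        assert abs(mask.sum() - truth_area) / truth_area < 0.20


class TestSegment:
    def test_two_disjoint_blobs_two_labels(self):
        img = (_blob((64, 64), (18.0, 18.0), 4.0)
               + _blob((64, 64), (45.0, 44.0), 4.0))
        proj = Projection(img)
        mask = foreground_mask(proj, min_area=10)
        seeds = detect_seeds(symmetry_map(proj, 2.0, 2.0), 0.3, 4.0)
        labels = segment(proj, seeds, mask, min_area=10)
        assert labels.n_cells == 2
        labels.check_connectivity()

    def test_labels_partition_the_mask(self):
        img = (_blob((64, 64), (18.0, 18.0), 4.0)
               + _blob((64, 64), (45.0, 44.0), 4.0))
        proj = Projection(img)
        mask = foreground_mask(proj, min_area=10)
        seeds = detect_seeds(symmetry_map(proj, 2.0, 2.0), 0.3, 4.0)
        labels = segment(proj, seeds, mask, min_area=10)
        assert np.array_equal(labels.labels > 0, mask)

    def test_empty_seed_set_all_background(self):
        proj = Projection(np.ones((16, 16)))
        from symquant.segmentation import SeedSet
        labels = segment(proj, SeedSet([], 2.0, 0.3),
                         np.ones((16, 16), dtype=bool), min_area=1)
        assert labels.n_cells == 0

    def test_outside_mask_seeds_dropped_with_warning(self):
        proj = Projection(_blob((32, 32), (16.0, 16.0), 4.0))
        mask = foreground_mask(proj, min_area=5)
        from symquant.segmentation import SeedSet
        seeds = SeedSet([(16, 16), (1, 1)], 4.0, 0.3)
        with pytest.warns(UserWarning, match="dropped 1 seed"):
            labels = segment(proj, seeds, mask, min_area=5)
        assert labels.n_cells == 1

    def test_touching_pair_split_along_valley(self):
        spec = SceneSpec(rows=192, cols=192, n_cells=6, touching_pairs=3,
                         seed=17, **NOISELESS)
        stack, truth = render_scene(spec)
        labels = segment_pipeline(stack)
        for p in range(3):
            (r1, c1), (r2, c2) = (truth.true_centers[2 * p],
                                  truth.true_centers[2 * p + 1])
            l1 = labels.labels[round(r1), round(c1)]
            l2 = labels.labels[round(r2), round(c2)]
            assert l1 > 0 and l2 > 0 and l1 != l2


class TestPipeline:
    def test_five_cell_recovery(self):
        from symquant.evaluation import segmentation_recovery
        spec = SceneSpec(rows=192, cols=192, n_cells=5, seed=31, **NOISELESS)
        r = segmentation_recovery(spec)
        assert r["n_pred"] == 5
        assert r["min_iou"] >= 0.8

    def test_empty_scene_zero_cells(self):
        spec = SceneSpec(n_cells=0, noise_model="none", background_level=1.0)
        stack, _ = render_scene(spec)
        with pytest.warns(UserWarning, match="single-valued"):
            labels = segment_pipeline(stack)
        assert labels.n_cells == 0

    def test_deterministic(self):
        spec = SceneSpec(rows=128, cols=128, n_cells=4, seed=12)
        stack, _ = render_scene(spec)
        l1 = segment_pipeline(stack)
        l2 = segment_pipeline(stack)
        assert np.array_equal(l1.labels, l2.labels)

    def test_regions_confined_to_mask_and_connected(self):
        spec = SceneSpec(rows=192, cols=192, n_cells=6, seed=13)
        stack, _ = render_scene(spec)
        labels, inter = segment_pipeline(stack, return_intermediates=True)
        assert not (labels.labels[~inter["mask"]] > 0).any()
        labels.check_connectivity()
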