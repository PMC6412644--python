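"""Segmentation stack: preprocessing, adhesion features, reconstruction,
markers, minima imposition, watershed and the full pipeline."""

import math
import warnings

import numpy as np
import pytest
from scipy import ndimage as ndi
from skimage.segmentation import watershed as skimage_watershed

from dropvision.segment import (
    CarrierImage,
    MmcwsParams,
    RegionFeatures,
    StructuringElement,
    area_threshold,
    background_markers,
    classify_adhesion,
    close_reconstruction,
    foreground_markers,
    gradient_magnitude,
    hybrid_reconstruction,
    impose_minima,
    mmcws,
    open_reconstruction,
    otsu_binarize,
    preprocess,
    region_shape_degree,
    shape_degree,
    watershed_transform,
)
from tests import _oracles
from tests.conftest import make_disk_image


def rasterized_disk(r, pad=5):
    n = 2 * r + 2 * pad
    yy, xx = np.mgrid[:n, :n]
    return ((yy - n / 2 + 0.5) ** 2 + (xx - n / 2 + 0.5) ** 2) <= r * r


class TestPreprocess:
    def test_grayscale_constant_passthrough(self):
        img = CarrierImage(np.full((6, 6), 0.5), scale_cm_per_px=0.01)
        np.testing.assert_allclose(preprocess(img), 0.5)

    def test_pure_red_maps_to_bt601_weight(self):
        px = np.zeros((6, 6, 3))
        px[..., 0] = 1.0
        img = CarrierImage(px, scale_cm_per_px=0.01)
        np.testing.assert_allclose(preprocess(img), 0.299)

    def test_bright_polarity_inverts(self):
        img = CarrierImage(np.full((6, 6), 0.8), 0.01, polarity="bright")
        np.testing.assert_allclose(preprocess(img), 1.0 - 0.8)

    def test_rejects_bad_channel_count(self):
        with pytest.raises(ValueError):
            preprocess(CarrierImage(np.zeros((4, 4, 2)), 0.01))


class TestOtsu:
    def test_bimodal_split(self):
        gray = np.concatenate(
            [np.full(32, 0.2), np.full(32, 0.8)]
        ).reshape(8, 8)
        fg = otsu_binarize(gray)
        assert fg.sum() == 32
        assert fg[gray == 0.2].all()

    def test_four_pixel_image(self):
        fg = otsu_binarize(np.array([[0.0, 0.0], [1.0, 1.0]]))
        np.testing.assert_array_equal(fg, [[True, True], [False, False]])

    def test_constant_image_warns_and_is_empty(self):
        with pytest.warns(UserWarning):
            fg = otsu_binarize(np.full((4, 4), 0.5))
        assert not fg.any()

    def test_threshold_maximizes_between_class_variance(self):
        # independent oracle: enumerate every split between observed levels
        rng = np.random.default_rng(0)
        gray = rng.choice(np.linspace(0.1, 0.9, 8), size=(16, 16))
        fg = otsu_binarize(gray)

        def between_var(mask):
            if not mask.any() or mask.all():
                return -1.0
            w0, w1 = mask.mean(), 1 - mask.mean()
            return w0 * w1 * (gray[mask].mean() - gray[~mask].mean()) ** 2

        levels = np.unique(gray)
        best = max(
            between_var(gray < 0.5 * (a + b))
            for a, b in zip(levels, levels[1:])
        )
        assert between_var(fg) == pytest.approx(best, rel=1e-12)


class TestGradient:
    def test_constant_image_has_zero_gradient(self):
        assert gradient_magnitude(np.full((6, 6), 0.3)).max() == 0.0

    def test_vertical_step_peaks_on_edge(self):
        img = np.zeros((7, 9))
        img[:, 5:] = 1.0
        g = gradient_magnitude(img)
        assert g[:, 0].max() == 0.0
        assert g.argmax(axis=1).tolist().count(4) + g.argmax(axis=1).tolist().count(5) == 7

    def test_matches_hand_convolution(self):
        rng = np.random.default_rng(1)
        img = rng.random((5, 5))
        kx = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], float)
        ky = kx.T
        # scipy's "reflect" boundary repeats the edge sample (numpy "symmetric")
        pad = np.pad(img, 1, mode="symmetric")
        ix = np.zeros_like(img)
        iy = np.zeros_like(img)
        for y in range(5):
            for x in range(5):
                win = pad[y : y + 3, x : x + 3]
                # correlation vs convolution: flip the kernel
                ix[y, x] = (win * kx[::-1, ::-1]).sum()
                iy[y, x] = (win * ky[::-1, ::-1]).sum()
        np.testing.assert_allclose(
            gradient_magnitude(img), np.hypot(ix, iy), atol=1e-12
        )


class TestShapeDegree:
    def test_analytic_circle_is_one(self):
        for r in (0.5, 1.0, 7.3):
            assert shape_degree(math.pi * r * r, 2 * math.pi * r) == pytest.approx(1.0)

    def test_square_closed_form(self):
        s = 4.0
        assert shape_degree(s * s, 4 * s) == pytest.approx(math.pi / 4)

    def test_tangent_disk_dumbbell_closed_form(self):
        # two unit disks sharing a point: A = 2*pi, L = 4*pi
        assert shape_degree(2 * math.pi, 4 * math.pi) == pytest.approx(0.5)

    def test_rasterized_disks_converge_monotonically_to_one(self):
        es = [region_shape_degree(rasterized_disk(r)) for r in (5, 10, 20, 40)]
        assert all(a < b for a, b in zip(es, es[1:]))
        assert es[-1] == pytest.approx(1.0, abs=0.05)
        assert all(e <= 1.0 for e in es)

    def test_rejects_degenerate_inputs(self):
        with pytest.raises(ValueError):
            shape_degree(0.0, 10.0)
        with pytest.raises(ValueError):
            shape_degree(10.0, 0.0)


class TestAreaThresholdAndAdhesion:
    def test_mean_area(self):
        assert area_threshold([40.0]) == 40.0
        assert area_threshold([10.0, 20.0, 30.0]) == 20.0
        rng = np.random.default_rng(0)
        areas = rng.integers(5, 500, size=1000).astype(float)
        assert area_threshold(areas) == pytest.approx(float(np.mean(areas)))

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            area_threshold([])

    @pytest.mark.parametrize(
        "e_val, area, expected",
        [
            (0.86, 50.0, "single"),  # round and small
            (0.48, 50.0, "adhesive"),  # fused shape
            (0.90, 200.0, "adhesive"),  # round but oversized blob
        ],
    )
    def test_rule(self, e_val, area, expected):
        reg = RegionFeatures(1, int(area), 10.0, e_val, False)
        assert classify_adhesion(reg, e=0.67, d=100.0) == expected


def random_small_images(rng, n):
    """Mix of binary and 4-level grayscale images up to 8x8."""
    for _ in range(n):
        h, w = rng.integers(4, 9, size=2)
        if rng.random() < 0.5:
            yield (rng.random((h, w)) < 0.5).astype(float)
        else:
            yield rng.choice([0.0, 0.25, 0.5, 1.0], size=(h, w))


class TestReconstruction:
    def test_matches_naive_fixed_point_oracle(self):
        rng = np.random.default_rng(2)
        se = StructuringElement(1)
        fp = se.footprint()
        for g in random_small_images(rng, 40):
            r = g  # self-reference, the common usage
            got = open_reconstruction(g, r, se)
            exp = _oracles.brute_open_reconstruction(g, r, fp)
            np.testing.assert_allclose(got, exp, atol=1e-12)
            got_c = close_reconstruction(g, r, se)
            exp_c = _oracles.brute_close_reconstruction(g, r, fp)
            np.testing.assert_allclose(got_c, exp_c, atol=1e-12)

    def test_blob_larger_than_se_is_preserved_exactly(self):
        g = np.zeros((10, 10))
        g[2:8, 2:8] = 1.0
        out = open_reconstruction(g, g, StructuringElement(2))
        np.testing.assert_allclose(out, g)

    def test_speckle_smaller_than_se_is_removed(self):
        g = np.zeros((9, 9))
        g[4, 4] = 1.0
        out = open_reconstruction(g, g, StructuringElement(1))
        assert out.max() == 0.0

    def test_pinhole_is_filled_by_close_reconstruction(self):
        g = np.ones((9, 9))
        g[4, 4] = 0.0
        out = close_reconstruction(g, g, StructuringElement(1))
        assert out.min() == 1.0

    def test_close_is_dual_of_open_under_complement(self):
        rng = np.random.default_rng(5)
        se = StructuringElement(1)
        for g in random_small_images(rng, 10):
            lhs = close_reconstruction(g, g, se)
            rhs = 1.0 - open_reconstruction(1.0 - g, 1.0 - g, se)
            np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_hybrid_removes_salt_and_pepper(self):
        clean = np.zeros((12, 12))
        clean[3:9, 3:9] = 1.0
        noisy = clean.copy()
        noisy[1, 1] = 1.0  # salt far from the blob
        noisy[5, 5] = 0.0  # pepper inside the blob
        se = StructuringElement(1)
        np.testing.assert_allclose(
            hybrid_reconstruction(noisy, noisy, se),
            hybrid_reconstruction(clean, clean, se),
        )

    def test_stage_order_matters(self):
        rng = np.random.default_rng(11)
        se = StructuringElement(1)
        differs = False
        for g in random_small_images(rng, 25):
            ab = hybrid_reconstruction(g, g, se)
            closed = close_reconstruction(g, g, se)
            ba = open_reconstruction(closed, closed, se)
            if not np.allclose(ab, ba):
                differs = True
                break
        assert differs, "open-then-close always equalled close-then-open"

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            open_reconstruction(np.zeros((3, 3)), np.zeros((4, 4)))


class TestMarkers:
    def test_two_disjoint_disks_give_two_foreground_markers(self):
        img = make_disk_image([(20, 16), (44, 48)], [8, 8])
        gray = preprocess(img)
        fgm = foreground_markers(gray, StructuringElement(3), otsu_binarize(gray))
        _, n = ndi.label(fgm, structure=np.ones((3, 3), bool))
        assert n == 2

    def test_single_disk_marker_inside(self):
        img = make_disk_image([(32, 32)], [10])
        gray = preprocess(img)
        disk_mask = otsu_binarize(gray)
        fgm = foreground_markers(gray, StructuringElement(3), disk_mask)
        _, n = ndi.label(fgm, structure=np.ones((3, 3), bool))
        assert n == 1
        assert (fgm & ~disk_mask).sum() == 0

    def test_scene_marker_count_matches_truth(self, small_scene):
        gray = preprocess(small_scene.image)
        fgm = foreground_markers(gray, StructuringElement(3), otsu_binarize(gray))
        _, n = ndi.label(fgm, structure=np.ones((3, 3), bool))
        assert n == small_scene.truth_n

    def test_background_ridge_between_two_disks(self):
        img = make_disk_image([(32, 16), (32, 48)], [8, 8])
        binary = otsu_binarize(preprocess(img))
        bgm = background_markers(binary)
        assert bgm.any()
        assert not (bgm & binary).any()
        assert bgm[:, 28:37].any()  # a ridge passes between the disks

    def test_single_disk_ridge_disjoint_from_disk(self):
        img = make_disk_image([(32, 32)], [8])
        binary = otsu_binarize(preprocess(img))
        bgm = background_markers(binary)
        assert bgm.any()
        assert not (bgm & binary).any()

    def test_scene_ridges_avoid_truth_droplets(self, small_scene):
        binary = otsu_binarize(preprocess(small_scene.image))
        bgm = background_markers(binary)
        assert not (bgm & small_scene.truth_mask).any()

    def test_all_foreground_warns(self):
        with pytest.warns(UserWarning):
            bgm = background_markers(np.ones((5, 5), bool))
        assert not bgm.any()


class TestImposeMinima:
    def test_single_marker_pixel_is_unique_minimum(self):
        rng = np.random.default_rng(0)
        grad = rng.random((8, 8))
        markers = np.zeros((8, 8), bool)
        markers[3, 4] = True
        out = impose_minima(grad, markers)
        minima = _oracles.brute_regional_minima(out)
        np.testing.assert_array_equal(minima, markers)

    def test_random_cases_minima_equal_markers(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            grad = rng.random((16, 16))
            markers = rng.random((16, 16)) < 0.08
            if not markers.any():
                markers[0, 0] = True
            out = impose_minima(grad, markers)
            np.testing.assert_array_equal(
                _oracles.brute_regional_minima(out), markers
            )

    def test_empty_markers_rejected(self):
        with pytest.raises(ValueError):
            impose_minima(np.zeros((4, 4)), np.zeros((4, 4), bool))


class TestWatershed:
    def test_double_well_splits_at_barrier(self):
        surface = np.array(
            [[0.0, 1.0, 2.0, 5.0, 2.0, 1.0, 0.0]]
        )
        markers = np.zeros_like(surface, dtype=np.int32)
        markers[0, 0], markers[0, 6] = 1, 2
        lab = watershed_transform(surface, markers)
        assert lab[0, :3].tolist() == [1, 1, 1]
        assert lab[0, 4:].tolist() == [2, 2, 2]

    def test_single_marker_floods_everything(self):
        rng = np.random.default_rng(0)
        surface = rng.random((6, 6))
        markers = np.zeros((6, 6), np.int32)
        markers[2, 2] = 1
        assert (watershed_transform(surface, markers) == 1).all()

    def test_matches_independent_implementation(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            surface = rng.random((10, 10))
            markers = np.zeros((10, 10), np.int32)
            k = rng.integers(2, 5)
            for i, p in enumerate(rng.choice(100, size=k, replace=False), 1):
                markers[p // 10, p % 10] = i
            got = watershed_transform(surface, markers, connectivity=2)
            exp = skimage_watershed(surface, markers, connectivity=2)
            np.testing.assert_array_equal(got, exp)

    def test_mask_restricts_flooding(self):
        surface = np.zeros((5, 5))
        markers = np.zeros((5, 5), np.int32)
        markers[2, 2] = 1
        mask = np.zeros((5, 5), bool)
        mask[1:4, 1:4] = True
        lab = watershed_transform(surface, markers, mask=mask)
        assert (lab[mask] == 1).all()
        assert (lab[~mask] == 0).all()

    def test_no_markers_rejected(self):
        with pytest.raises(ValueError):
            watershed_transform(np.zeros((3, 3)), np.zeros((3, 3), np.int32))


class TestMmcws:
    def test_disjoint_disks_pass_through(self):
        centers = [(12 + 14 * i, 12 + 14 * j) for i in range(4) for j in range(4)]
        img = make_disk_image(centers[:16], [4] * 16, shape=(72, 72))
        res = mmcws(img)
        assert res.n_droplets == 16  # one label per disk, no splits invoked
        _, n_binary = ndi.label(res.binary, structure=np.ones((3, 3), bool))
        assert res.n_droplets == n_binary

    def test_overlapping_pair_is_split(self):
        # centres 1.5 r apart: one binary component, two droplets
        img = make_disk_image([(32, 26), (32, 38)], [8, 8])
        binary = otsu_binarize(preprocess(img))
        _, n_binary = ndi.label(binary, structure=np.ones((3, 3), bool))
        assert n_binary == 1
        res = mmcws(img)
        assert res.n_droplets == 2

    def test_deterministic(self, small_scene):
        r1 = mmcws(small_scene.image)
        r2 = mmcws(small_scene.image)
        np.testing.assert_array_equal(r1.labels, r2.labels)

    def test_splitting_never_merges(self, adhesive_scene):
        res = mmcws(adhesive_scene.image)
        _, n_binary = ndi.label(res.binary, structure=np.ones((3, 3), bool))
        assert res.n_droplets >= n_binary

    def test_labels_partition_their_foreground(self, adhesive_scene):
        res = mmcws(adhesive_scene.image)
        assert sum(r.area_px for r in res.regions) == int((res.labels > 0).sum())
        # labelled pixels are a subset of the binary foreground
        assert not (res.labels > 0)[~res.binary].any()

    def test_empty_image_warns_and_returns_empty(self):
        img = CarrierImage(np.full((16, 16), 0.8), 0.01)
        with pytest.warns(UserWarning):
            res = mmcws(img)
        assert res.n_droplets == 0
        assert res.labels.max() == 0

    def test_label_ids_contiguous(self, small_scene):
        res = mmcws(small_scene.image)
        present = np.unique(res.labels)
        assert present[0] == 0
        np.testing.assert_array_equal(
            present[1:], np.arange(1, res.n_droplets + 1)
        )
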