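"""Texture operators against hand-computed values and brute-force oracles."""

import numpy as np
import pytest

from deltarad.texture import (collage_map, compute_glcm, default_gabor_bank,
                              gabor_maps, haralick_maps, haralick_stats,
                              quantize)
from scipy import ndimage

from _oracles import (collage_window_oracle, glcm_window_oracle,
                      haralick_oracle, quantize_oracle)


class TestQuantize:
    @pytest.mark.parametrize("values,n,rng_,expected", [
        ([0, 1, 2, 3], 4, (0, 3), [0, 1, 2, 3]),
        ([5, 5, 5], 4, (5, 5), [0, 0, 0]),
        ([0, 0.49, 0.5, 1.0], 2, (0, 1), [0, 0, 1, 1]),
    ])
    def test_known_binnings(self, values, n, rng_, expected):
        got = quantize(np.asarray(values, float), n, rng_)
        np.testing.assert_array_equal(got, expected)

    def test_matches_direct_bin_edge_oracle(self, rng):
        v = rng.uniform(-3, 9, size=(12, 12))
        got = quantize(v, 16, (-3, 9))
        np.testing.assert_array_equal(got, quantize_oracle(v, 16, -3.0, 9.0))

    def test_rejects_fewer_than_two_levels(self):
        with pytest.raises(ValueError):
            quantize(np.zeros(3), 1, (0, 1))


class TestGlcm:
    def test_two_by_two_hand_enumeration(self):
        patch = np.array([[0, 1], [1, 1]])
        glcm = compute_glcm(patch, offsets=((0, 1), (1, 0)), n_levels=2)
        np.testing.assert_allclose(glcm, [[0.0, 0.25], [0.25, 0.5]])

    def test_constant_patch_single_cell(self):
        glcm = compute_glcm(np.full((3, 3), 2), n_levels=4)
        expected = np.zeros((4, 4))
        expected[2, 2] = 1.0
        np.testing.assert_allclose(glcm, expected)

    def test_symmetry(self, rng):
        for _ in range(5):
            patch = rng.integers(0, 8, size=(6, 7))
            glcm = compute_glcm(patch, n_levels=8)
            np.testing.assert_allclose(glcm, glcm.T)
            assert glcm.sum() == pytest.approx(1.0, abs=1e-9)

    def test_single_pixel_has_no_pairs(self):
        with pytest.raises(ValueError):
            compute_glcm(np.array([[3]]), n_levels=4)


class TestHaralickStats:
    def test_hand_computed_three_cell_matrix(self):
        glcm = np.array([[0.0, 0.25], [0.25, 0.5]])
        s = haralick_stats(glcm)
        assert s["entropy"] == pytest.approx(1.5)
        assert s["energy"] == pytest.approx(0.375)
        assert s["contrast"] == pytest.approx(0.5)
        assert s["inertia"] == pytest.approx(0.5)

    def test_diagonal_matrix(self):
        s = haralick_stats(np.diag([0.5, 0.5]))
        assert s["contrast"] == 0.0
        assert s["inverse_difference_moment"] == pytest.approx(1.0)

    def test_single_cell_matrix(self):
        s = haralick_stats(np.array([[1.0]]))
        assert s["entropy"] == 0.0
        assert s["energy"] == 1.0

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError):
            haralick_stats(np.array([[1.0, 1.0], [0.0, 0.0]]))

    def test_all_13_match_termwise_oracle(self, rng):
        for _ in range(10):
            c = rng.random((6, 6))
            P = (c + c.T) / (c + c.T).sum()
            got = haralick_stats(P)
            want = haralick_oracle(P)
            for name in got:
                assert got[name] == pytest.approx(want[name], abs=1e-10), name


class TestHaralickMaps:
    def test_constant_slice_degenerate_maps(self):
        sl = np.full((9, 9), 4.2)
        roi = np.zeros((9, 9), bool)
        roi[3:6, 3:6] = True
        maps = haralick_maps(sl, roi, window=3)
        np.testing.assert_allclose(maps["entropy"][roi], 0.0)
        np.testing.assert_allclose(maps["energy"][roi], 1.0)

    def test_single_voxel_roi(self, rng):
        sl = rng.normal(size=(9, 9))
        roi = np.zeros((9, 9), bool)
        roi[4, 4] = True
        maps = haralick_maps(sl, roi, window=5)
        for m in maps.values():
            assert np.isfinite(m[roi]).sum() == 1
            assert np.isnan(m[~roi]).all()

    def test_checkerboard_center_equals_single_window_glcm(self):
        sl = np.indices((9, 9)).sum(axis=0) % 2 * 1.0
        roi = np.ones((9, 9), bool)  # full ROI so the slice range is (0, 1)
        maps = haralick_maps(sl, roi, window=3, n_levels=16)
        levels = quantize(sl, 16, (0.0, 1.0))
        P = glcm_window_oracle(levels, 4, 4, 3, 16)
        want = haralick_oracle(P)
        for name, m in maps.items():
            assert m[4, 4] == pytest.approx(want[name], abs=1e-10), name

    @pytest.mark.parametrize("window", [3, 5, 7])
    def test_every_voxel_matches_bruteforce_window_oracle(self, window, rng):
        sl = rng.normal(10, 3, size=(12, 11))
        roi = rng.random((12, 11)) < 0.4
        roi[5, 5] = True
        maps = haralick_maps(sl, roi, window=window, n_levels=8)
        vals = sl[roi]
        levels = quantize(sl, 8, (vals.min(), vals.max()))
        for (y, x) in np.argwhere(roi):
            want = haralick_oracle(glcm_window_oracle(levels, y, x, window, 8))
            for name in maps:
                assert maps[name][y, x] == pytest.approx(
                    want[name], abs=1e-9), (name, y, x)

    def test_intensity_shift_invariance(self, rng):
        sl = rng.normal(0, 2, size=(10, 10))
        roi = np.zeros((10, 10), bool)
        roi[3:7, 3:7] = True
        m1 = haralick_maps(sl, roi, 5)
        m2 = haralick_maps(sl + 117.0, roi, 5)
        for name in m1:
            np.testing.assert_allclose(m1[name][roi], m2[name][roi],
                                       atol=1e-9)


class TestGabor:
    def test_kernels_have_zero_dc(self):
        for k in default_gabor_bank():
            assert abs(k.sum()) < 1e-12

    def test_constant_slice_zero_response(self):
        sl = np.full((20, 20), 9.0)
        roi = np.ones((20, 20), bool)
        maps = gabor_maps(sl, roi)
        for m in maps.values():
            np.testing.assert_allclose(m[roi], 0.0, atol=1e-9)

    def test_response_invariant_to_constant_offset(self, rng):
        sl = rng.normal(size=(20, 20))
        roi = np.ones((20, 20), bool)
        m1 = gabor_maps(sl, roi)
        m2 = gabor_maps(sl + 55.0, roi)
        for name in m1:
            np.testing.assert_allclose(m1[name][roi], m2[name][roi], atol=1e-8)

    def test_oriented_stripes_prefer_aligned_filter(self):
        cols = np.arange(32)
        sl = np.tile(np.cos(2 * np.pi * cols / 4.0), (32, 1))  # vertical stripes
        roi = np.ones((32, 32), bool)
        maps = gabor_maps(sl, roi)
        center = (16, 16)
        assert maps["orient000"][center] > maps["orient072"][center]
        assert maps["orient000"][center] > maps["orient108"][center]

    def test_matches_direct_convolution(self, rng):
        sl = rng.normal(size=(24, 24))
        roi = np.ones((24, 24), bool)
        bank = default_gabor_bank()
        maps = gabor_maps(sl, roi, bank)
        direct = np.abs(ndimage.convolve(sl, bank[0], mode="reflect"))
        np.testing.assert_allclose(maps["orient000"], direct, atol=1e-12)

    def test_kernel_larger_than_slice_rejected(self, rng):
        with pytest.raises(ValueError):
            gabor_maps(rng.normal(size=(6, 6)), np.ones((6, 6), bool))


class TestCollage:
    def test_constant_slice_zero_entropy(self):
        sl = np.full((15, 15), 3.0)
        roi = np.zeros((15, 15), bool)
        roi[5:10, 5:10] = True
        m = collage_map(sl, roi)
        np.testing.assert_allclose(m[roi], 0.0)

    def test_linear_ramp_single_orientation(self):
        sl = np.tile(np.arange(17, dtype=float), (17, 1))
        roi = np.zeros((17, 17), bool)
        roi[6:11, 6:11] = True  # interior: sobel sees a clean single gradient
        m = collage_map(sl, roi)
        np.testing.assert_allclose(m[roi], 0.0, atol=1e-9)

    def test_noise_slice_matches_bruteforce_oracle(self, rng):
        sl = rng.normal(size=(13, 13))
        roi = np.zeros((13, 13), bool)
        roi[4:9, 4:9] = True
        m = collage_map(sl, roi, window=5, n_bins=8)
        gx = ndimage.sobel(sl, axis=0, mode="reflect")
        gy = ndimage.sobel(sl, axis=1, mode="reflect")
        for (y, x) in np.argwhere(roi):
            want = collage_window_oracle(gx, gy, y, x, 5, 8)
            assert m[y, x] == pytest.approx(want, abs=1e-8), (y, x)

    def test_shift_invariance(self, rng):
        sl = rng.normal(size=(14, 14))
        roi = np.zeros((14, 14), bool)
        roi[5:9, 5:9] = True
        np.testing.assert_allclose(collage_map(sl, roi)[roi],
                                   collage_map(sl + 31.0, roi)[roi], atol=1e-9)
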