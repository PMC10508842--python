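"""Intensity standardization and mask resampling."""

import numpy as np
import pytest

from deltarad.images import ImageVolume, RoiMask
from deltarad.preprocess import (DEFAULT_PERCENTILES, StandardizationTemplate,
                                 learn_template, piecewise_linear_map,
                                 resample_mask_nn, standardize,
                                 volume_landmarks)


def _vol(arr, spacing=(1.0, 1.0, 1.0), **kw):
    return ImageVolume(np.asarray(arr, dtype=float), spacing, **kw)


class TestLearnTemplate:
    def test_single_volume_yields_its_own_percentiles(self, rng):
        v = _vol(rng.normal(100, 20, size=(8, 8, 4)))
        t = learn_template([v])
        expected = np.percentile(v.array[v.array != 0], DEFAULT_PERCENTILES)
        np.testing.assert_allclose(t.landmark_values, expected)

    def test_duplicate_volume_changes_nothing(self, rng):
        v = _vol(rng.normal(100, 20, size=(8, 8, 4)))
        t1 = learn_template([v])
        t2 = learn_template([v, v])
        np.testing.assert_allclose(t1.landmark_values, t2.landmark_values)

    def test_landmarks_average_across_volumes(self):
        # uniform grids 0..99 and 0..199: each landmark is the mean of the
        # two volumes' own percentiles (direct percentile oracle)
        a = _vol(np.arange(1, 101, dtype=float).reshape(10, 10, 1))
        b = _vol(np.arange(1, 201, dtype=float).reshape(10, 20, 1))
        t = learn_template([a, b], percentiles=[10, 50, 90])
        for k, p in enumerate([10, 50, 90]):
            expected = (np.percentile(a.array, p) + np.percentile(b.array, p)) / 2
            assert t.landmark_values[k] == pytest.approx(expected)

    def test_empty_list_and_constant_volume_rejected(self):
        with pytest.raises(ValueError):
            learn_template([])
        with pytest.raises(ValueError):
            learn_template([_vol(np.full((4, 4, 2), 7.0))])


class TestStandardize:
    def test_identity_on_template_defining_volume(self, rng):
        v = _vol(rng.normal(50, 10, size=(10, 10, 5)))
        t = learn_template([v])
        out = standardize(v, t)
        got = volume_landmarks(out, t.landmark_percentiles)
        np.testing.assert_allclose(got, t.landmark_values, rtol=1e-6)

    def test_map_is_monotone(self, rng):
        v = _vol(rng.normal(0, 1, size=(10, 10, 4)))
        t = learn_template([_vol(rng.normal(100, 25, size=(10, 10, 4)))])
        out = standardize(v, t)
        order_in = np.argsort(v.array.ravel(), kind="stable")
        mapped = out.array.ravel()[order_in]
        assert np.all(np.diff(mapped) >= -1e-9)

    def test_segment_interpolation_on_hand_computed_array(self):
        # two-landmark template: 10 -> 100 and 20 -> 400 (slope 30)
        src = np.array([10.0, 20.0])
        dst = np.array([100.0, 400.0])
        values = np.array([10, 12.5, 15, 17.5, 20, 11, 19, 13, 16, 18.0])
        expected = 100 + (values - 10) * 30.0
        np.testing.assert_allclose(piecewise_linear_map(values, src, dst),
                                   expected)

    def test_extrapolation_continues_outer_segments(self):
        src = np.array([10.0, 20.0, 40.0])
        dst = np.array([0.0, 10.0, 20.0])
        vals = np.array([0.0, 50.0])
        # below: slope 1 -> -10; above: slope 0.5 -> 25
        np.testing.assert_allclose(piecewise_linear_map(vals, src, dst),
                                   [-10.0, 25.0])

    def test_idempotent_on_landmarks(self, rng):
        v = _vol(rng.normal(80, 15, size=(12, 12, 4)))
        t = learn_template([_vol(rng.normal(200, 30, size=(12, 12, 4)))])
        once = standardize(v, t)
        twice = standardize(once, t)
        lm1 = volume_landmarks(once, t.landmark_percentiles)
        lm2 = volume_landmarks(twice, t.landmark_percentiles)
        # exact up to percentile-interpolation round-off near the knots
        np.testing.assert_allclose(lm1, lm2, rtol=1e-3)

    def test_adc_and_constant_volumes_rejected(self, rng):
        t = learn_template([_vol(rng.normal(100, 10, size=(6, 6, 3)))])
        adc = _vol(rng.normal(1400, 100, size=(6, 6, 3)), sequence="ADC")
        with pytest.raises(ValueError):
            standardize(adc, t)
        with pytest.raises(ValueError):
            standardize(_vol(np.full((6, 6, 3), 3.0)), t)

    def test_template_json_roundtrip(self, tmp_path, rng):
        t = learn_template([_vol(rng.normal(100, 10, size=(6, 6, 3)))])
        t.to_json(tmp_path / "t.json")
        back = StandardizationTemplate.from_json(tmp_path / "t.json")
        assert back == t


class TestResampleMask:
    def test_identity_grid(self):
        arr = np.zeros((6, 6, 3), dtype=bool)
        arr[2:4, 2:4, 1] = True
        m = RoiMask(arr, (1.0, 1.0, 1.0))
        out = resample_mask_nn(m, (6, 6, 3), (1.0, 1.0, 1.0))
        np.testing.assert_array_equal(out.array, arr)

    def test_downsampling_filled_square(self):
        arr = np.zeros((4, 4, 1), dtype=bool)
        arr[:, :, 0] = True
        m = RoiMask(arr, (1.0, 1.0, 1.0))
        out = resample_mask_nn(m, (2, 2, 1), (2.0, 2.0, 1.0))
        assert out.array.all()

    def test_upsampling_single_voxel_center_containment(self):
        arr = np.zeros((5, 5, 1), dtype=bool)
        arr[2, 2, 0] = True
        m = RoiMask(arr, (1.0, 1.0, 1.0))
        fine = resample_mask_nn(m, (20, 20, 1), (0.25, 0.25, 1.0))
        # brute force: a fine voxel is on iff its center rounds to voxel 2
        for i in range(20):
            for j in range(20):
                cx, cy = i * 0.25, j * 0.25
                inside = (round(cx) == 2) and (round(cy) == 2)
                expected = int(np.floor(cx + 0.5)) == 2 and \
                    int(np.floor(cy + 0.5)) == 2
                assert fine.array[i, j, 0] == expected, (i, j, inside)

    def test_disjoint_grids_rejected(self):
        arr = np.ones((4, 4, 2), dtype=bool)
        m = RoiMask(arr, (1.0, 1.0, 1.0))
        with pytest.raises(ValueError):
            resample_mask_nn(m, (4, 4, 2), (1.0, 1.0, 1.0),
                             target_origin_mm=(100.0, 0.0, 0.0))

    def test_empty_result_flagged(self):
        arr = np.zeros((6, 6, 2), dtype=bool)
        arr[0, 0, 0] = True
        m = RoiMask(arr, (1.0, 1.0, 1.0))
        out = resample_mask_nn(m, (2, 2, 2), (1.0, 1.0, 1.0),
                               target_origin_mm=(3.0, 3.0, 0.0))
        assert out.empty_after_resample
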