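"""Preprocessing: orientation, resampling, intensity windows, crops, masks."""

import numpy as np
import pytest

from petldm.core import CT_HU, CT_NORM, PET_SUV, Mask3D, Volume3D
from petldm.phantom import generate_case
from petldm.preprocess import (body_mask, clip_normalize_ct, clip_pet_suv,
                               fixed_size_crop_pad, lung_base_crop_bounds,
                               preprocess_case, reorient_to_ras, resample,
                               surrogate_lung_mask)


class TestReorient:
    def test_ras_identity(self, rng):
        v = Volume3D(rng.normal(size=(4, 5, 6)), (1, 2, 3), "RAS", CT_HU)
        out = reorient_to_ras(v)
        np.testing.assert_array_equal(out.values, v.values)

    def test_lps_flips_first_two_axes(self, rng):
        data = rng.normal(size=(4, 5, 6)).astype(np.float32)
        v = Volume3D(data, (1, 1, 1), "LPS", CT_HU)
        out = reorient_to_ras(v)
        assert out.shape == (4, 5, 6)
        np.testing.assert_array_equal(out.values, data[::-1, ::-1, :])

    def test_axis_permutation_tracks_spacing(self, rng):
        v = Volume3D(rng.normal(size=(4, 5, 6)), (1.0, 2.0, 3.0), "ASR", CT_HU)
        out = reorient_to_ras(v)
        assert out.shape == (6, 4, 5)
        assert out.spacing == (3.0, 1.0, 2.0)

    def test_idempotent(self, rng):
        v = Volume3D(rng.normal(size=(3, 4, 5)), (1, 1, 1), "LAS", CT_HU)
        once = reorient_to_ras(v)
        twice = reorient_to_ras(once)
        np.testing.assert_array_equal(once.values, twice.values)

    def test_unknown_code_raises(self, rng):
        v = Volume3D(rng.normal(size=(3, 3, 3)), (1, 1, 1), "XYZ", CT_HU)
        with pytest.raises(ValueError, match="XYZ"):
            reorient_to_ras(v)


class TestResample:
    def test_identity_spacing(self, rng):
        v = Volume3D(rng.normal(size=(8, 8, 8)), (2, 2, 2), "RAS", CT_HU)
        out = resample(v, (2, 2, 2))
        np.testing.assert_array_equal(out.values, v.values)

    def test_constant_preserved(self):
        v = Volume3D(np.full((8, 8, 8), 7.0), (1, 1, 1), "RAS", CT_HU)
        out = resample(v, (2.5, 1.5, 0.75))
        np.testing.assert_allclose(out.values, 7.0, rtol=1e-6)

    def test_linear_ramp_downsample_matches_analytic(self):
        # f(x) = x in mm at voxel centres (i + 1/2) * spacing
        n = 16
        vals = np.broadcast_to(((np.arange(n) + 0.5) * 1.0)[:, None, None],
                               (n, 4, 4)).copy()
        v = Volume3D(vals, (1, 1, 1), "RAS", PET_SUV)
        out = resample(v, (2, 1, 1), mode="linear")
        expected = (np.arange(8) + 0.5) * 2.0
        np.testing.assert_allclose(out.values[:, 2, 2], expected, rtol=1e-5)

    def test_nearest_keeps_masks_binary(self, rng):
        m = Mask3D(rng.random((9, 9, 9)) > 0.5, (1, 1, 1), "RAS")
        out = resample(m, (1.7, 1.7, 1.7), mode="nearest")
        assert out.values.dtype == bool

    def test_negative_spacing_rejected(self, rng):
        v = Volume3D(rng.normal(size=(4, 4, 4)), (1, 1, 1), "RAS", CT_HU)
        with pytest.raises(ValueError):
            resample(v, (0, 1, 1))


class TestIntensity:
    def test_ct_window_endpoints_and_midpoint(self):
        v = Volume3D(np.array([[[-1000.0, 1000.0, 0.0, -2000.0]]]),
                     (1, 1, 1), "RAS", CT_HU)
        out = clip_normalize_ct(v, (-1000, 1000))
        np.testing.assert_allclose(out.values[0, 0], [-1, 1, 0, -1], atol=1e-6)
        assert out.modality == CT_NORM

    def test_invalid_window(self):
        v = Volume3D(np.zeros((2, 2, 2)), (1, 1, 1), "RAS", CT_HU)
        with pytest.raises(ValueError):
            clip_normalize_ct(v, (100, -100))

    def test_pet_clip(self):
        v = Volume3D(np.array([[[5.0, 100.0, -0.5]]]), (1, 1, 1), "RAS", PET_SUV)
        out = clip_pet_suv(v, 30.0)
        np.testing.assert_allclose(out.values[0, 0], [5.0, 30.0, 0.0])


class TestMasksAndCrops:
    def test_surrogate_lung_dice_vs_ground_truth(self, noiseless_spec):
        ct, _, _, lungs = generate_case(noiseless_spec, 17)
        est = surrogate_lung_mask(ct)
        inter = (est.values & lungs.values).sum()
        dice = 2 * inter / (est.values.sum() + lungs.values.sum())
        assert dice >= 0.95

    def test_all_soft_tissue_warns_empty(self):
        ct = Volume3D(np.full((8, 8, 8), 40.0), (1, 1, 1), "RAS", CT_HU)
        with pytest.warns(UserWarning):
            m = surrogate_lung_mask(ct)
        assert not m.values.any()

    def test_lung_base_bounds_definition(self):
        vals = np.zeros((8, 8, 64), dtype=bool)
        vals[2:4, 2:4, 10:41] = True
        bounds = lung_base_crop_bounds(Mask3D(vals, (1, 1, 1), "RAS"))
        assert bounds.intervals == ((0, 8), (0, 8), (10, 64))

    def test_lungs_at_bottom_keep_full_axis(self):
        vals = np.zeros((4, 4, 16), dtype=bool)
        vals[1:3, 1:3, 0:5] = True
        bounds = lung_base_crop_bounds(Mask3D(vals, (1, 1, 1), "RAS"))
        assert bounds.intervals[2] == (0, 16)

    def test_empty_lung_mask_raises(self):
        with pytest.raises(ValueError, match="external"):
            lung_base_crop_bounds(Mask3D(np.zeros((4, 4, 4), bool), (1, 1, 1), "RAS"))

    def test_body_mask_contains_lungs_and_lesions(self, noiseless_spec):
        ct, _, lesions, lungs = generate_case(noiseless_spec, 23)
        b = body_mask(ct)
        assert (b.values | ~lesions.values).all()   # lesions subset of body
        assert (b.values | ~lungs.values).all()     # lungs filled into body
        assert not b.values[0, 0, 0]

    def test_body_mask_all_air_raises(self):
        ct = Volume3D(np.full((6, 6, 6), -1000.0), (1, 1, 1), "RAS", CT_HU)
        with pytest.raises(ValueError):
            body_mask(ct)


class TestFixedSizeCropPad:
    def test_identity(self, rng):
        v = Volume3D(rng.normal(size=(8, 8, 4)), (1, 1, 1), "RAS", PET_SUV)
        out = fixed_size_crop_pad(v, (8, 8, 4))
        np.testing.assert_array_equal(out.values, v.values)

    def test_central_crop(self, rng):
        data = rng.normal(size=(10, 8, 4)).astype(np.float32)
        v = Volume3D(data, (1, 1, 1), "RAS", PET_SUV)
        out = fixed_size_crop_pad(v, (8, 8, 4))
        np.testing.assert_array_equal(out.values, data[1:9])

    def test_symmetric_pad_odd_remainder_far_side(self, rng):
        data = rng.normal(size=(5, 8, 4)).astype(np.float32)
        v = Volume3D(data, (1, 1, 1), "RAS", PET_SUV)
        out = fixed_size_crop_pad(v, (8, 8, 4), pad_value=-1.0)
        assert out.shape == (8, 8, 4)
        np.testing.assert_array_equal(out.values[1:6], data)
        assert (out.values[0] == -1).all() and (out.values[6:] == -1).all()

    def test_idempotent(self, rng):
        v = Volume3D(rng.normal(size=(5, 9, 4)), (1, 1, 1), "RAS", PET_SUV)
        once = fixed_size_crop_pad(v, (8, 8, 4), pad_value=0.0)
        twice = fixed_size_crop_pad(once, (8, 8, 4), pad_value=0.0)
        np.testing.assert_array_equal(once.values, twice.values)


def test_composed_pipeline_shapes_and_alignment(noiseless_spec):
    ct, pet, lesions, lungs = generate_case(noiseless_spec, 31)
    out = preprocess_case(ct, pet, lung_mask=lungs,
                          extra_masks={"lesion": lesions},
                          target_spacing=(6, 6, 6), target_shape=(32, 32, 16))
    for key, v in out.items():
        assert v.shape == (32, 32, 16), key
        assert np.allclose(v.spacing, (6, 6, 6))
    assert out["pet"].modality == PET_SUV
    assert (out["pet"].values >= 0).all()
    assert out["ct_norm"].modality == CT_NORM
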