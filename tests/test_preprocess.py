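import numpy as np
import pytest

from petseg.image_io import MaskKind, Modality
from petseg.preprocess import (PreprocessConfig, binarize_mask,
                               crop_axial, normalize_intensity, preprocess_case,
                               resample_ct, resample_pet)

from conftest import make_case, make_mask, make_volume


class TestResample:
    def test_ct_halving_512_to_256(self):
        cfg = PreprocessConfig(target_inplane=256)
        ct = make_volume(np.random.default_rng(0).normal(size=(512, 512, 3)),
                         spacing=(0.98, 0.98, 5.0))
        mask = make_mask(np.ones((512, 512, 3)), spacing=(0.98, 0.98, 5.0))
        out_ct, out_mask = resample_ct(ct, mask, cfg)
        assert out_ct.shape == (256, 256, 3)
        assert out_mask.shape == (256, 256, 3)
        # spacing doubles in-plane, z untouched
        assert out_ct.spacing == pytest.approx((1.96, 1.96, 5.0))

    def test_constant_volume_stays_constant(self):
        cfg = PreprocessConfig(target_inplane=16)
        ct = make_volume(np.full((32, 32, 4), 7.0))
        mask = make_mask(np.ones((32, 32, 4)))
        out_ct, out_mask = resample_ct(ct, mask, cfg)
        np.testing.assert_allclose(out_ct.data, 7.0, rtol=1e-6)
        assert out_mask.data.all()   # all-ones mask stays all ones

    def test_pet_200_to_256_upsampling(self):
        cfg = PreprocessConfig(target_inplane=256)
        pet = make_volume(np.zeros((200, 200, 2)), spacing=(4.07, 4.07, 5.0),
                          modality=Modality.PET)
        mask = make_mask(np.zeros((200, 200, 2)), spacing=(4.07, 4.07, 5.0),
                         kind=MaskKind.COARSE)
        out_pet, out_mask = resample_pet(pet, mask, cfg)
        assert out_pet.shape == (256, 256, 2)
        assert out_pet.data.max() == 0.0
        assert out_mask.foreground_count() == 0

    def test_hot_voxel_total_intensity_roughly_preserved(self):
        # linear upsampling should approximately conserve the (scaled) sum
        cfg = PreprocessConfig(target_inplane=30)
        data = np.zeros((20, 20, 20), dtype=np.float32)
        data[10, 10, 10] = 100.0
        pet = make_volume(data, modality=Modality.PET)
        mask = make_mask(np.zeros_like(data), kind=MaskKind.COARSE)
        out, _ = resample_pet(pet, mask, cfg)
        scale = (30 / 20) ** 2
        assert out.data.sum() == pytest.approx(data.sum() * scale, rel=0.05)

    def test_geometry_mismatch_rejected(self):
        cfg = PreprocessConfig(target_inplane=16)
        ct = make_volume(np.zeros((32, 32, 4)))
        mask = make_mask(np.zeros((32, 32, 2)))
        with pytest.raises(ValueError):
            resample_ct(ct, mask, cfg)


class TestBinarize:
    def test_rule_on_mixed_grid(self):
        values = np.array([0.0, 0.5, 0.7, 0.2]).reshape(1, 1, 4)
        out = binarize_mask(values, 0.5, (1, 1, 1), MaskKind.FINE)
        np.testing.assert_array_equal(out.data.ravel(), [0, 1, 1, 0])

    @pytest.mark.parametrize("value,expected", [(0.5, 1), (0.4999, 0), (1.0, 1), (0.0, 0)])
    def test_tie_goes_to_one(self, value, expected):
        out = binarize_mask(np.full((1, 1, 1), value), 0.5, (1, 1, 1), MaskKind.FINE)
        assert out.data[0, 0, 0] == expected

    def test_idempotent(self, rng):
        values = rng.random((6, 6, 6))
        once = binarize_mask(values, 0.5, (1, 1, 1), MaskKind.FINE)
        twice = binarize_mask(once.data.astype(float), 0.5, (1, 1, 1), MaskKind.FINE)
        np.testing.assert_array_equal(once.data, twice.data)


class TestCropAxial:
    def _tall_case(self, nz=171, centroid=90):
        case = make_case(shape=(8, 8, nz))
        fine = np.zeros((8, 8, nz), dtype=np.uint8)
        fine[2:6, 2:6, centroid - 2:centroid + 3] = 1   # z-centroid at `centroid`
        case.fine_mask.data[...] = 0
        case.fine_mask.data[...] = fine
        return case

    def test_reference_window_around_centroid(self):
        # 128-slice crop of a 171-slice case with mask centroid at z=90
        case = self._tall_case()
        cfg = PreprocessConfig(target_inplane=8, crop_slices=128)
        out = crop_axial(case, cfg)
        assert all(g.shape[2] == 128 for g in out.grids())
        # window [26, 154): the centroid slice lands at index 90-26
        assert out.fine_mask.data[:, :, 90 - 26].any()
        assert out.fine_mask.foreground_count() == case.fine_mask.foreground_count()

    def test_window_clamped_at_volume_edge(self):
        case = self._tall_case(nz=140, centroid=135)
        cfg = PreprocessConfig(target_inplane=8, crop_slices=128)
        out = crop_axial(case, cfg)
        assert out.ct.shape[2] == 128
        assert out.fine_mask.foreground_count() == case.fine_mask.foreground_count()

    def test_crop_of_crop_is_identity(self):
        case = self._tall_case()
        cfg = PreprocessConfig(target_inplane=8, crop_slices=128)
        once = crop_axial(case, cfg)
        twice = crop_axial(once, cfg)
        np.testing.assert_array_equal(once.ct.data, twice.ct.data)
        np.testing.assert_array_equal(once.fine_mask.data, twice.fine_mask.data)

    def test_too_few_slices_rejected(self):
        case = self._tall_case(nz=100, centroid=50)
        with pytest.raises(ValueError):
            crop_axial(case, PreprocessConfig(target_inplane=8, crop_slices=128))

    def test_empty_centroid_mask_rejected(self):
        case = make_case(shape=(8, 8, 140))
        case.fine_mask.data[...] = 0
        with pytest.raises(ValueError):
            crop_axial(case, PreprocessConfig(target_inplane=8, crop_slices=128))


class TestNormalize:
    def test_ct_min_max_by_hand(self):
        vol = make_volume(np.array([-100.0, 0.0, 300.0]).reshape(1, 1, 3))
        out = normalize_intensity(vol)
        np.testing.assert_allclose(out.data.ravel(), [0.0, 0.25, 1.0], atol=1e-6)

    def test_pet_divided_by_maximum(self):
        vol = make_volume(np.array([0.0, 2.0, 8.0]).reshape(1, 1, 3),
                          modality=Modality.PET)
        out = normalize_intensity(vol)
        np.testing.assert_allclose(out.data.ravel(), [0.0, 0.25, 1.0], atol=1e-6)

    def test_already_unit_interval_unchanged(self):
        data = np.array([0.0, 0.5, 1.0]).reshape(1, 1, 3)
        out = normalize_intensity(make_volume(data))
        np.testing.assert_allclose(out.data, data, atol=1e-6)

    def test_constant_volume_rejected(self):
        with pytest.raises(ValueError):
            normalize_intensity(make_volume(np.full((2, 2, 2), 5.0)))

    def test_output_in_unit_interval(self, rng):
        vol = make_volume(rng.normal(0, 300, size=(8, 8, 8)))
        out = normalize_intensity(vol)
        assert out.data.min() == pytest.approx(0.0, abs=1e-6)
        assert out.data.max() == pytest.approx(1.0, abs=1e-6)


def test_full_pipeline_common_grid():
    case = make_case(shape=(32, 32, 24))
    cfg = PreprocessConfig(target_inplane=16, crop_slices=16)
    out = preprocess_case(case, cfg)
    for g in out.grids():
        assert g.shape == (16, 16, 16)
        assert g.spacing == out.ct.spacing
    assert 0.0 <= out.ct.data.min() and out.ct.data.max() == pytest.approx(1.0, abs=1e-6)
    assert set(np.unique(out.fine_mask.data)) <= {0, 1}
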