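import numpy as np
import pytest

from petseg.approaches import (ApproachSpec, assemble_input, dilate_mask,
                               input_channels, premask_ct, run_approach)
from petseg.image_io import MaskKind, Modality
from petseg.preprocess import PreprocessConfig, preprocess_case
from petseg.unet3d import UNetConfig, build_model, predict_mask

from conftest import make_case, make_mask, make_volume


def brute_force_dilate(data, voxels):
    out = np.zeros_like(data)
    fg = np.argwhere(data)
    for (x, y, z) in fg:
        out[max(0, x - voxels):x + voxels + 1,
            max(0, y - voxels):y + voxels + 1,
            max(0, z - voxels):z + voxels + 1] = 1
    return out


class TestSpecValidation:
    @pytest.mark.parametrize("name,channels", [("A1", 1), ("A2", 1), ("A3", 2),
                                               ("A4", 2), ("A5", 1)])
    def test_channel_wiring_table(self, name, channels):
        assert input_channels(name) == channels

    def test_two_step_approaches_require_stage1(self):
        with pytest.raises(ValueError):
            ApproachSpec("A5", stage2_model="x")
        with pytest.raises(ValueError):
            ApproachSpec("A4", stage2_model="x")

    def test_single_step_approaches_forbid_stage1(self):
        with pytest.raises(ValueError):
            ApproachSpec("A1", stage2_model="x", stage1_model="y")


class TestDilateMask:
    def test_zero_radius_is_identity(self, rng):
        m = make_mask((rng.random((8, 8, 8)) > 0.7).astype(np.uint8))
        np.testing.assert_array_equal(dilate_mask(m, 0).data, m.data)

    def test_empty_mask_stays_empty(self):
        m = make_mask(np.zeros((8, 8, 8)))
        assert dilate_mask(m, 3).foreground_count() == 0

    def test_interior_voxel_radius2_cube_gives_125(self):
        data = np.zeros((9, 9, 9)); data[4, 4, 4] = 1
        out = dilate_mask(make_mask(data), 2)
        assert out.foreground_count() == 125

    def test_matches_brute_force_cube_oracle(self, rng):
        data = (rng.random((10, 10, 10)) > 0.9).astype(np.uint8)
        for v in (1, 2):
            out = dilate_mask(make_mask(data), v)
            np.testing.assert_array_equal(out.data, brute_force_dilate(data, v))

    def test_monotone_in_mask_and_radius(self, rng):
        data = (rng.random((10, 10, 10)) > 0.92).astype(np.uint8)
        m = make_mask(data)
        d1, d2 = dilate_mask(m, 1), dilate_mask(m, 2)
        assert (m.data <= d1.data).all()
        assert (d1.data <= d2.data).all()

    def test_cross_element_smaller_than_cube(self):
        data = np.zeros((9, 9, 9)); data[4, 4, 4] = 1
        cross = dilate_mask(make_mask(data), 2, structuring="cross")
        cube = dilate_mask(make_mask(data), 2, structuring="cube")
        assert 0 < cross.foreground_count() < cube.foreground_count()


class TestPremaskCt:
    def test_all_ones_mask_is_identity(self, rng):
        ct = make_volume(rng.normal(size=(8, 8, 8)))
        m = make_mask(np.ones((8, 8, 8)), kind=MaskKind.COARSE)
        out = premask_ct(ct, m, 2)
        np.testing.assert_array_equal(out.data, ct.data)
        assert out.modality is Modality.MASKED_CT

    def test_all_zeros_mask_zeroes_everything(self, rng):
        ct = make_volume(rng.normal(size=(8, 8, 8)))
        m = make_mask(np.zeros((8, 8, 8)), kind=MaskKind.COARSE)
        assert (premask_ct(ct, m, 2).data == 0).all()

    def test_intensities_inside_dilation_unchanged_outside_zero(self, rng):
        ct = make_volume(rng.normal(size=(12, 12, 12)) + 10)
        data = np.zeros((12, 12, 12)); data[5:7, 5:7, 5:7] = 1
        m = make_mask(data, kind=MaskKind.COARSE)
        out = premask_ct(ct, m, 2)
        dil = dilate_mask(m, 2).data.astype(bool)
        np.testing.assert_array_equal(out.data[dil], ct.data[dil])
        assert (out.data[~dil] == 0).all()

    def test_geometry_mismatch_rejected(self, rng):
        ct = make_volume(rng.normal(size=(8, 8, 8)))
        m = make_mask(np.zeros((8, 8, 4)), kind=MaskKind.COARSE)
        with pytest.raises(ValueError):
            premask_ct(ct, m, 2)


@pytest.fixture
def prepped_case():
    case = make_case(shape=(16, 16, 8))
    return preprocess_case(case, PreprocessConfig(target_inplane=16, crop_slices=8))


class TestAssembleInput:
    def test_a1_is_ct_passthrough(self, prepped_case):
        x = assemble_input(ApproachSpec("A1", stage2_model="x"), prepped_case)
        np.testing.assert_array_equal(x[0], prepped_case.ct.data)
        assert x.shape[0] == 1

    def test_a3_stacks_ct_then_pet(self, prepped_case):
        x = assemble_input(ApproachSpec("A3", stage2_model="x"), prepped_case)
        np.testing.assert_array_equal(x[0], prepped_case.ct.data)
        np.testing.assert_array_equal(x[1], prepped_case.pet.data)

    def test_a4_second_channel_is_binary_mask(self, prepped_case):
        spec = ApproachSpec("A4", stage2_model="x", stage1_model="y")
        x = assemble_input(spec, prepped_case, prepped_case.coarse_mask)
        assert set(np.unique(x[1])) <= {0.0, 1.0}

    def test_a5_zero_outside_dilated_coarse(self, prepped_case):
        spec = ApproachSpec("A5", stage2_model="x", stage1_model="y", dilation_voxels=2)
        x = assemble_input(spec, prepped_case, prepped_case.coarse_mask)
        outside = ~dilate_mask(prepped_case.coarse_mask, 2).data.astype(bool)
        assert (x[0][outside] == 0).all()

    def test_missing_coarse_for_two_step_rejected(self, prepped_case):
        spec = ApproachSpec("A5", stage2_model="x", stage1_model="y")
        with pytest.raises(ValueError):
            assemble_input(spec, prepped_case)


class TestRunApproach:
    def _models(self):
        one = build_model(UNetConfig(in_channels=1, depth=2, base_channels=3, init_seed=0))
        return one

    def test_a5_equals_manual_two_stage_composition(self, prepped_case):
        stage1 = build_model(UNetConfig(in_channels=1, depth=2, base_channels=3, init_seed=1))
        stage2 = build_model(UNetConfig(in_channels=1, depth=2, base_channels=3, init_seed=2))
        spec = ApproachSpec("A5", stage2_model=stage2, stage1_model=stage1)
        end_to_end = run_approach(spec, prepped_case)
        # manual composition: predict coarse, premask, predict fine
        coarse = predict_mask(stage1, prepped_case.pet.data[None],
                              prepped_case.pet.spacing, kind=MaskKind.COARSE)
        x = assemble_input(spec, prepped_case, coarse)
        manual = predict_mask(stage2, x, prepped_case.ct.spacing)
        np.testing.assert_array_equal(end_to_end.data, manual.data)

    def test_a2_returns_coarse_kind(self, prepped_case):
        spec = ApproachSpec("A2", stage2_model=self._models())
        out = run_approach(spec, prepped_case)
        assert out.kind is MaskKind.COARSE
        assert out.shape == prepped_case.pet.shape

    def test_checkpoint_path_accepted_as_model(self, prepped_case, tmp_path):
        from petseg.unet3d import save_checkpoint
        model = self._models()
        save_checkpoint(model, tmp_path / "m.npz")
        spec = ApproachSpec("A1", stage2_model=str(tmp_path / "m.npz"))
        out = run_approach(spec, prepped_case)
        ref = run_approach(ApproachSpec("A1", stage2_model=model), prepped_case)
        np.testing.assert_array_equal(out.data, ref.data)
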