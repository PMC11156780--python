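import numpy as np
import pytest

from petseg.image_io import BinaryMask3D, MaskKind, Modality, PatientCase, Tracer, VolumeGrid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_mask(data, spacing=(1.0, 1.0, 1.0), kind=MaskKind.FINE):
    return BinaryMask3D(np.asarray(data, dtype=np.uint8), spacing, kind)


def make_volume(data, spacing=(1.0, 1.0, 1.0), modality=Modality.CT):
    return VolumeGrid(np.asarray(data, dtype=np.float32), spacing, modality)


def make_case(shape=(16, 16, 8), spacing=(1.0, 1.0, 1.0), case_id="t-000", seed=0):
    """Small hand-built case: a bright box 'kidney' on both sides."""
    rng = np.random.default_rng(seed)
    ct = np.full(shape, 30.0, dtype=np.float32)
    fine = np.zeros(shape, dtype=np.uint8)
    pet = np.full(shape, 0.2, dtype=np.float32)
    nx, ny, nz = shape
    for x0 in (nx // 8, 5 * nx // 8):
        sl = np.s_[x0:x0 + nx // 4, ny // 4:3 * ny // 4, nz // 4:3 * nz // 4]
        ct[sl] = 140.0
        pet[sl] = 10.0
        fine[sl] = 1
    ct += rng.normal(0, 5, shape).astype(np.float32)
    coarse = fine.copy()
    return PatientCase(
        case_id=case_id,
        ct=make_volume(ct, spacing, Modality.CT),
        pet=make_volume(pet, spacing, Modality.PET),
        fine_mask=make_mask(fine, spacing, MaskKind.FINE),
        coarse_mask=make_mask(coarse, spacing, MaskKind.COARSE),
        tracer=Tracer.GA68,
    )
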