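"""The five input-fusion strategies for u-net kidney segmentation.

    A1: CT image                      -> fine segmentation
    A2: PET image                     -> coarse segmentation
    A3: CT + PET (2 channels)         -> fine segmentation
    A4: CT + coarse mask (2 channels) -> fine segmentation (stage 2)
    A5: CT pre-segmented (voxelwise-multiplied) by the coarse mask, enlarged
        by 2 voxels along each axis    -> fine segmentation (stage 2)

A4 and A5 are two-step approaches and are not trained end-to-end: stage 1 is
the A2 network (PET -> coarse mask); at inference its prediction feeds
stage 2, while stage-2 training uses the manual coarse mask.  The mask
enlargement prevents kidney tissue just outside the coarse PET uptake region
from being cut off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image_io import BinaryMask3D, MaskKind, Modality, PatientCase, VolumeGrid
from .unet3d import UNet3D, load_checkpoint, predict_mask

__all__ = ["APPROACH_NAMES", "ApproachSpec", "input_channels", "assemble_input",
           "dilate_mask", "premask_ct", "run_approach"]

APPROACH_NAMES = ("A1", "A2", "A3", "A4", "A5")

_CHANNELS = {"A1": 1, "A2": 1, "A3": 2, "A4": 2, "A5": 1}


def input_channels(name: str) -> int:
    """Stage-2 input channel count of an approach."""
    return _CHANNELS[name]


def _resolve(model) -> UNet3D | None:
    if model is None or isinstance(model, UNet3D):
        return model
    loaded, _ = load_checkpoint(model)
    return loaded


@dataclass
class ApproachSpec:
    name: str
    stage2_model: object = None          # UNet3D or checkpoint path
    stage1_model: object = None          # PET coarse net; required for A4/A5
    dilation_voxels: int = 2
    structuring: str = "cube"            # "cube" | "cross"
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.name not in APPROACH_NAMES:
            raise ValueError(f"unknown approach {self.name!r}")
        if self.name in ("A4", "A5"):
            if self.stage1_model is None:
                raise ValueError(f"{self.name} requires a stage-1 (A2) model")
        elif self.stage1_model is not None:
            raise ValueError(f"{self.name} takes no stage-1 model")
        if self.dilation_voxels < 0:
            raise ValueError("dilation_voxels must be >= 0")


def _structure(voxels: int, kind: str) -> np.ndarray:
    if kind == "cube":
        return np.ones((2 * voxels + 1,) * 3, dtype=bool)
    if kind == "cross":
        return ndimage.iterate_structure(
            ndimage.generate_binary_structure(3, 1), voxels)
    raise ValueError(f"unknown structuring element {kind!r}")


def dilate_mask(mask: BinaryMask3D, voxels: int, structuring: str = "cube") -> BinaryMask3D:
    """Morphological dilation; the default cubic element of half-width
    ``voxels`` enlarges the mask by that many voxels along every axis."""
    if voxels < 0:
        raise ValueError("voxels must be >= 0")
    if voxels == 0 or mask.data.sum() == 0:
        return mask.with_data(mask.data.copy())
    out = ndimage.binary_dilation(mask.data.astype(bool),
                                  structure=_structure(voxels, structuring))
    return mask.with_data(out.astype(np.uint8))


def premask_ct(ct: VolumeGrid, coarse: BinaryMask3D, voxels: int = 2,
               structuring: str = "cube") -> VolumeGrid:
    """Zero every CT voxel outside the dilated coarse mask (voxelwise
    multiplication); intensities inside are untouched."""
    if not coarse.matches_geometry(ct):
        raise ValueError("CT and coarse mask must share geometry")
    dilated = dilate_mask(coarse, voxels, structuring)
    return ct.with_data(ct.data * dilated.data, modality=Modality.MASKED_CT)


def assemble_input(spec: ApproachSpec, case: PatientCase,
                   coarse: BinaryMask3D | None = None) -> np.ndarray:
    """Stack the (C, X, Y, Z) network input for an approach.

    ``coarse`` is the coarse mask to wire in for A4/A5 stage 2 (ground truth
    during training, the A2 prediction at inference); it must be absent for
    A1-A3.
    """
    if spec.name in ("A4", "A5"):
        if coarse is None:
            raise ValueError(f"{spec.name} stage 2 requires a coarse mask")
    elif coarse is not None:
        raise ValueError(f"{spec.name} takes no coarse mask input")
    ct = case.ct.data[None]
    pet = case.pet.data[None]
    if spec.name == "A1":
        return ct
    if spec.name == "A2":
        return pet
    if spec.name == "A3":
        return np.concatenate([ct, pet], axis=0)
    if spec.name == "A4":
        return np.concatenate([ct, coarse.data[None].astype(np.float32)], axis=0)
    # A5
    masked = premask_ct(case.ct, coarse, spec.dilation_voxels, spec.structuring)
    return masked.data[None]


def run_approach(spec: ApproachSpec, case: PatientCase) -> BinaryMask3D:
    """End-to-end inference for one preprocessed case.

    A4/A5 first run the stage-1 (A2) network on the PET to predict the coarse
    mask, then stage 2 on the assembled input.  Returns the binarized fine
    mask (the coarse mask for A2).
    """
    stage2 = _resolve(spec.stage2_model)
    if stage2 is None:
        raise ValueError("spec.stage2_model is required to run an approach")
    coarse = None
    if spec.name in ("A4", "A5"):
        stage1 = _resolve(spec.stage1_model)
        coarse = predict_mask(stage1, case.pet.data[None], case.pet.spacing,
                              threshold=spec.threshold, kind=MaskKind.COARSE)
    x = assemble_input(spec, case, coarse)
    kind = MaskKind.COARSE if spec.name == "A2" else MaskKind.FINE
    return predict_mask(stage2, x, case.ct.spacing, threshold=spec.threshold, kind=kind)
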