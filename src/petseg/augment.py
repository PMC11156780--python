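"""Randomized training/validation augmentation.

Each augmented copy applies one shared spatial transform to CT, PET and both
masks (zoom 0.8-1.2, rotation about the longitudinal z-axis within +/-7.5
degrees, an integer voxel shift of magnitude 1-5 per axis with random sign,
and random axial/sagittal flips), plus a Hounsfield-unit shift of +/-7.5 HU
applied to the CT only.  The HU shift happens in HU space, i.e. before any
[0,1] normalization.  Masks are re-binarized at 0.5 after interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .image_io import BinaryMask3D, PatientCase

__all__ = ["AugmentConfig", "augment_case", "expand_split"]


@dataclass
class AugmentConfig:
    zoom_range: tuple[float, float] = (0.8, 1.2)
    rotation_deg_range: tuple[float, float] = (-7.5, 7.5)
    shift_voxels_range: tuple[int, int] = (1, 5)
    flip_probability: float = 0.5          # per listed axis (axial, sagittal)
    hu_shift_range: tuple[float, float] = (-7.5, 7.5)
    copies_per_case: int = 9
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.zoom_range[0] <= self.zoom_range[1]):
            raise ValueError("zoom_range must be positive and ordered")
        if self.copies_per_case < 0:
            raise ValueError("copies_per_case must be >= 0")


def _draw_params(cfg: AugmentConfig, rng: np.random.Generator) -> dict:
    lo, hi = cfg.shift_voxels_range
    shift = rng.integers(lo, hi + 1, size=3) * rng.choice([-1, 1], size=3)
    return {
        "zoom": float(rng.uniform(*cfg.zoom_range)),
        "rotation_deg": float(rng.uniform(*cfg.rotation_deg_range)),
        "shift": tuple(int(s) for s in shift),
        "flip_sagittal": bool(rng.random() < cfg.flip_probability),  # x axis
        "flip_axial": bool(rng.random() < cfg.flip_probability),     # z axis
        "hu_shift": float(rng.uniform(*cfg.hu_shift_range)),
    }


def _affine_zoom_rotate(data: np.ndarray, zoom: float, rotation_deg: float,
                        cval: float) -> np.ndarray:
    """Single-interpolation zoom about the center composed with an in-plane
    rotation about the z axis (output grid = input grid)."""
    if zoom == 1.0 and rotation_deg == 0.0:
        return np.asarray(data, dtype=np.float32)
    theta = np.deg2rad(rotation_deg)
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    # output -> input mapping: inverse rotation then inverse zoom
    matrix = rot.T / zoom
    center = (np.array(data.shape) - 1) / 2.0
    offset = center - matrix @ center
    return ndimage.affine_transform(data.astype(np.float32), matrix, offset=offset,
                                    order=1, mode="constant", cval=cval)


def _integer_shift(data: np.ndarray, shift: tuple[int, int, int], cval: float) -> np.ndarray:
    out = np.full_like(data, cval)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax, sh in enumerate(shift):
        n = data.shape[ax]
        if abs(sh) >= n:
            return out
        if sh >= 0:
            dst[ax], src[ax] = slice(sh, n), slice(0, n - sh)
        else:
            dst[ax], src[ax] = slice(0, n + sh), slice(-sh, n)
    out[tuple(dst)] = data[tuple(src)]
    return out


def _apply_spatial(data: np.ndarray, p: dict, cval: float) -> np.ndarray:
    out = _affine_zoom_rotate(data, p["zoom"], p["rotation_deg"], cval)
    out = _integer_shift(out, p["shift"], cval)
    if p["flip_sagittal"]:
        out = out[::-1, :, :]
    if p["flip_axial"]:
        out = out[:, :, ::-1]
    return np.ascontiguousarray(out)


def _transform_mask(mask: BinaryMask3D, p: dict) -> BinaryMask3D:
    values = _apply_spatial(mask.data.astype(np.float32), p, 0.0)
    return mask.with_data((values >= 0.5).astype(np.uint8))


def augment_case(case: PatientCase, cfg: AugmentConfig,
                 draw: np.random.Generator) -> PatientCase:
    """One augmented copy; the same transform parameters drive all four grids.

    Out-of-field voxels are filled with the CT's minimum (air-like) or with 0
    for PET and masks.  Expects an un-normalized (HU-space) CT.
    """
    p = _draw_params(cfg, draw)
    ct_fill = float(case.ct.data.min())
    ct = case.ct.with_data(_apply_spatial(case.ct.data, p, ct_fill) + p["hu_shift"])
    pet = case.pet.with_data(_apply_spatial(case.pet.data, p, 0.0))
    return replace(
        case,
        case_id=f"{case.case_id}",
        ct=ct,
        pet=pet,
        fine_mask=_transform_mask(case.fine_mask, p),
        coarse_mask=_transform_mask(case.coarse_mask, p),
    )


def expand_split(cases: list[PatientCase], cfg: AugmentConfig) -> list[PatientCase]:
    """Return the originals plus ``copies_per_case`` augmented versions each,
    i.e. n * (copies_per_case + 1) cases; deterministic given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    out: list[PatientCase] = []
    for case in cases:
        out.append(case)
        for k in range(cfg.copies_per_case):
            aug = augment_case(case, cfg, rng)
            out.append(replace(aug, case_id=f"{case.case_id}-aug{k + 1}"))
    return out
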