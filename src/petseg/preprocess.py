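"""Common-grid preprocessing: resampling, axial cropping, normalization.

Reference pipeline: CT in-plane resolution is halved (512 -> 256), PET is
linearly interpolated up to the same matrix (200 -> 256), masks are
re-binarized at 0.5 (ties go to 1), a 128-slice axial window centered on the
kidneys is cut out, and each volume is scaled to [0, 1].
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .image_io import BinaryMask3D, Modality, PatientCase, VolumeGrid

__all__ = [
    "CropCenterPolicy",
    "PreprocessConfig",
    "resample_ct",
    "resample_pet",
    "resample_z",
    "binarize_mask",
    "crop_axial",
    "normalize_intensity",
    "preprocess_case",
]


class CropCenterPolicy(str, enum.Enum):
    FINE_MASK_CENTROID = "FINE_MASK_CENTROID"
    COARSE_MASK_CENTROID = "COARSE_MASK_CENTROID"
    EXPLICIT = "EXPLICIT"


@dataclass
class PreprocessConfig:
    target_inplane: int = 256
    crop_slices: int = 128
    binarize_threshold: float = 0.5
    crop_center_policy: CropCenterPolicy = CropCenterPolicy.FINE_MASK_CENTROID
    explicit_center_z: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.binarize_threshold < 1:
            raise ValueError("binarize_threshold must lie strictly in (0, 1)")
        if self.crop_slices < 1:
            raise ValueError("crop_slices must be >= 1")
        if self.target_inplane < 8:
            raise ValueError("target_inplane must be >= 8")
        self.crop_center_policy = CropCenterPolicy(self.crop_center_policy)


def binarize_mask(values: np.ndarray, threshold: float, spacing, kind) -> BinaryMask3D:
    """Threshold interpolated mask values: >= threshold -> 1, below -> 0."""
    values = np.asarray(values)
    if not np.isfinite(values).all():
        raise ValueError("mask values must be finite before binarization")
    return BinaryMask3D(data=(values >= threshold).astype(np.uint8),
                        spacing=spacing, kind=kind)


def _resample_inplane(data: np.ndarray, target: int) -> np.ndarray:
    nx, ny, _ = data.shape
    zoom = (target / nx, target / ny, 1.0)
    out = ndimage.zoom(data.astype(np.float32), zoom, order=1, mode="nearest",
                       grid_mode=True)
    # grid_mode=True treats the array as nx cells of equal extent, so the
    # physical field of view is preserved; guard the rounding of the shape.
    assert out.shape[0] == target and out.shape[1] == target
    return out


def _resampled_spacing(spacing, old_shape, new_shape):
    return tuple(s * o / n for s, o, n in zip(spacing, old_shape, new_shape))


def _resample_pair(vol: VolumeGrid, mask: BinaryMask3D, cfg: PreprocessConfig):
    if not mask.matches_geometry(vol):
        raise ValueError("volume and mask must share geometry before resampling")
    new_data = _resample_inplane(vol.data, cfg.target_inplane)
    new_spacing = _resampled_spacing(vol.spacing, vol.shape, new_data.shape)
    new_vol = vol.with_data(new_data, spacing=new_spacing)
    mask_values = _resample_inplane(mask.data.astype(np.float32), cfg.target_inplane)
    new_mask = binarize_mask(mask_values, cfg.binarize_threshold, new_spacing, mask.kind)
    return new_vol, new_mask


def resample_ct(ct: VolumeGrid, fine_mask: BinaryMask3D, cfg: PreprocessConfig):
    """Halve (or generally resample) the CT in-plane matrix to the target size;
    z is untouched. The fine mask follows the identical transform and is
    re-binarized."""
    if ct.shape[0] < cfg.target_inplane or ct.shape[1] < cfg.target_inplane:
        raise ValueError("CT in-plane dimensions must be >= target_inplane")
    return _resample_pair(ct, fine_mask, cfg)


def resample_pet(pet: VolumeGrid, coarse_mask: BinaryMask3D, cfg: PreprocessConfig):
    """Linearly interpolate the PET (typically 200 -> 256 in-plane) and its
    coarse mask onto the target in-plane matrix."""
    return _resample_pair(pet, coarse_mask, cfg)


def resample_z(data: np.ndarray, target_nz: int) -> np.ndarray:
    """Linear z-resampling used when CT and PET slice counts differ."""
    if data.shape[2] == target_nz:
        return np.asarray(data, dtype=np.float32)
    zoom = (1.0, 1.0, target_nz / data.shape[2])
    return ndimage.zoom(data.astype(np.float32), zoom, order=1, mode="nearest",
                        grid_mode=True)


def _crop_window(center_z: int, nz: int, crop: int) -> tuple[int, int]:
    start = center_z - crop // 2
    start = max(0, min(start, nz - crop))
    return start, start + crop


def _mask_centroid_z(mask: BinaryMask3D) -> int:
    if mask.foreground_count() == 0:
        raise ValueError("crop-center mask is empty; cannot derive a centroid")
    zs = np.nonzero(mask.data)[2]
    return int(round(zs.mean()))


def crop_axial(case: PatientCase, cfg: PreprocessConfig) -> PatientCase:
    """Cut a fixed-length axial window (default 128 slices) centered on the
    kidney region out of all four grids; the window is clamped to the volume."""
    case.validate_common_grid()
    nz = case.ct.shape[2]
    if nz < cfg.crop_slices:
        raise ValueError(f"z-dimension {nz} smaller than crop_slices {cfg.crop_slices}")
    ref_mask = None
    if cfg.crop_center_policy is CropCenterPolicy.FINE_MASK_CENTROID:
        ref_mask = case.fine_mask
        center = _mask_centroid_z(ref_mask)
    elif cfg.crop_center_policy is CropCenterPolicy.COARSE_MASK_CENTROID:
        ref_mask = case.coarse_mask
        center = _mask_centroid_z(ref_mask)
    else:
        if cfg.explicit_center_z is None:
            raise ValueError("EXPLICIT crop policy requires explicit_center_z")
        center = int(cfg.explicit_center_z)
    lo, hi = _crop_window(center, nz, cfg.crop_slices)
    if ref_mask is not None:
        # shift the window so the reference mask's z-extent is fully inside,
        # whenever that extent fits in crop_slices at all
        zs = np.nonzero(ref_mask.data)[2]
        zmin, zmax = int(zs.min()), int(zs.max())
        if zmax - zmin + 1 <= cfg.crop_slices:
            lo = min(max(lo, zmax + 1 - cfg.crop_slices), zmin)
            lo = max(0, min(lo, nz - cfg.crop_slices))
            hi = lo + cfg.crop_slices
    sl = np.s_[:, :, lo:hi]
    return replace(
        case,
        ct=case.ct.with_data(case.ct.data[sl]),
        pet=case.pet.with_data(case.pet.data[sl]),
        fine_mask=case.fine_mask.with_data(case.fine_mask.data[sl]),
        coarse_mask=case.coarse_mask.with_data(case.coarse_mask.data[sl]),
    )


def normalize_intensity(vol: VolumeGrid) -> VolumeGrid:
    """Scale a volume to [0, 1].

    PET (non-negative physical signal): clamp below at 0, divide by the
    maximum.  CT (can be negative in HU): min-max scaling, which is the only
    reading under which the stated [0, 1] interval is attainable.  No HU
    clipping is applied beforehand.
    """
    data = vol.data.astype(np.float32)
    if np.isclose(data.min(), data.max()):
        raise ValueError("constant volume cannot be normalized to [0, 1]")
    if vol.modality is Modality.PET:
        data = np.clip(data, 0.0, None)
        peak = data.max()
        if peak <= 0:
            raise ValueError("PET volume has no positive signal")
        out = data / peak
    else:
        lo, hi = data.min(), data.max()
        out = (data - lo) / (hi - lo)
    return vol.with_data(out, intensity_units="normalized")


def preprocess_case(case: PatientCase, cfg: PreprocessConfig | None = None,
                    normalize: bool = True) -> PatientCase:
    """Full per-case pipeline: in-plane resampling of CT and PET, z matching,
    axial crop, optional [0,1] normalization.

    When CT and PET already share a grid (the synthetic-phantom path) the
    resampling steps are skipped unless the in-plane size differs from the
    target.  The preprocessed case carries the CT-derived spacing.
    """
    cfg = cfg or PreprocessConfig()
    ct, fine = case.ct, case.fine_mask
    pet, coarse = case.pet, case.coarse_mask
    if ct.shape[0] != cfg.target_inplane or ct.shape[1] != cfg.target_inplane:
        ct, fine = resample_ct(ct, fine, cfg)
    if pet.shape[0] != cfg.target_inplane or pet.shape[1] != cfg.target_inplane:
        pet, coarse = resample_pet(pet, coarse, cfg)
    if pet.shape[2] != ct.shape[2]:
        pet = pet.with_data(resample_z(pet.data, ct.shape[2]), spacing=ct.spacing)
        coarse = binarize_mask(resample_z(coarse.data.astype(np.float32), ct.shape[2]),
                               cfg.binarize_threshold, ct.spacing, coarse.kind)
    # canonical spacing: CT's
    pet = replace(pet, spacing=ct.spacing)
    coarse = replace(coarse, spacing=ct.spacing)
    fine = replace(fine, spacing=ct.spacing)
    out = replace(case, ct=ct, pet=pet, fine_mask=fine, coarse_mask=coarse)
    if out.ct.shape[2] != cfg.crop_slices:
        out = crop_axial(out, cfg)
    if normalize:
        out = replace(out, ct=normalize_intensity(out.ct), pet=normalize_intensity(out.pet))
    out.validate_common_grid()
    return out
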