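"""Volume and mask containers plus NIfTI round-trip I/O.

All pipeline stages exchange :class:`VolumeGrid` / :class:`BinaryMask3D`
objects.  The internal axis order is (x: left-right, y: anterior-posterior,
z: inferior-superior); "slices" are z-planes.  Header voxel spacing is
authoritative and is carried through every operation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "Modality",
    "MaskKind",
    "Tracer",
    "VolumeGrid",
    "BinaryMask3D",
    "PatientCase",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_dicom_series",
]


class Modality(str, enum.Enum):
    CT = "CT"
    PET = "PET"
    MASKED_CT = "MASKED_CT"


class MaskKind(str, enum.Enum):
    FINE = "FINE"
    COARSE = "COARSE"


class Tracer(str, enum.Enum):
    """PSMA radiopharmaceutical label: [68Ga]Ga-PSMA-I&T or [18F]F-PSMA-1007."""

    GA68 = "GA68"
    F18 = "F18"


def _check_geometry(data: np.ndarray, spacing: tuple[float, float, float]) -> None:
    if data.ndim != 3:
        raise ValueError(f"expected a 3D grid, got ndim={data.ndim}")
    if any(s < 1 for s in data.shape):
        raise ValueError(f"every dimension must be >= 1, got shape {data.shape}")
    if len(spacing) != 3 or any(not (s > 0) for s in spacing):
        raise ValueError(f"spacing must be three strictly positive values, got {spacing}")


@dataclass
class VolumeGrid:
    """A 3D scalar image with physical voxel spacing in mm.

    ``intensity_units`` is Hounsfield units for CT and arbitrary
    activity-concentration units for PET.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    modality: Modality
    intensity_units: str = field(default="")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        self.modality = Modality(self.modality)
        self.spacing = tuple(float(s) for s in self.spacing)
        _check_geometry(self.data, self.spacing)
        if not self.intensity_units:
            self.intensity_units = "HU" if self.modality is Modality.CT else "arbitrary-activity"

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray, **kw) -> "VolumeGrid":
        return replace(self, data=data, **kw)


@dataclass
class BinaryMask3D:
    """A {0,1} label grid sharing a :class:`VolumeGrid`'s geometry.

    ``kind`` distinguishes the detailed CT-based kidney segmentation (FINE:
    cortex + medulla, excluding renal pelvis, vessels and cysts) from the
    coarse PET-uptake-based one (COARSE).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    kind: MaskKind

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        values = np.unique(data)
        if not np.isin(values, (0, 1)).all():
            raise ValueError("mask voxels must be exactly 0 or 1")
        self.data = data.astype(np.uint8)
        self.kind = MaskKind(self.kind)
        self.spacing = tuple(float(s) for s in self.spacing)
        _check_geometry(self.data, self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def matches_geometry(self, other) -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)

    def with_data(self, data: np.ndarray, **kw) -> "BinaryMask3D":
        return replace(self, data=data, **kw)

    def foreground_count(self) -> int:
        return int(self.data.sum())


@dataclass
class PatientCase:
    """One subject: co-registered CT and PET plus both ground-truth masks."""

    case_id: str
    ct: VolumeGrid
    pet: VolumeGrid
    fine_mask: BinaryMask3D
    coarse_mask: BinaryMask3D
    tracer: Tracer

    def __post_init__(self) -> None:
        self.tracer = Tracer(self.tracer)

    def grids(self):
        return (self.ct, self.pet, self.fine_mask, self.coarse_mask)

    def validate_common_grid(self) -> None:
        """After preprocessing all four grids must share dimensions."""
        shapes = {g.shape for g in self.grids()}
        if len(shapes) != 1:
            raise ValueError(f"case {self.case_id}: grids do not share dimensions: {shapes}")


def _affine_from_spacing(spacing) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    return aff


def _spacing_from_img(img, path) -> tuple[float, float, float]:
    zooms = img.header.get_zooms()[:3]
    if len(zooms) < 3 or any(z <= 0 or not np.isfinite(z) for z in zooms):
        raise ValueError(f"{path}: missing or invalid voxel spacing in header")
    return tuple(float(z) for z in zooms)


def read_volume(path, modality: Modality | str) -> VolumeGrid:
    """Read a NIfTI volume; header spacing is taken as-is (no rescaling
    beyond nibabel's scl_slope/scl_inter application)."""
    path = Path(path)
    if path.is_dir():
        return read_dicom_series(path, modality)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float32)
    return VolumeGrid(data=data, spacing=_spacing_from_img(img, path), modality=Modality(modality))


def write_volume(vol: VolumeGrid, path) -> None:
    img = nib.Nifti1Image(vol.data.astype(np.float32), _affine_from_spacing(vol.spacing))
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def read_mask(path, kind: MaskKind | str) -> BinaryMask3D:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    return BinaryMask3D(data=(data >= 0.5).astype(np.uint8),
                        spacing=_spacing_from_img(img, path), kind=MaskKind(kind))


def write_mask(mask: BinaryMask3D, path) -> None:
    """Masks are stored losslessly as unsigned 8-bit NIfTI."""
    img = nib.Nifti1Image(mask.data.astype(np.uint8), _affine_from_spacing(mask.spacing))
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def read_dicom_series(directory, modality: Modality | str) -> VolumeGrid:
    """Optional DICOM-series reader; converts to the same VolumeGrid carrier."""
    try:
        import SimpleITK as sitk
    except ImportError as exc:  # pragma: no cover
        raise ImportError("DICOM reading requires SimpleITK") from exc
    reader = sitk.ImageSeriesReader()
    files = reader.GetGDCMSeriesFileNames(str(directory))
    if not files:
        raise IOError(f"no DICOM series found in {directory}")
    reader.SetFileNames(files)
    img = reader.Execute()
    # SimpleITK arrays come back (z, y, x); transpose to the internal (x, y, z).
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0).astype(np.float32)
    return VolumeGrid(data=data, spacing=tuple(img.GetSpacing()), modality=Modality(modality))
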