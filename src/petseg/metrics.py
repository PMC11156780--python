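"""Segmentation evaluation metrics: Dice score, average Hausdorff distance,
volume deviation, and the per-kidney (left/right) split.

AHD is computed between the physical-coordinate point sets of ALL foreground
voxel centers of the two masks (not surfaces): with sets A (size N) and B
(size M),

    AHD(A, B) = [ (1/N) sum_a min_b ||a-b||_2
                + (1/M) sum_b min_a ||b-a||_2 ] / 2   (in mm).

Voxel centers sit at (index + 0.5) * spacing per axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .image_io import BinaryMask3D

__all__ = ["KidneyMetricRecord", "dice_score", "average_hausdorff",
           "volume_deviation", "split_kidneys", "evaluate_pair"]


@dataclass
class KidneyMetricRecord:
    case_id: str
    side: str                 # "left" | "right"
    dsc: float
    vd_percent: float
    ahd_mm: float
    approach: str = ""

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        if not (0.0 <= self.dsc <= 1.0 and self.vd_percent >= 0.0 and self.ahd_mm >= 0.0):
            raise ValueError("metric values out of range")


def _check_pair(x: BinaryMask3D, y: BinaryMask3D) -> None:
    if x.shape != y.shape:
        raise ValueError(f"mask shapes differ: {x.shape} vs {y.shape}")


def dice_score(x: BinaryMask3D, y: BinaryMask3D) -> float:
    """2|X∩Y| / (|X|+|Y|): 1 = perfect overlap, 0 = none."""
    _check_pair(x, y)
    sx, sy = int(x.data.sum()), int(y.data.sum())
    if sx + sy == 0:
        raise ValueError("Dice score undefined for two empty masks")
    inter = int((x.data & y.data).sum())
    return 2.0 * inter / (sx + sy)


def _foreground_points(mask: BinaryMask3D) -> np.ndarray:
    idx = np.argwhere(mask.data)
    return (idx + 0.5) * np.asarray(mask.spacing)


def average_hausdorff(x: BinaryMask3D, y: BinaryMask3D) -> float:
    """Symmetrized mean nearest-neighbor distance in mm between the foreground
    voxel-center point sets of the two masks."""
    _check_pair(x, y)
    if x.data.sum() == 0 or y.data.sum() == 0:
        raise ValueError("average Hausdorff distance undefined for an empty mask")
    a = _foreground_points(x)
    b = _foreground_points(y)
    d_ab = cKDTree(b).query(a, k=1)[0]
    d_ba = cKDTree(a).query(b, k=1)[0]
    return float((d_ab.mean() + d_ba.mean()) / 2.0)


def volume_deviation(x: BinaryMask3D, y: BinaryMask3D) -> float:
    """|vol(x) - vol(y)| / vol(y) * 100, with y the reference mask."""
    _check_pair(x, y)
    sy = int(y.data.sum())
    if sy == 0:
        raise ValueError("volume deviation undefined for an empty reference mask")
    return abs(int(x.data.sum()) - sy) / sy * 100.0


def split_kidneys(mask: BinaryMask3D) -> tuple[BinaryMask3D, BinaryMask3D]:
    """Partition the foreground by the volume's mid-sagittal plane.

    The first axis runs right-to-left in patient terms, so the upper half of
    the x index range is the patient-left side.  Returns (left, right); either
    side may be empty (e.g. a patient with a single kidney).
    """
    nx = mask.shape[0]
    half = nx // 2
    left = np.zeros_like(mask.data)
    right = np.zeros_like(mask.data)
    left[half:] = mask.data[half:]
    right[:half] = mask.data[:half]
    return mask.with_data(left), mask.with_data(right)


def evaluate_pair(predicted: BinaryMask3D, reference: BinaryMask3D, case_id: str,
                  approach: str = "") -> list[KidneyMetricRecord]:
    """Per-kidney DSC/VD/AHD of a predicted mask against the reference.

    Sides where either mask is empty are skipped (the metrics are undefined
    there), mirroring evaluation on patients with an absent kidney.
    """
    records = []
    pred_sides = split_kidneys(predicted)
    ref_sides = split_kidneys(reference)
    for side, p, r in zip(("left", "right"), pred_sides, ref_sides):
        if p.data.sum() == 0 or r.data.sum() == 0:
            continue
        records.append(KidneyMetricRecord(
            case_id=case_id, side=side, approach=approach,
            dsc=dice_score(p, r),
            vd_percent=volume_deviation(p, r),
            ahd_mm=average_hausdorff(p, r),
        ))
    return records
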