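"""Synthetic co-registered PET/CT abdominal phantoms with ground-truth masks.

Each case contains up to two kidneys (axis-aligned ellipsoids with a medial
hilum indentation and a carved renal-pelvis region), optional cortical cysts,
and an optional liver/spleen-like adjacent organ touching a kidney.  The
deliberately built-in confounders mirror the failure modes of CT-only
segmentation:

* cysts have near-kidney CT intensity but background-level ("cold") PET
  uptake, so only the PET can cheaply exclude them;
* the adjacent organ has CT intensity close to the kidney but clearly lower
  tracer uptake.

Two ground-truth masks are emitted per case: the fine CT-style mask (kidney
tissue minus pelvis and cysts) and the coarse PET-style mask (supra-threshold
uptake region of the kidneys, excluding adjacent organs).  The PET is the
noiseless uptake map blurred with a Gaussian point-spread function plus noise;
the CT adds Gaussian noise to the piecewise-constant intensity map.

Geometry parameters are fractions of the field of view, so phantoms scale
consistently from tiny test grids to the default desk grid (64x64x32 at
2x2x5 mm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .image_io import (BinaryMask3D, MaskKind, Modality, PatientCase, Tracer,
                       VolumeGrid)

__all__ = ["PhantomParams", "generate_case", "generate_cohort", "split_cohort"]


@dataclass
class PhantomParams:
    grid_shape: tuple[int, int, int] = (64, 64, 32)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 5.0)
    kidney_count: int = 2
    # geometry as fractions of the per-axis field of view
    kidney_half_axes_frac: tuple[float, float, float] = (0.10, 0.16, 0.28)
    hilum_depth_frac: float = 0.5        # of the kidney's x half-axis
    pelvis_scale: float = 0.35           # pelvis ellipsoid vs kidney half-axes
    cyst_probability: float = 0.5        # per kidney
    cyst_radius_frac: tuple[float, float] = (0.06, 0.11)  # of the min FOV extent
    adjacent_organ_probability: float = 0.5
    organ_half_axes_frac: tuple[float, float, float] = (0.13, 0.20, 0.30)
    # CT mean intensities in HU
    ct_background: float = 30.0
    ct_kidney: float = 140.0
    ct_cyst: float = 115.0               # close to kidney: the CT-only confound
    ct_organ: float = 140.0
    ct_pelvis: float = 25.0
    # PET uptake (arbitrary activity-concentration units)
    pet_background: float = 0.2
    pet_kidney: float = 10.0             # maximum tissue uptake
    pet_cyst: float = 0.2                # cold, == background
    pet_organ: float = 2.0
    pet_psf_fwhm_mm: float = 6.0
    noise_sd_ct: float = 12.0
    noise_sd_pet: float = 0.3
    coarse_threshold_fraction: float = 0.5   # of pet_kidney, on the unblurred map
    tracer_label_ratio: float = 0.5          # fraction labelled GA68
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.kidney_count <= 2:
            raise ValueError("kidney_count must be 0, 1 or 2")
        if self.pet_cyst > self.pet_background * 1.5 + 1e-9:
            raise ValueError("cyst uptake must be cold (approximately background)")
        if self.pet_kidney <= max(self.pet_organ, self.pet_background):
            raise ValueError("kidney uptake must be the maximum tissue uptake")

    @property
    def extent_mm(self) -> np.ndarray:
        return np.asarray(self.grid_shape) * np.asarray(self.spacing_mm)


def _coords_mm(shape, spacing):
    axes = [(np.arange(n) + 0.5) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid(coords, center_mm, half_axes_mm) -> np.ndarray:
    q = sum(((c - m) / a) ** 2 for c, m, a in zip(coords, center_mm, half_axes_mm))
    return q <= 1.0


class _Tissues:
    """Boolean label fields accumulated while building one phantom."""

    def __init__(self, shape):
        self.kidney = np.zeros(shape, dtype=bool)    # tissue incl. pelvis, excl. cysts
        self.pelvis = np.zeros(shape, dtype=bool)
        self.cyst = np.zeros(shape, dtype=bool)
        self.organ = np.zeros(shape, dtype=bool)


def _build_kidney(t: _Tissues, coords, center, half_axes, medial_sign, p: PhantomParams,
                  rng: np.random.Generator) -> int:
    """Carve one kidney; returns the number of cysts added."""
    body = _ellipsoid(coords, center, half_axes)
    # hilum: indentation on the medial face (towards the mid-sagittal plane),
    # realized as a subtracted ellipsoid centered on the medial edge
    depth = p.hilum_depth_frac * half_axes[0]
    hilum_center = (center[0] + medial_sign * half_axes[0], center[1], center[2])
    hilum = _ellipsoid(coords, hilum_center, (depth, 0.5 * half_axes[1], 0.5 * half_axes[2]))
    body &= ~hilum
    # renal pelvis: small ellipsoid just inside the hilum; tissue, but excluded
    # from the fine mask
    pelvis_center = (center[0] + medial_sign * 0.5 * half_axes[0], center[1], center[2])
    pelvis = _ellipsoid(coords, pelvis_center,
                        tuple(p.pelvis_scale * a for a in half_axes)) & body
    n_cysts = 0
    if rng.random() < p.cyst_probability:
        n_cysts = int(rng.integers(1, 3))
        rmin, rmax = (f * p.extent_mm.min() for f in p.cyst_radius_frac)
        for _ in range(n_cysts):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            c_center = tuple(c + 0.8 * a * d for c, a, d in zip(center, half_axes, u))
            radius = rng.uniform(rmin, rmax)
            cyst = _ellipsoid(coords, c_center, (radius,) * 3)
            t.cyst |= cyst & body
    t.kidney |= body
    t.pelvis |= pelvis
    return n_cysts


def _build_organ(t: _Tissues, coords, kidney_center, kidney_half_axes, lateral_sign,
                 p: PhantomParams, rng: np.random.Generator) -> bool:
    """Liver/spleen-like blob abutting the kidney.

    The organ is placed overlapping the kidney surface along a random
    direction (in-plane angle biased away from the mid-sagittal side) so that
    it genuinely touches; carving the kidney back out leaves a contiguous
    equal-intensity interface — the CT-only confound.
    """
    half_axes = tuple(f * e for f, e in zip(p.organ_half_axes_frac, p.extent_mm))
    angle = rng.uniform(-0.75 * np.pi, 0.75 * np.pi)  # 0 = lateral
    direction = np.array([lateral_sign * np.cos(angle), np.sin(angle), 0.0])
    # radius of each ellipsoid along the contact direction
    k_r = 1.0 / np.sqrt(sum((direction[i] / kidney_half_axes[i]) ** 2
                            for i in range(2)) + 1e-12)
    o_r = 1.0 / np.sqrt(sum((direction[i] / half_axes[i]) ** 2
                            for i in range(2)) + 1e-12)
    reach = k_r + o_r * rng.uniform(0.45, 0.7)   # overlapping -> contact guaranteed
    center = (
        kidney_center[0] + direction[0] * reach,
        kidney_center[1] + direction[1] * reach,
        kidney_center[2] + rng.uniform(-0.1, 0.1) * p.extent_mm[2],
    )
    organ = _ellipsoid(coords, center, half_axes)
    organ &= ~t.kidney & ~t.cyst
    t.organ |= organ
    # contact flag: does the organ touch the 1-voxel neighborhood of a kidney?
    touch = ndimage.binary_dilation(t.kidney) & organ
    return bool(touch.any())


def _render(t: _Tissues, p: PhantomParams, rng: np.random.Generator):
    shape = p.grid_shape
    ct = np.full(shape, p.ct_background, dtype=np.float32)
    kidney_solid = t.kidney & ~t.cyst
    ct[t.organ] = p.ct_organ
    ct[kidney_solid] = p.ct_kidney
    ct[t.pelvis & ~t.cyst] = p.ct_pelvis
    ct[t.cyst] = p.ct_cyst

    uptake = np.full(shape, p.pet_background, dtype=np.float32)
    uptake[t.organ] = p.pet_organ
    uptake[kidney_solid] = p.pet_kidney
    uptake[t.cyst] = p.pet_cyst

    # coarse PET-style mask: supra-threshold uptake restricted to the kidneys
    # (adjacent organs excluded), from the unblurred map — a deterministic
    # stand-in for the visually chosen threshold of a human segmenter
    coarse = (uptake >= p.coarse_threshold_fraction * p.pet_kidney) & t.kidney
    fine = kidney_solid & ~t.pelvis

    if p.pet_psf_fwhm_mm > 0:
        sigma_vox = (p.pet_psf_fwhm_mm / 2.3548) / np.asarray(p.spacing_mm)
        pet = ndimage.gaussian_filter(uptake, sigma_vox)
    else:
        pet = uptake.copy()
    if p.noise_sd_ct > 0:
        ct = ct + rng.normal(0.0, p.noise_sd_ct, shape).astype(np.float32)
    if p.noise_sd_pet > 0:
        pet = pet + rng.normal(0.0, p.noise_sd_pet, shape).astype(np.float32)
    return ct, pet, fine, coarse


def generate_case(params: PhantomParams, draw: np.random.Generator,
                  case_id: str = "phantom-000") -> PatientCase:
    case, _ = generate_case_with_info(params, draw, case_id)
    return case


def generate_case_with_info(params: PhantomParams, draw: np.random.Generator,
                            case_id: str = "phantom-000"):
    """Generate one phantom plus its manifest row (tracer, cyst count,
    organ-contact flag)."""
    p = params
    extent = p.extent_mm
    half_axes = tuple(f * e for f, e in zip(p.kidney_half_axes_frac, extent))
    margin = 1.05
    if any(2 * margin * a >= e for a, e in zip(half_axes, extent)):
        raise ValueError("kidney does not fit in the grid; shrink kidney_half_axes_frac")
    coords = _coords_mm(p.grid_shape, p.spacing_mm)
    t = _Tissues(p.grid_shape)
    # side -1: patient-right (low x); side +1: patient-left (high x)
    sides = ([-1, 1] if p.kidney_count == 2
             else [int(draw.choice([-1, 1]))] if p.kidney_count == 1 else [])
    n_cysts = 0
    kidney_geo = []
    for side in sides:
        center = (
            extent[0] * (0.5 + side * 0.25) + draw.uniform(-0.04, 0.04) * extent[0],
            extent[1] * 0.5 + draw.uniform(-0.12, 0.12) * extent[1],
            extent[2] * 0.5 + draw.uniform(-0.10, 0.10) * extent[2],
        )
        jitter = draw.uniform(0.8, 1.2, size=3)
        axes = tuple(a * j for a, j in zip(half_axes, jitter))
        n_cysts += _build_kidney(t, coords, center, axes, -side, p, draw)
        kidney_geo.append((center, axes, side))
    organ_contact = False
    if kidney_geo and draw.random() < p.adjacent_organ_probability:
        center, axes, side = kidney_geo[int(draw.integers(len(kidney_geo)))]
        organ_contact = _build_organ(t, coords, center, axes, side, p, draw)
    ct, pet, fine, coarse = _render(t, p, draw)
    tracer = Tracer.GA68 if draw.random() < p.tracer_label_ratio else Tracer.F18
    case = PatientCase(
        case_id=case_id,
        ct=VolumeGrid(ct, p.spacing_mm, Modality.CT),
        pet=VolumeGrid(pet, p.spacing_mm, Modality.PET),
        fine_mask=BinaryMask3D(fine.astype(np.uint8), p.spacing_mm, MaskKind.FINE),
        coarse_mask=BinaryMask3D(coarse.astype(np.uint8), p.spacing_mm, MaskKind.COARSE),
        tracer=tracer,
    )
    info = {"case_id": case_id, "tracer": tracer.value, "cyst_count": n_cysts,
            "organ_contact": organ_contact, "tissues": t}
    return case, info


def generate_cohort(n: int, params: PhantomParams, seed: int,
                    with_manifest: bool = False):
    """n independent phantoms with unique case ids; deterministic given seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    root = np.random.SeedSequence(seed)
    cases, rows = [], []
    for i, child in enumerate(root.spawn(n)):
        rng = np.random.default_rng(child)
        case, info = generate_case_with_info(params, rng, case_id=f"phantom-{i:03d}")
        cases.append(case)
        rows.append({k: v for k, v in info.items() if k != "tissues"})
    if with_manifest:
        return cases, pd.DataFrame(rows)
    return cases


def _largest_remainder(n: int, fractions) -> list[int]:
    raw = [n * f for f in fractions]
    sizes = [int(np.floor(r)) for r in raw]
    rem = n - sum(sizes)
    order = np.argsort([s - r for s, r in zip(sizes, raw)])  # most-negative = largest frac part
    for i in range(rem):
        sizes[order[i]] += 1
    return sizes


def split_cohort(cases: list[PatientCase], fractions=(78 / 108, 10 / 108, 20 / 108),
                 balance_by: str = "tracer", seed: int = 0):
    """Disjoint, exhaustive train/validation/test split, stratified so each
    split's tracer proportions stay within one case of the cohort's."""
    if abs(sum(fractions) - 1.0) > 1e-6:
        raise ValueError("fractions must sum to 1")
    n = len(cases)
    targets = _largest_remainder(n, fractions)
    if any(t < 1 for t in targets):
        raise ValueError("cohort too small for the requested split")
    rng = np.random.default_rng(seed)
    if balance_by == "tracer":
        keys = sorted({c.tracer for c in cases}, key=lambda t: t.value)
        groups = [[c for c in cases if c.tracer == k] for k in keys]
    else:
        groups = [list(cases)]
    splits: list[list[PatientCase]] = [[], [], []]
    for group in groups:
        idx = rng.permutation(len(group))
        sizes = _largest_remainder(len(group), fractions)
        start = 0
        for s, size in enumerate(sizes):
            splits[s].extend(group[i] for i in idx[start:start + size])
            start += size
    # per-group rounding can leave totals off by one; rebalance deterministically
    for _ in range(3 * n):
        surplus = next((s for s in range(3) if len(splits[s]) > targets[s]), None)
        deficit = next((s for s in range(3) if len(splits[s]) < targets[s]), None)
        if surplus is None or deficit is None:
            break
        splits[deficit].append(splits[surplus].pop())
    return tuple(splits)
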