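"""Desk-scale end-to-end experiments tying the pipeline together.

These are the CPU-sized counterparts of the full-scale study: train the
stage-1 (A2: PET -> coarse) network and the stage-2 networks of the CT-only
(A1) and PET-pre-segmented (A5) approaches on a mixed synthetic cohort, then
compare fine-mask Dice on a held-out test set split by construction into
confounder-bearing (cysts and/or an abutting organ) and clean phantoms.

The desk profile trades size for CPU feasibility: 32x32x16 grids covering the
same 128x128x160 mm field of view as the default phantom, a depth-2 u-net
with 6 base channels, and 28 Adam epochs at a learning rate of 3e-3 (halved
once).  The architecture and pipeline are identical to the full-scale
profile; only the problem size differs.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .approaches import ApproachSpec, assemble_input, run_approach
from .metrics import dice_score
from .preprocess import PreprocessConfig, preprocess_case
from .synthetic_phantom import PhantomParams, generate_cohort
from .training import TrainConfig, train_model
from .unet3d import UNetConfig, build_model

__all__ = ["DeskProfile", "train_approach_models", "headline_comparison"]

#: phantom settings shared by the desk-scale experiments: same physical field
#: of view as the default phantom, rendered on a 32x32x16 grid, with strong
#: cyst / adjacent-organ confounding
DESK_PHANTOM = dict(
    grid_shape=(32, 32, 16), spacing_mm=(4.0, 4.0, 10.0),
    cyst_probability=0.8, adjacent_organ_probability=0.8,
    ct_cyst=135.0, cyst_radius_frac=(0.08, 0.14),
    organ_half_axes_frac=(0.18, 0.26, 0.35),
)


@dataclass
class DeskProfile:
    n_train: int = 16
    n_val: int = 4
    n_test_confounded: int = 10
    n_test_clean: int = 6
    epochs: int = 28
    initial_lr: float = 3e-3
    base_channels: int = 6
    depth: int = 2


def _preprocess_all(cases):
    cfg = PreprocessConfig(target_inplane=32, crop_slices=16)
    return [preprocess_case(c, cfg) for c in cases]


def _training_pairs(name: str, cases, target_kind: str):
    """(input, target) pairs; A4/A5 stage-2 training wires in the manual
    coarse mask (the two-step approaches are not trained end-to-end)."""
    spec = ApproachSpec(name, stage2_model="unused",
                        stage1_model=("unused" if name in ("A4", "A5") else None))
    pairs = []
    for c in cases:
        coarse = c.coarse_mask if name in ("A4", "A5") else None
        x = assemble_input(spec, c, coarse)
        y = (c.coarse_mask if target_kind == "coarse" else c.fine_mask).data
        pairs.append((x, y))
    return pairs


def train_approach_models(train_cases, val_cases, profile: DeskProfile, seed: int,
                          approaches=("A2", "A1", "A5"), workdir=None) -> dict:
    """Train one u-net per requested approach on preprocessed cases; returns
    ``{name: UNet3D}`` with each model restored to its best-validation state."""
    workdir = Path(workdir) if workdir else Path(tempfile.mkdtemp(prefix="petseg-train-"))
    tcfg = TrainConfig(epochs=profile.epochs, initial_lr=profile.initial_lr,
                       lr_halving_period=max(profile.epochs // 2, 1), seed=seed)
    models = {}
    for i, name in enumerate(approaches):
        from .approaches import input_channels
        cfg = UNetConfig(in_channels=input_channels(name), depth=profile.depth,
                         base_channels=profile.base_channels, init_seed=seed * 10 + i)
        model = build_model(cfg)
        target = "coarse" if name == "A2" else "fine"
        train_model(model,
                    _training_pairs(name, train_cases, target),
                    _training_pairs(name, val_cases, target),
                    tcfg, workdir / f"{name}.npz")
        models[name] = model
    return models


def _mean_dice(spec: ApproachSpec, cases, reference: str = "fine") -> list[float]:
    out = []
    for c in cases:
        pred = run_approach(spec, c)
        ref = c.fine_mask if reference == "fine" else c.coarse_mask
        try:
            out.append(dice_score(pred, ref))
        except ValueError:      # empty prediction: count as total miss
            out.append(0.0)
    return out


def headline_comparison(seed: int, profile: DeskProfile | None = None) -> dict:
    """One desk-scale replication of the study's central comparison.

    Trains A2/A1/A5 on a mixed cohort and evaluates fine-mask Dice on a
    held-out test set whose phantoms are generated, by construction, either
    with confounders (every kidney has cysts and an abutting organ) or clean
    (neither).  Returns per-approach mean DSC overall and per subset.
    """
    profile = profile or DeskProfile()
    params = PhantomParams(**DESK_PHANTOM, seed=seed)
    n_fit = profile.n_train + profile.n_val
    cohort = generate_cohort(n_fit, params, seed=seed)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_fit)
    train = [cohort[i] for i in order[:profile.n_train]]
    val = [cohort[i] for i in order[profile.n_train:]]

    conf_params = replace(params, cyst_probability=1.0, adjacent_organ_probability=1.0)
    clean_params = replace(params, cyst_probability=0.0, adjacent_organ_probability=0.0)
    test_conf = generate_cohort(profile.n_test_confounded, conf_params, seed=seed + 10_000)
    test_clean = generate_cohort(profile.n_test_clean, clean_params, seed=seed + 20_000)

    train, val = _preprocess_all(train), _preprocess_all(val)
    test_conf, test_clean = _preprocess_all(test_conf), _preprocess_all(test_clean)

    models = train_approach_models(train, val, profile, seed)
    spec_a1 = ApproachSpec("A1", stage2_model=models["A1"])
    spec_a5 = ApproachSpec("A5", stage2_model=models["A5"], stage1_model=models["A2"])
    spec_a2 = ApproachSpec("A2", stage2_model=models["A2"])

    res = {"seed": seed}
    for label, spec in (("a1", spec_a1), ("a5", spec_a5)):
        conf = _mean_dice(spec, test_conf)
        clean = _mean_dice(spec, test_clean)
        res[f"dsc_{label}_confounded"] = float(np.mean(conf))
        res[f"dsc_{label}_clean"] = float(np.mean(clean))
        res[f"dsc_{label}"] = float(np.mean(conf + clean))
    res["dsc_a2_coarse"] = float(np.mean(_mean_dice(spec_a2, test_conf + test_clean,
                                                    reference="coarse")))
    return res
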