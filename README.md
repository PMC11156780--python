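# petseg — PET-guided deep-learning kidney segmentation

For dosimetry of radiopharmaceutical therapies (e.g. ¹⁷⁷Lu-PSMA), the kidneys
are a critical organ at risk, and their volume and shape are usually derived
from CT. Purely CT-based automatic segmentation struggles exactly where it
matters: renal cysts have near-parenchymal Hounsfield values, and the liver,
spleen or pancreas can abut the kidney with no visible CT boundary. PSMA-PET
resolves both ambiguities for free — kidney parenchyma accumulates the tracer
strongly, cysts are photopenic, and neighboring organs show clearly different
uptake.

`petseg` implements and compares five 3D u-net input-fusion strategies for
fine (cortex + medulla, excluding pelvis, vessels and cysts) kidney
segmentation on co-registered PET/CT:

| approach | input | output |
|---|---|---|
| A1 | CT image | fine segmentation |
| A2 | PET image | coarse (uptake) segmentation |
| A3 | CT + PET (2 channels) | fine segmentation |
| A4 | CT + coarse mask (2 channels) | fine segmentation |
| A5 | CT voxelwise-multiplied by the coarse mask, enlarged by 2 voxels per axis | fine segmentation |

A4 and A5 are two-step pipelines (not trained end-to-end): a first u-net (A2)
predicts the coarse uptake mask from PET; the second u-net then refines it on
CT. The mask enlargement in A5 prevents kidney tissue just outside the uptake
region from being cut off.

The package is fully runnable on one CPU without any patient data: a
synthetic phantom generator produces co-registered CT/PET volumes with
fine and coarse ground-truth masks, including the confounders above (cysts
with near-kidney HU and zero uptake, equal-intensity abutting organs).

## Core definitions

Training loss (x = sigmoid prediction, y = binary target, N voxels):

    L(x, y) = [1 − 2Σxᵢyᵢ / (Σxᵢ + Σyᵢ)] − (1/N) Σ[yᵢ ln xᵢ + (1−yᵢ) ln(1−xᵢ)]

Evaluation metrics, per kidney (left/right split at the mid-sagittal plane):

* **DSC** = 2|X∩Y| / (|X|+|Y|)
* **VD** = |vol(X) − vol(Y)| / vol(Y) × 100 %
* **AHD** = ½ [ mean_a min_b ‖a−b‖₂ + mean_b min_a ‖a−b‖₂ ] over the
  foreground voxel-center point sets, in mm

Cohort statistics: two-sided Wilcoxon signed-rank tests between approaches,
two-sided Mann-Whitney U tests for tracer effects (⁶⁸Ga vs ¹⁸F labels).

The u-net is an encoder–decoder with skip connections: two 3×3×3
convolutions per block, each followed by instance normalization, leaky ReLU
(slope 0.2) and dropout (p = 0.1); 2×2×2 average pooling down, stride-2
transpose convolutions up, channel doubling per level, sigmoid output. The
network and its backpropagation are implemented in pure NumPy (no deep
learning framework required); training uses Adam with a halving learning-rate
schedule and keeps the checkpoint with minimal validation loss.

## Worked example

```python
import numpy as np
from petseg import (PhantomParams, generate_cohort, preprocess_case,
                    PreprocessConfig, dice_score)
from petseg.experiments import headline_comparison

r = headline_comparison(seed=1)
print({k: round(v, 3) for k, v in r.items() if k != "seed"})
```

Output (seed 1):

```
{'dsc_a1_confounded': 0.784, 'dsc_a1_clean': 0.971, 'dsc_a1': 0.854,
 'dsc_a5_confounded': 0.807, 'dsc_a5_clean': 0.959, 'dsc_a5': 0.864,
 'dsc_a2_coarse': 0.987}
```

Reading this: on clean phantoms both approaches segment well (DSC ≈ 0.96–0.97);
on phantoms with cysts and an abutting equal-intensity organ the CT-only
approach A1 drops to 0.78 while the PET-pre-segmented approach A5 holds 0.81 —
the PET-based pre-segmentation pays off exactly on the confounded anatomy.
The stage-1 PET network reproduces the coarse uptake mask almost perfectly
(DSC 0.99).

There is also a CLI:

```bash
petseg simulate --n 20 --out cohort/ --seed 7          # phantom cohort + manifest
petseg segment  --approach A5 --ct ct.nii.gz --pet pet.nii.gz \
                --stage1-ckpt a2.npz --stage2-ckpt a5.npz --out mask.nii.gz
petseg evaluate --pred mask.nii.gz --ref ref.nii.gz --out metrics.csv
petseg compare  --metrics a1.csv --metrics a5.csv --reference A5 --out summary.csv
```

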