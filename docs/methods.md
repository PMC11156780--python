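# Methods

This note documents the models, parameters and design choices behind
`petseg`, in the spirit of a methods appendix: what is computed, under which
assumptions, and what the synthetic experiments do and do not show.

## Problem setting

Input per subject: a contrast-enhanced CT volume (Hounsfield units) and a
co-registered PSMA-PET volume (activity-concentration-like values), plus two
binary kidney labels used for training — a *fine* mask (cortex + medulla,
excluding renal pelvis, vessels and cysts; the dosimetry ground truth) and a
*coarse* mask (the supra-threshold tracer-uptake region of the kidneys,
excluding adjacent organs). Registration is assumed given (PET/CT scanner);
rigid or deformable alignment is out of scope.

## Preprocessing

All four grids of a case are brought onto one matrix: the CT is resampled
in-plane to the target size (reference setting: 512×512 → 256×256, i.e.
halved), the PET is linearly interpolated up to the same matrix (200×200 →
256×256), mask values are re-binarized after interpolation at 0.5 with ties
going to foreground, a fixed axial window (reference: 128 slices) centered on
the kidney region is cut out, and each volume is scaled to [0, 1].

Numerical choices:

* All scalar resampling is linear; `grid_mode` resampling preserves the
  physical field of view, and spacing is updated accordingly.
* Normalization: PET is clamped below at 0 and divided by its maximum. CT is
  min-max scaled — pure division by the maximum cannot reach the unit
  interval when negative HU are present. No HU clipping is applied.
* Crop centering: the fine-mask centroid during training, the coarse-mask
  centroid or an explicit slice index at inference. The window is shifted to
  contain the reference mask's z-extent whenever it fits, then clamped to the
  volume.
* If CT and PET slice counts differ, the PET z-grid is linearly resampled to
  the CT's before cropping.
* After preprocessing, the case carries the CT-derived spacing on all grids.
  For real acquisitions whose CT and PET fields of view differ, matching the
  matrix sizes (as done here) does not exactly align physical coordinates;
  the phantom generator emits both modalities on one grid, so there the
  correspondence is exact.

## Augmentation

Each augmented copy draws one spatial transform shared by CT, PET and both
masks: zoom 0.8–1.2 and rotation about the longitudinal axis within ±7.5°
(composed into a single affine, one interpolation), an integer voxel shift of
magnitude 1–5 per axis with random sign, and independent axial/sagittal flips
with probability 0.5 each. The CT additionally receives a ±7.5 HU intensity
shift, applied in HU space before normalization. Masks are re-binarized at
0.5 after interpolation; out-of-field voxels are filled with the CT minimum
(air-like) or 0 (PET, masks). A split of n cases expands to n×(copies+1)
sets (originals retained), so 78 training and 10 validation cases with 9
copies each yield 780 and 100 sets. Test data are never augmented.

## Network

A 3D u-net in the classic encoder–decoder arrangement: per level one block of
two 3×3×3 convolutions (no bias), each followed by instance normalization,
leaky ReLU (negative slope 0.2) and channel dropout (p = 0.1); 2×2×2 average
pooling for downsampling; stride-2 2×2×2 transpose convolutions (with
instance norm + leaky ReLU) for upsampling, concatenated with the skip
tensor; channel count doubles per level; a final 1×1×1 convolution and a
sigmoid map to (0, 1). The reference profile uses 4 levels and 24 first-layer
channels on 256×256×128 inputs; the architecture is shape-invariant, and a
desk profile (2–3 levels, 4–8 channels, 32×32×16 – 64×64×32 inputs) is used
for all CPU-scale experiments and tests.

The layers and their backpropagation are implemented directly in NumPy
(einsum-based convolutions over sliding-window views), with an Adam optimizer
(β₁ = 0.9, β₂ = 0.999, ε = 1e-8). Every layer's gradient is validated against
central finite differences in float64 in the test suite, and the forward
convolution against `scipy.ndimage.correlate`.

## Training

Dice-BCE loss: the soft Dice complement plus mean binary cross-entropy, with
the prediction clamped to [1e−7, 1−1e−7] inside the logarithms (the loss is
undefined at exactly 0/1). Training runs a fixed number of epochs — no early
stopping — with the learning rate halved every `lr_halving_period` epochs
(reference: 60 epochs, initial 7×10⁻⁵, halved every 20; the desk profile uses
28 epochs at 3×10⁻³ halved once, a workable rate for the much smaller
problem). Validation loss is computed after every epoch with dropout
disabled; the checkpoint holds the parameters of the epoch with minimal
validation loss and is restored into the model at the end. Batch size
defaults to 1 (whole 3D volumes); larger batches accumulate gradients before
each Adam step. All randomness (shuffling, dropout, initialization) is
seeded.

## Approaches A1–A5

Channel wiring as in the README table. Decisions worth recording:

* "Enlarged by two voxels along each axis" is realized as morphological
  dilation with a cubic 5×5×5 structuring element, which guarantees the
  2-voxel enlargement along every axis simultaneously; a cross-shaped element
  is available by flag.
* In A4 the coarse mask enters as a binarized {0,1} channel (no dilation —
  enlargement is specific to A5's multiplication).
* Stage-2 training of A4/A5 uses the manual (ground-truth) coarse mask as
  stage-1 output; at inference the predicted A2 mask is used. The two u-nets
  are trained separately, never end-to-end.
* Network outputs are binarized at 0.5.

## Evaluation and statistics

DSC, VD and AHD as defined in the README. AHD is computed between the
point sets of **all** foreground voxel centers (not surfaces) at
(index + 0.5)·spacing, in mm — with overlapping interiors contributing zeros
this yields the small magnitudes characteristic of well-overlapping
segmentations; a KD-tree gives exact nearest-neighbor distances, verified
against an all-pairs oracle. Kidneys are separated at the volume's
mid-sagittal plane (high-x half = patient left); sides where either mask is
empty are skipped rather than imputed.

Paired approach comparisons use two-sided Wilcoxon signed-rank tests (exact
null for n ≤ 25 without ties, zero differences discarded); tracer effects use
two-sided Mann-Whitney U tests (exact for small tie-free samples). Raw
p-values are compared against 0.05; no multiple-testing correction. Both
tests delegate to scipy and are verified against exhaustive sign-pattern /
rank-assignment enumeration in the tests.

## Synthetic phantoms

Each phantom contains up to two kidneys — axis-aligned ellipsoids with a
medial hilum indentation and a carved pelvis — with optional cortical cysts
and an optional liver/spleen-like organ placed overlapping the kidney surface
along a random direction (then carved back, leaving a contiguous
equal-intensity interface). Geometry is parameterized as fractions of the
field of view so phantoms scale across grid sizes; the default grid is
64×64×32 at 2×2×5 mm (desk experiments use 32×32×16 at 4×4×10 mm, same
128×128×160 mm field of view).

Defaults (all exposed through `PhantomParams`): CT means of 30/140/115/140/25
HU for background/kidney/cyst/organ/pelvis with 12 HU Gaussian noise — the
cyst–kidney and organ–kidney contrasts are deliberately within noise; PET
uptake 0.2/10/0.2/2 (background/kidney/cyst/organ) blurred with a 6 mm FWHM
Gaussian point-spread function plus noise (σ = 0.3). The fine mask is kidney
tissue minus pelvis and cysts; the coarse mask thresholds the *unblurred*
uptake map at 50 % of kidney uptake restricted to the kidneys — a
deterministic stand-in for a human's visually chosen PET threshold. Tracer
labels (⁶⁸Ga/¹⁸F) are drawn per case.

What the phantoms emulate: the two-ground-truth labeling protocol, the
cyst/adjacent-organ confounders, PET blur and noise, cold cysts, absent
kidneys (`kidney_count=0`). What they do not: bean-like kidney shape, beam
hardening, PET scatter/randoms, intensity inhomogeneity, true anatomical
variability. Passing the desk-scale experiments therefore demonstrates the
*mechanism* — that a PET-derived pre-segmentation removes CT-ambiguous
confounders — not clinical-grade absolute accuracy.

## Desk-scale experiments and their sizes

Full-scale training (108 patients, 256×256×128, 60 epochs) is far beyond a
single CPU; the package's experiments use a deliberately small but complete
replica: 16 training + 4 validation phantoms at 32×32×16, a depth-2 u-net
with 6 base channels, 28 epochs, and a held-out test set of 10
confounder-bearing plus 6 clean phantoms, repeated over three seeds. These
sizes were chosen once as the smallest configuration at which all three
networks train to convergence (clean-phantom DSC ≈ 0.95–0.99) in a few
minutes per seed.

Observed behavior at these sizes (recomputed by `scripts/acceptance.py` and
asserted by the acceptance tests): A5 exceeds A1 in pooled mean test DSC, and
the advantage concentrates on the confounder-bearing phantoms, mirroring the
full-scale conclusion qualitatively. Individual seeds can come out close to
tied — the assertion is on the pooled means over the three fixed seeds, not
on any absolute DSC value.

## Known limitations

* The NumPy network trains at desk scale only; the reference profile is
  provided for completeness but is impractically slow without an accelerated
  backend.
* Physical alignment of differently-sized CT/PET fields of view is
  approximated by matrix-size matching (see Preprocessing).
* The phantom's intensity distributions are plausibility-driven, not fitted
  to patient data.
* No post-processing (e.g. largest-connected-component filtering) is applied
  to predicted masks.
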