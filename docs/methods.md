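# Methods

## Problem and approach

`flairvol` classifies 3D FLAIR brain MRI volumes into four diagnostic
categories of subcortical ischemic vascular disease (SIVD): healthy controls
(HC), SIVD with no cognitive impairment (NCI), vascular mild cognitive
impairment (VaMCI) and vascular dementia (VaD).  On FLAIR, the disease
signatures are hyperintense white-matter lesions (WMH), lacunar infarcts
(small CSF-filled cavities, often with a hyperintense rim) and atrophy
(enlarged ventricles).  The pipeline has two parts: ROI-cropping
preprocessing that removes the uninformative zero background left by skull
stripping, and a custom 3D convolutional network trained end to end on the
cropped volumes, with a 2D slice-based VGG-16-topology network as the
baseline it is compared against.

## Preprocessing

Volumes are loaded from NIfTI-1 files or DICOM series (slices ordered by
position along the slice normal, so file order is irrelevant).  Skull
stripping delegates to an external BET executable (fractional intensity
threshold 0.5) when one is configured; otherwise an internal fallback runs:
Otsu threshold over positive voxels scaled by `frac_threshold/0.5`, largest
connected component, morphological closing (input padded first so the
image border cannot erode brain voxels), hole filling.  The result has
every non-brain voxel at exactly 0.

Each axial slice's region of interest is the tightest inclusive bounding box
around its non-zero entries.  The maximal ROI (MROI) is the union of these
per-slice boxes — per volume, and in dataset mode (the default for model
input) the union over all volumes, so one common box is applied to every
subject.  Cropping slices to the MROI preserves voxel positions and never
resamples; the slice axis is never cropped.  Box indices are 0-based and
inclusive: the clinical acquisition's corner vertices (49,60) and (207,200)
span 207−49+1 = 159 rows and 200−60+1 = 141 columns, reducing 256×256×66
volumes to 159×141×66.  Inclusive indexing is forced by that vertex
arithmetic.

Before entering a model, each cropped volume is min–max scaled to [0,1]
over its brain voxels (background stays 0).  This normalization is an
addition to the reference preprocessing chain; it is required for stable
training from random initialization.

## Architectures

The 3D network is a fixed stack of eight 3×3×3 convolutions ("same"
padding, stride 1) with channel widths 32, 64, 64, 128, 128, 256, 256, 512,
a 2×2×2 max pool (stride 2) after every second convolution, batch
normalization before every ReLU, then flatten → dense(256, linear) →
dense(64, linear) → dense(4) → softmax.  Design points that were open:

* **Channel schedule.** Only the endpoints (32 → 512 over eight layers) are
  fixed by the reference design; doubling per two-conv block is the
  conventional reading and is what we emit.
* **Padding.** "Same" padding keeps all shape bookkeeping in the pools;
  159×141×66 then floor-halves to 9×8×4 after the fourth pool.
* **FC widths.** 256 and 64 (unspecified originally); configurable.
* **Batch norm on the linear FC layers.** Included by default (BN precedes
  "each activation", and the identity activation is read as an activation);
  a flag disables it.
* **Scaling.** `base_channels` scales every conv width proportionally
  (schedule `b..16b`), preserving topology for desk-scale runs.

The 2D baseline is the VGG-16 topology: 13 3×3 convolutions in blocks of
2,2,3,3,3 (channels 64,128,256,512,512 at full width), five 2×2 pools,
three dense layers.  Batch normalization is added before each ReLU — a
deviation from canonical VGG-16 needed to train from random initialization.
ImageNet-pretrained weights are not bundled; requesting them logs a warning
and falls back to random initialization.  A volume is classified by running
every second brain-containing slice through the network and averaging the
softmax outputs over slices (one prediction per subject).  Alternatives
(middle slice only) exist but slice-average is the default.

Weights use He initialization (scale √(2/fan-in)); all parameters and
activations are float32.

## The numpy network engine

No deep-learning framework is part of the toolkit's dependency footprint;
`flairvol.nn` implements the layers directly in numpy with analytic
backward passes, each verified against central-difference numerical
gradients in the test suite.  Convolution inner loops are numba-compiled
(direct convolution; at these channel widths it outperforms im2col+GEMM).
The input gradient of a stride-1 same-padded convolution is computed as a
convolution with the spatially flipped, channel-transposed kernel.  Batch
normalization keeps running mean/variance (momentum 0.9) for evaluation
mode.  Training is bit-deterministic on CPU given the seed: weight
initialization, batch order and the label shuffle all derive from one
`numpy.random.Generator`.

## Training protocol

* **Loss.** The default loss is binary cross-entropy summed over the four
  class outputs,
  `−Σᵢ [yᵢ log pᵢ + (1−yᵢ) log(1−pᵢ)]`, applied to softmax outputs with
  one-hot targets, averaged over the batch.  Probabilities are clipped at
  ε = 1e-7 before the logarithms.  This differs from plain categorical
  cross-entropy by the `(1−y) log(1−p)` terms, and unlike softmax+categorical
  CE its gradient is not bounded — late-training metrics therefore
  fluctuate more than a categorical-CE run would.  Categorical CE is a
  config alternative (`loss: categorical`).
* **Optimizer.** SGD with momentum 0.9 (momentum and batch size 4 were
  unspecified originally; both configurable).
* **Learning rate.** `lr(step) = 1e-2 · decay^(step/300)` with a continuous
  (non-staircase) exponent; the decay base is unspecified originally and
  defaults to 0.9.
* **Splitting.** Stratified 75/25 train/test at subject level by
  largest-remainder apportionment: the global train count is
  round(0.75·N) and every class stays within one subject of its
  proportional share.  Ten-fold stratified cross-validation inside the
  training set (scikit-learn `StratifiedKFold`) is available; the mean of
  the ten sessions' validation accuracies is the protocol's training-set
  accuracy figure.
* **Model selection.** None: final-epoch weights are kept; per-epoch train
  and test loss/accuracy are recorded for curves.

## Synthetic cohort

Real FLAIR volumes from the target cohort are not distributable, so a
seeded phantom generator emulates it.  A phantom is an ellipsoidal brain
(mid-intensity white matter 0.60, brighter cortical shell 0.75, in
arbitrary units) on an exactly-zero background, with per-subject ±4%
anatomical jitter; two dark (0.15) ellipsoidal ventricles scaled by an
atrophy factor; WMH as the top `wmh_fraction` of a smoothed random field
over the periventricular white-matter shell, set to `lesion_contrast`
(1.6) times the white-matter baseline; and `n_lacunes` quasi-spherical
lesions with dark cores and hyperintense rims placed without overlap in
deep white matter (an explicit error if the brain is too small to fit
them).  Gaussian noise (σ = 0.05, roughly SNR 12 against white matter —
a plausibly clean clinical FLAIR) is added inside the brain only.

Class severity defaults are fixtures, not clinically calibrated (no
validated lesion-load thresholds exist for these diagnostic boundaries):
`n_lacunes` 0/1/3/6, `wmh_fraction` 0/0.02/0.08/0.20, `ventricle_scale`
1.0/1.05/1.15/1.30 for HC/NCI/VaMCI/VaD.  With these defaults the total
lesion-volume distributions of adjacent classes overlap by far less than
25% over 30 phantoms per class, which is what makes downstream training
testable.  The default cohort composition mirrors the clinical study:
52 VaD, 82 VaMCI, 83 NCI, 46 HC (217 patients, 263 subjects).  Grid
presets: `test` 64×64×32 (4 mm voxels) for desk-scale work and `paper`
256×256×66 (1×1×2 mm) matching the clinical geometry.

What the phantoms do **not** model: anatomy beyond ellipsoids, pulse-
sequence physics, Rician noise statistics, scanner inhomogeneity, partial
volume, or any correlation between lesion location and cognition.  Passing
tests on phantoms demonstrates that the pipeline's mechanics (ROI logic,
training loop, metrics) are correct and that the models can learn a
volumetric lesion-burden signal; they say nothing about accuracy on real
clinical data.

## Desk-scale experiment and its metrics

The packaged comparison (`flairvol.experiment.run_comparison`) uses 40
subjects per class at the 64×64×32 preset, the 3D model at
`base_channels=2` (schedule 2..32; topology unchanged) for 20 epochs, the
2D baseline at the same width on every second brain slice for 8 epochs,
and a 10-epoch label-shuffle control — sizes chosen to keep a single-CPU
run in minutes.  Because the summed-BCE loss produces late-training
fluctuations, "reached" accuracy is defined as the best per-epoch
subject-level test accuracy within the epoch budget, identically for both
models; the shuffle control reports the mean of its last five epochs.

A known limitation: at these conditions the phantom's lesion-burden signal
is visible in individual slices, so the slice-averaged 2D baseline
saturates at the 40-subject test-set ceiling just as the 3D model does.
The experiment demonstrates learnability and the chance-level negative
control, but a strict 3D-over-2D margin — which on clinical data arises
from cross-slice structure the phantoms do not encode — does not emerge at
this scale.

## Numerical conventions

* Probabilities clipped at 1e-7 before logarithms.
* Undefined one-vs-rest metrics (zero denominators) are NaN with a logged
  note, never silently 0.
* Report tables round to two decimals, round-half-even.
* Argmax ties break toward the lowest class index, class order
  (HC, NCI, VaMCI, VaD).
* Per-subject phantom seeds are the first four bytes of
  SHA-256(master_seed:index), reduced below 2³¹.
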