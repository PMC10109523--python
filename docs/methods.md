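# Methods

## Pipeline overview

The toolkit implements three analysis tasks over brain MRI: tumor-presence
detection from a 2D image, tumor-presence detection from a hand-crafted
feature vector, and binary tumor segmentation (2D single-channel slices and
multimodal 4-channel slice stacks).  Each task has its own preprocessing
convention, network architecture, loss, and training recipe; the stages are
deliberately *not* harmonized with each other — the detection branch feeds
byte-scale [0, 255] images while the 2D segmentation branch feeds unit-scale
[0, 1] images — because the layer tables and preprocessing procedures pin
these choices per stage.

## Preprocessing

* **Detection**: grayscale → bilinear resize 256×256 → byte range →
  replicate to 3 channels.  The training loop and the inference entry point
  additionally feed the *network* the zero-centered unit-scale image
  (x/255 − 0.5), the conventional conditioning applied by rescaling data
  generators in this family of pipelines.  Raw byte inputs leave RMSprop at
  learning rate 1e-4 unable to converge in small epoch budgets, and
  uncentered unit inputs systematically drift the output logit so the 0.5
  decision threshold is miscalibrated; centering removes both pathologies.
  The `DetectionInput` container itself keeps the byte scale.
* **2D segmentation**: grayscale → resize 512×512 → divide by 255 →
  channel axis → downsample 128×128.  The intermediate 512×512 step adds
  nothing numerically but is retained because the procedure specifies it.
* **Multimodal segmentation**: per modality, global z-scoring over the whole
  volume ((x − μ)/σ with a σ = 0 guard mapping constant volumes to zero);
  axial slices 60..129 (0-based, exactly 70 of 155) are kept, resized to
  128×128, and stacked in the fixed order T1, T2, T1ce, FLAIR.  Label
  volumes are binarized first (any nonzero tumor sub-region label → 1),
  then windowed and resized nearest-neighbour.
* Intensity rasters are always resized bilinearly, masks always
  nearest-neighbour with re-binarization, so masks are exactly {0, 1} at
  every stage.

## Architectures and the parameter audit

Networks are described declaratively (`ModelGraph`: ordered layer specs
with named inbound edges).  Output shapes follow from standard shape
inference, and parameters from the usual closed forms — conv:
`f·(k²·c + 1)`; dense: `u·(d + 1)`; batchnorm: `4c`, of which the moving
mean/variance (`2c`) are non-trainable.  The audit reproduces the published
totals exactly:

| network                  | total       | non-trainable |
|--------------------------|-------------|---------------|
| detection CNN            | 352,609     | 0             |
| feature CNN (4 inputs)   | 2,817       | 0             |
| 2D U-Net                 | 22,718,529  | 1,920         |
| 2D U-Net++               | 22,498,881  | 1,920         |
| multimodal U-Net         | 31,055,873  | 11,776        |

Three wiring details are forced by those totals rather than by the layer
tables, which are internally inconsistent in places:

* the detection CNN's intermediate "dense (ReLU)" rows carry no weights
  (a parameterized reading would add 5,216) and are realized as bare
  activation blocks;
* the 2D U-Net's output convolution is 1×1 (a 3×3 head would add 512);
* in the U-Net++, the up-transition into the deepest nested node outputs
  256 channels, and the second column-0 node (X02) concatenates the
  *reused* up-sampled tensor feeding X01 rather than a fresh transposed
  convolution (a new one would add 73,792).

The multimodal U-Net++ follows the same nested topology with a 4-channel
input; its published counts cannot be reconciled with any batch-norm
placement its table admits (240 non-trainable parameters would require
batch-norm over 120 channels total), so they are not asserted — the
builder's audit is 22,500,609 with 1,920 non-trainable.

"3D" models operate on 4-channel 2D slices, not volumetric kernels: the
slice-wise preprocessing and the tabulated shapes admit no depth-wise
convolution.

A width multiplier (default 1.0) scales every filter count (minimum 1) for
desk-scale training; at 1.0 the audits above are unchanged.

## Training runtime

No GPU framework is used: the package ships a compact numpy runtime with
explicit forward/backward passes.  Convolutions use a shift-and-GEMM
formulation (one BLAS matmul per kernel tap with shifted accumulation);
transposed convolutions scatter per-tap GEMM outputs onto the doubled grid.
Gradients are verified against central differences in the test suite.
Design choices:

* float32 throughout; Glorot-uniform initialization for conv, transposed
  conv, and dense weights (the default of the reference deep-learning
  stack this runtime emulates); zero biases.
* Batch normalization: ε = 1e-3, momentum 0.8 (`moving ← 0.8·moving +
  0.2·batch`), batch statistics during training, moving statistics at
  inference.
* Inverted dropout (masks drawn from the network's seeded generator).
* Optimizers: Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8) and RMSprop (ρ = 0.9,
  ε = 1e-7).
* Losses: pixel-mean BCE with probabilities clipped to [1e-7, 1 − 1e-7];
  soft Dice with +1 smoothing in numerator and denominator, computed
  per-sample and averaged over the batch; hybrid = equal-weight sum.  The
  sigmoid backward pass clips the saturation term so the composed
  sigmoid+BCE gradient reduces to the stable fused form (p − y).
* All randomness (initialization, shuffling, dropout, augmentation) flows
  from seeded generators, so a fixed seed reproduces a training run
  bit-for-bit; this is asserted in the acceptance suite.

## Training recipes

| task             | epochs | batch | optimizer | lr    | loss   | augmentation        |
|------------------|--------|-------|-----------|-------|--------|---------------------|
| detect_image     | 50     | 16    | RMSprop   | 1e-4  | BCE    | flips + random      |
| detect_features  | 100    | 16    | Adam      | 1e-3  | BCE    | none                |
| seg2d_unet(++)   | 60     | 8     | Adam      | 1e-3  | hybrid | flips + random      |
| seg3d_unet(++)   | 50     | 8     | Adam      | 1e-4  | Dice   | none                |

Epochs, segmentation batch size, optimizers, learning rates and losses are
the published recipes; the detection batch size (16), the Adam learning
rate for the feature CNN (1e-3, the optimizer's standard default), and the
augmentation magnitudes are this package's choices.  Splitting is a seeded
shuffle, 80:20 train/test, then 80:20 train/validation of the remainder
(64/16/20 for n = 100), unstratified.  Flip augmentation appends a
horizontally and a vertically mirrored copy of every training pair (3n
total); the per-epoch random perturbation draws a brightness factor
uniform in [0.8, 1.2] (images only, clipped to the valid range) and a zoom
factor uniform in [0.9, 1.1] (bilinear for images, nearest for masks,
recentered to the original frame).  Mild ranges keep masks valid under
augmentation.  Early stopping is not used.

## Hand-crafted features

The 42-element vector concatenates, in fixed order: 4 intensity moments
(mean, population variance, skewness, excess kurtosis; constant images get
skewness = kurtosis = 0), 6 GLCM statistics (contrast, dissimilarity,
homogeneity, ASM, energy = √ASM, correlation; distance 1, angle 0°, 256
levels, symmetric, normalized; correlation of a constant image defined as
1), 8 wavelet statistics (mean and energy of the LL/LH/HL/HH sub-bands of
a single-level Haar transform, edge-padding odd sizes), Shannon entropy
(base 2, 256-bin histogram), a 10-bin normalized histogram of uniform
local binary patterns (P = 8, R = 1), and the 13 classic Haralick
co-occurrence statistics averaged over the four directions (0°, 45°, 90°,
135°), with guarded logarithms and a correlation guard for degenerate
matrices.  The source procedure names the feature families but not their
parameters; the values above are the most common defaults in the texture
literature and fix the vector length the feature CNN depends on.  The
Haralick block is implemented directly from the normalized co-occurrence
matrix (sum/difference distributions, entropies, information measures of
correlation), since only the 6-statistic GLCM block is available from the
imaging library used elsewhere.  Images are quantized to 256 gray levels
before any co-occurrence or histogram computation.  Feature tables are CSV
with header `name,label,<feature names>`.

Feature-group selection maps named blocks onto vector slices: intensity
(4), glcm (6), dwt (8), "other" (entropy + LBP + Haralick, 24), or the
full 42; the feature CNN's input length adapts accordingly.

## Inference and post-processing

Detection thresholds the sigmoid output strictly at 0.5 (0.5 itself is
class 0).  Segmentation masks are `probability > 0.5`.  Post-processing
reports tumor area (positive pixels), brain area (pixels above 5% of the
image maximum — exact on skull-free phantoms), tumor ratio
(tumor/brain, 0 when no brain), and confidence (mean probability over
predicted-tumor pixels, 0 for an empty mask).  "Confidence" has no
canonical definition in this pipeline family; the masked-mean definition
is this package's.  Dice of two empty masks is defined as 1.0.  Areas are
reported in pixels; no pixel-spacing metadata is consumed.

## Phantom data

A phantom is a bright elliptical brain (intensity 110) on a dark background
(8) with additive Gaussian noise (σ = 5, byte scale), and — when a tumor is
present — a brighter ellipse (default contrast +60) fully inside the brain,
whose rasterization is the exact ground-truth mask.  Multimodal phantoms
render one anatomy at four gains (1.0, 0.8, 1.2, 0.9) with small offsets,
place the tumor in a contiguous axial band strictly inside the slice
window [60, 130) (so window-selection bugs collapse the Dice score rather
than passing silently), and label tumor voxels with {1, 2, 4} in concentric
shells to exercise mask binarization.  Intensity values emulate the
contrast relationships of real MRI only qualitatively: there is no skull,
bias field, partial-volume effect, or texture.  Consequently the
desk-scale training results demonstrate that the pipeline wiring, losses,
and optimization are sound — not that these architectures reach any
particular performance on clinical data.

Generators are pure functions of (spec, seed); the detection dataset
writer emits `Y<i>.png` / `N<i>.png` files whose names round-trip through
the label parser, plus a manifest CSV.

## Desk-scale study conditions

The acceptance suite trains at width multiplier 0.25: the 2D U-Net on 200
phantoms for 8 epochs (held-out mean Dice ≥ 0.85; the run under the
default conditions reaches ≈ 0.96) and the detection CNN on 60 balanced
phantoms for 5 epochs (held-out accuracy ≥ 0.9).  These problem sizes keep
a full run on one CPU core in the tens of minutes while leaving the
learning signal far above the thresholds.  Bit-wise seed reproducibility
is asserted on a smaller two-epoch configuration, since the property is
independent of problem size in a deterministic runtime.

## Known limitations

* No volumetric (true 3D) convolutions; multimodal cases are processed
  slice-wise.
* No skull stripping, bias-field correction, or registration; inputs are
  assumed co-registered and skull-free (phantoms are).
* DICOM windowing metadata is ignored; pixel data is min-max rescaled to
  bytes after slope/intercept, which is deterministic but not
  radiologically calibrated.
* The CPU runtime is tuned for the desk-scale widths; full-width training
  (22M–31M parameters) is architecturally supported but impractically slow
  on one core.
* Tumor-type classification (meningioma/glioma/pituitary) and sub-region
  scoring (necrotic/edema/enhancing) are out of scope; masks are binary.
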