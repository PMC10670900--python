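# Methods

`cbctsynth` enhances cone-beam CT (CBCT) slices into planning-CT-quality
synthetic CT (sCT) with a residual U-Net trained coarse-to-fine under a
composite loss. This note records the model, its assumptions, the tunable
parameters, and the design decisions taken where the design was genuinely
open.

## Problem setting

CBCT acquired on the treatment machine suffers scatter-induced cupping,
streaks, noise, reduced soft-tissue contrast and globally inaccurate
Hounsfield Units (HU), which blocks its direct use for dose calculation in
adaptive radiotherapy. Given spatially aligned pairs (CBCT slice, planning
CT slice) the task is supervised image-to-image regression: learn a map
whose output matches the planning CT in HU while preserving tissue edges.

## Intensity pipeline

HU values are clipped to [−1000, 1500] and converted to linear attenuation

    mu = (HU / 1000 + 1) * mu_water,

with `mu_water = 0.0192 mm⁻¹` (~120 kV) by default. The affine form above
makes −1000 HU map to exactly 0 and 0 HU to exactly `mu_water` in floating
point; the inverse is exact to ≤1e-6 HU over the full clipped range.

The network itself consumes `mu / mu(1500 HU)`, i.e. attenuation normalised
to [0, 1]. Raw attenuation values (≤0.048 mm⁻¹) would make the
weighted-MAE term numerically negligible against the MS-SSIM term under
the default loss weights, so all loss bookkeeping happens on the
normalised scale: the 500 HU region threshold maps to 0.6 and the data
range to 1. Because every transform in the chain is affine and applied
symmetrically to predictions and targets, reported HU metrics are
independent of `mu_water` and of the normalisation.

## Network

A residual U-Net of depth 4: a stem of two 3×3 convolutions, four encoder
residual blocks each preceded by 2×2 max-pooling with filter counts
doubling per level, four decoder stages (2×2/stride-2 transposed
convolution, skip concatenation, residual block with filters halving), and
a linear 1×1 head. Batch normalisation follows every convolution except
the head. Residual shortcuts are identities when channel counts match and
1×1 projections otherwise. Inputs must be divisible by 2⁴ = 16 per side;
no cropping is performed inside the network.

Open choices resolved here: the encoder down-sampling operator
(max-pooling, the classic U-Net choice), the activation (ReLU, with the
residual addition before the block's final activation, plain ResNet-v1
layout), the stem staying at full resolution, and the per-level filter
ladder `base_filters × {1, 2, 4, 8, 16}` with `base_filters` exposed
(64 for the full model; 8–16 in tests and the desk-scale benchmark).

The network, its backward pass and the Adam optimiser are implemented
directly in NumPy (im2col convolutions; transposed convolutions exploit the
non-overlapping 2×2/stride-2 geometry). All layer gradients and all loss
gradients are verified against central finite differences in the test
suite.

Initialisation matters a great deal on short schedules. Convolution
weights are drawn from U(±1/√fan_in) with zero biases, the final
batch-norm γ of every residual block is initialised to zero (each block
starts as a rectified projection of its shortcut — the "zero-γ" residual
trick), and the output head's weights are scaled by 0.1 so initial
predictions sit near the data scale. Together these remove an early
training phase that otherwise spends tens of epochs fixing the output's
gross scale; one Adam optimiser instance persists across the hierarchical
stages for the same reason (a freshly zeroed second-moment estimate takes
maximally large steps and destroys the warm-started weights at each stage
boundary).

## Loss

`L = λ1·wMAE + λ2·(1 − MS-SSIM) + λ3·GDL` with `λ = (1, 3, 2)`.

* **Weighted MAE**: MAE computed separately over the high-intensity region
  (ground truth > 500 HU, bone) and the remnant region, the latter
  multiplied by ω = 5. Region membership is taken from the ground-truth
  image; the paper-style alternative (prediction or both) is ambiguous in
  the literature, and the ground-truth convention keeps the region fixed
  during optimisation. An empty region contributes 0, so all-air slices
  remain trainable.
* **MS-SSIM loss**: 1 − multi-scale SSIM. SSIM uses an 11-px Gaussian
  window (σ = 1.5), the standard two-constant form with
  `C1 = (0.01·R)²`, `C2 = (0.03·R)²` (a printed variant that reuses C1 in
  the variance term is treated as typographical; the standard form is
  implemented). MS-SSIM combines contrast/structure at every level of a
  dyadic pyramid and luminance at the coarsest, with the canonical 5-level
  weights (0.0448, 0.2856, 0.3001, 0.2363, 0.1333), renormalised when the
  image is too small for all levels (64-px inputs support 3 levels); with
  one level MS-SSIM reduces exactly to SSIM.
* **Gradient difference loss**: mean squared mismatch of forward-difference
  gradients along each axis. The mean (rather than sum) normalisation makes
  λ3 resolution-independent.

## Hierarchical training

The training set is expanded into a three-level resolution pyramid: level
L is the dataset pushed through `3 − L` cycles of (2×2-average
down-sampling, bilinear up-sampling back to native size), so all levels
share the native pixel grid and the native level is bit-identical to the
source. Stages run coarsest-first for 50/30/20 epochs (desk-scale preset
10/6/4), each stage warm-starting from the previous stage's final weights
with no re-initialisation and no layer freezing. Adam (lr 0.001, default
moments, batch 8) is re-instantiated per stage; the learning rate is
constant throughout. Validation during a stage uses the same resolution
level as that stage's training data. Model selection: the best-validation
checkpoint within the final stage (stage hand-off always uses stage-final
weights, so the hand-off contract is exact). Splitting is at patient
granularity with validation/test sizes rounded half-up and training taking
the remainder — 228 patients at 6:2:2 gives 136/46/46; no patient appears
in two subsets.

## Phantom simulator

The generator emulates the statistical structure of a pelvic cohort at
desk scale. Per patient one anatomy is sampled (elliptical body with a
subcutaneous fat ring, muscle interior, an anterior bladder-like organ,
femoral-head and sacrum-like bones with cortical rim ≈900 HU around
marrow ≈250 HU), and per slice the anatomy is jittered slightly, so
patient-level splitting is meaningful and leakage is testable. Smooth
within-tissue texture (σ = 12 HU) is added; the background is exactly
−1000 HU. Bone occupies a positive but <20 % fraction of body pixels, so
both regions of the weighted MAE are always populated. An optional
metallic insert (intra-uterine-device analogue, off by default) is placed
in the planning CT only, to exercise foreign-pixel replacement.

The degradation operator applies, in order: multiplicative soft-tissue
contrast rescale about 0 HU (factor 0.88), additive radial cupping bias
following the body's distance transform (90 HU, smoothed 4 px), 18 random
streak lines (±70 HU, Gaussian cross-profile), Gaussian blur (0.7 px),
additive white noise (σ = 70 HU), and a +30 HU global shift, then restores
the background to −1000. With these defaults the simulated CBCT-vs-CT gap
at 64 px averages ≈41 HU MAE (range ≈29–52 over seeds) and SSIM ≈0.71,
bracketing the tens-of-HU MAE / ≈0.77 SSIM regime reported for clinical
pelvic CBCT. A noise-only degradation reproduces the folded-normal mean
`σ·sqrt(2/π)` exactly, which the tests use as a closed-form oracle.

What the simulator does **not** model: physically derived scatter (no
Monte-Carlo), anatomical deformation between the paired scans (pairs are
pixel-aligned, standing in for an upstream registration step), 3D
structure, and detector-specific spectra. Passing the benchmark therefore
demonstrates that the architecture, losses and training machinery recover
a clean image from this artifact family — not clinical-grade performance
on real patients.

## Evaluation

Per-image MAE (HU), SSIM (11-px Gaussian window over a fixed 2500 HU data
range) and PSNR. PSNR uses the content-dependent peak — the maximum gray
value over both images — as its default, with the conventional fixed-range
variant behind a flag; the two agree whenever an image attains the clip
ceiling. Identical images report PSNR = +∞. Method comparison reports
mean ± sd per metric, the mean of per-image relative improvements over the
CBCT baseline (sign-flipped for SSIM/PSNR so improvement is positive when
the metric rises), and a paired two-sided Wilcoxon signed-rank p-value
(chosen for robustness; the underlying per-image differences are not
assumed normal).

## Benchmark and ablation scales

The reference benchmark simulates 40 patients × 8 slices at 64 px, trains
the base-16 network with the 10/6/4 schedule, and evaluates on the 8
held-out test patients; on it the synthetic CT roughly halves the CBCT MAE
and gains several dB of PSNR. Synthetic-CT evaluation restores the
background to air through the known body mask (recovered exactly from the
preprocessed CBCT, whose background is −1000 by construction), mirroring
the body masking applied to every other image in the pipeline. The
ablation driver runs the four loss-lambda variants plus a single-stage
baseline at a smaller scale (24 patients × 4 slices at 32 px, base-8
network, 20/12/10 epochs), enough for every variant to train meaningfully
and be ranked against the uncorrected CBCT within a desk-scale compute
budget. On short schedules the single-stage baseline can outperform
hierarchical training — the coarse stages consume most of the epoch
budget — which reverses at longer schedules where the warm-started fine
stages pay off. Determinism is exercised end-to-end: the same seeds
reproduce dataset content hashes bit-exactly and final metrics to
floating-point tolerance.

## Known limitations

* 2D slices only; no volumetric context.
* The artifact menu is phenomenological; severity parameters are scale
  bound (blur and streak widths are specified in pixels).
* Batch normalisation running statistics make early-epoch evaluation-mode
  predictions lag training-mode behaviour on very short schedules.
* The NumPy training loop is single-threaded-BLAS friendly but not fast;
  the full 400-px / base-64 configuration is supported but intended for
  patient runs, not CI.
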