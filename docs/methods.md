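# Methods

## What the benchmark models

`lcdbench` is a fully synthetic re-creation of a low-contrast
detectability (LCD) study on CT phantom images. The real experiment
behind this class of study crops homogeneous patches from a phantom
scan, hides or shows a single faint disk-shaped object per patch, and
asks observers — a trained convolutional network, a classic
template-matching observer, and human readers scoring a 1–5 confidence
scale — whether an object is present. Detectability is summarized per
imaging condition (tube current–time product in mAs, reconstruction
flavor, object size) as an ROC AUC, and the observers are compared
with multi-reader multi-case (MRMC) statistics.

Everything here is simulated, which is the point: every module is
testable against analytic oracles, and the full factorial design can
be regenerated from one seed.

## Phantom patch simulation

A patch is a 5 × 5 cm² square of Hounsfield units. The default raster
is 64 px at 0.78125 mm/px, chosen so that 5 cm maps exactly onto a
power-of-two grid (convenient for a detector that halves its feature
maps seven times); the raster is configurable.

* **Background**: homogeneous mean of 70 HU (the display window level
  of the emulated study) plus zero-mean Gaussian noise. White noise is
  the default because it keeps every oracle analytic (matched-filter
  SNR, disk mass, sample moments); an optional isotropic Gaussian
  correlation kernel is available since real CT noise is correlated.
* **Dose scaling**: quantum noise dominates CT noise, so the standard
  deviation scales as `sigma(mAs) = sigma_ref * sqrt(mas_ref / mAs)`.
  `sigma_ref` defaults to 10 HU at 200 mAs — the physical noise level
  of the emulated scanner is not recoverable, so this is an explicit
  free parameter chosen to make the 5 mm / +10 HU task hard and the
  9 mm task easy at high dose.
* **Reconstruction flavors**: `FBP` is the reference; `ADMIRE`
  (iterative-reconstruction-like) multiplies the noise amplitude by
  0.7 and then smooths the noise field with a 0.5 px Gaussian.
  Iterative reconstruction mainly reduces noise magnitude with a mild
  texture shift; both knobs are configurable and the smoothing is
  applied to the noise only, so the object's edge profile is
  reconstruction-independent.
* **Objects**: anti-aliased disks, rendered by incrementing pixel
  values by the covered-area fraction of the disk (4× per-axis
  subpixel sampling). The disk must lie entirely inside the patch.
  Coordinates are in mm from the top-left corner with pixel centers
  at `(i + 0.5) * spacing`.
* **Designs**: the training generator draws, for half of the images, a
  single object with diameter ~ U(3, 20) mm and contrast ~ U(5, 30) HU
  at a uniform in-bounds center, all under one acquisition condition
  (200 mAs, FBP). The test generator builds the full
  dose × reconstruction × size factorial with an exact present/absent
  split per cell — 640 images with the default grid (4 doses × 2
  reconstructions × {5, 9} mm × 20/20). Object-absent rows record the
  cell's nominal diameter so every image's stratum is recoverable.
* **Seeding**: one global seed expands into per-case seeds through
  `SeedSequence` entropy pooling; the per-case seed is stored in the
  manifest, making every image a pure function of its manifest row.

## Residual CNN observer

The detector follows a residual-learning design: seven levels, each a
residual block (two 3×3 convolutions with batch normalization and
ReLU, identity shortcut, 1×1 projection when channels change)
followed by 2×2 max-pooling, then a fully-connected layer over the
flattened final feature map with a two-way softmax. Reference filter
counts are 64, 128, 256, 512, 1024, 2048, 4096; `width_scale` shrinks
all of them proportionally, and the desk-scale default is 1/8
(8…512 filters, ~5 M parameters). With a 64-px input the halving
chain reaches 1×1 after six poolings, so the seventh level operates
at 1×1 and its pooling is skipped; a 128-px input activates all
seven.

Training is plain minibatch Adam (initial learning rate 1e-4, the
only optimizer constant the emulated study pins down; no schedule) on
the softmax cross-entropy of the binary present/absent ground truth,
from scratch, with a seeded label-stratified 90/10 train/validation
split. Input normalization is the fixed affine map (HU − 70)/25 — no
batch statistics at inference time. By default each training batch is
augmented with a random dihedral transform (rot90 + optional flip):
the detection task is exactly symmetric under that group, and at
desk-scale training sizes (10³–10⁴ images) the augmentation closes
most of the train/validation generalization gap. It can be disabled
in the config.

The layer stack itself (`lcdbench.nn`) is a small, self-contained
NHWC implementation with explicit backpropagation: direct numba
kernels for 3×3 convolutions while feature maps are spatially large,
im2col + BLAS matmuls once they are small and channel-heavy, and an
argmax-routed max-pool. Training is single-threaded CPU and
deterministic for a fixed seed.

### Grad-CAM

Heatmaps are gradient-weighted class activation maps: channel weights
are the spatial means of the target-class logit gradient at a chosen
residual block's output, and the map is the rectified weighted sum of
that block's features, bilinearly upsampled to the input. The common
convention of using the last convolutional layer is useless here —
the final block works at 1×1 and carries no spatial information — so
the default source is the deepest block whose feature map still
resolves the smallest test object: cells must be finer than a 5-mm
disk radius (~3 px), giving the 16×16-map level on a 64-px input. The
level is an explicit argument.

## Template-matching observer

A noise-free disk template (rendered by the same kernel as the
simulator) is slid over the patch; each offset is scored with
zero-normalized cross-correlation, and the case score is
`(max ZNCC + 1)/2 ∈ [0, 1]`. ZNCC is invariant to the window mean and
to positive rescaling — the natural similarity for a low-contrast
task on an arbitrary HU offset. Zero-variance windows score 0 (a flat
region carries no evidence). By default the template diameter is
matched to each test cell's object size (a matched-filter reading); a
fixed-diameter mode exists. The observer's ROC uses ten fixed
thresholds k/9, k = 0…9 — an inclusive even grid over [0, 1] — with
trapezoid AUC over the operating points anchored at (0,0) and (1,1).

## Simulated readers

Each reader is an equal-variance binormal decision maker: the latent
value on a case is N(0, 1) plus the reader's detectability index d′
for that case's condition cell when an object is present; four
increasing cutpoints (default −1, 0, 1, 2) convert the latent value
to a 5-point confidence rating. The closed form AUC = Φ(d′/√2) makes
the whole MRMC chain testable against an analytic target (d′ = 1 →
AUC 0.760). Panels are built by a profile factory with optional
reader-to-reader d′ jitter and descriptive "attending"/"trainee"
presets. No inter-reader error correlation beyond case sharing is
modeled — there is no defensible way to set its magnitude.

## Statistics

* **Empirical AUC**: rank-based all-pairs estimate, ties credited
  0.5; equivalent to the trapezoid over the exhaustive-threshold ROC.
* **Standard error**: the Hanley–McNeil closed form with
  Q1 = A/(2−A), Q2 = 2A²/(1+A); two AUCs are compared with
  z = ΔA / sqrt(SE₁² + SE₂²) and a two-sided normal p.
* **MRMC pooling**: unweighted mean of per-reader empirical AUCs with
  a case-level bootstrap (readers fixed, cases resampled with
  replacement) for SE and percentile CI. This is deliberately *not*
  the U-statistic variance decomposition of full MRMC software; the
  reader sample is treated as fixed.
* **Multiplicity**: Benjamini–Hochberg step-up adjustment, reported
  alongside the fixed significance thresholds 0.00625 (primary
  family) and 0.0125 (post-hoc family) that the report tables also
  print.
* **Robustness (AUC-reduction) test**: for a reference and a degraded
  condition arm, each bootstrap replicate resamples cases and
  computes Δ* = (AUC_A,ref − AUC_A,deg) − (AUC_B,ref − AUC_B,deg),
  with modality B pooled over readers; z = mean(Δ*)/sd(Δ*), two-sided
  normal p, percentile 95 % CI, 2000 replicates by default. When the
  two arms have equal case counts (the factorial always does) the
  index draw is shared between arms, which makes the
  identical-arms null exactly degenerate; independent resampling is
  available. Replicates that lose a class are redrawn (at most 100
  attempts). Under equal true reductions the test's type-I error is
  close to nominal (the acceptance suite measures ≈ 0.05–0.06 at
  α = 0.05 over 500 Monte-Carlo repetitions).

## Problem sizes used by the test and acceptance runs

The suites run at desk scale as the package's own standard profile:
width-1/8 detector, 2,000 training cases and 10 epochs for the
task-performance checks, 200 cases per condition cell for
detectability curves, 2,000 cases for reader-model recovery, 200–2000
bootstrap replicates, and 500 Monte-Carlo repetitions for the
calibration check. Full-width (width_scale = 1) and full-size
(n = 10,000) runs use the identical code paths through the config.

## What the synthetic data does and does not show

The generator reproduces the *design* of an LCD phantom study
(factorial structure, exact splits, dose-noise scaling, object
geometry) but not the physics: there are no sinograms or actual
reconstructions, noise is white by default rather than textured,
ADMIRE is a two-parameter emulation, and `sigma_ref` is not
calibrated to any scanner. Passing tests therefore demonstrate that
the algorithms and statistics behave correctly on a controlled world,
not that any particular AUC value transfers to real scans or real
readers.

Known limitations observed in this world:

* A detector trained at a single noise level can collapse to constant
  output (AUC 0.5) under strong noise-level shift — batch-norm
  statistics and learned features are dose-specific. The detectability
  monotonicity checks hold, but the degradation is abrupt rather than
  graded; training across conditions is the obvious extension.
* Batch-norm running statistics need a few hundred optimizer steps to
  stabilize; very short smoke trainings predict poorly in eval mode
  even when the training loss is low.
* The ten-threshold ROC underestimates the exhaustive-threshold AUC
  slightly when scores cluster inside one threshold bin; the
  acceptance suite bounds the gap at 0.05.
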