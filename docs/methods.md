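# Methods

## Problem

Ultra-wide-field (UWF) scanning-laser fundus photography images ~200° of the
retina through an undilated pupil, so eyelashes frequently cross the optical
path and cast dark, curved, semi-transparent shadows over the retina. These
artifacts obscure vessels and lesions and degrade downstream analysis.
`lashgan` restores artifact-free images from corrupted ones with a learned
image-to-image mapping, and ships a synthetic phantom simulator so the whole
pipeline trains, evaluates and reproduces without any patient data.

## Model

The restoration mapping is a conditional generative adversarial network
trained jointly from two data regimes:

* **Paired regime.** Pixel-aligned corrupted/clean pairs (x_p, y_p). The
  shared generator G produces a candidate G(x_p); a conditional
  discriminator D1 scores the channel-concatenated pair (x_p, ·) as real
  (x_p, y_p) or fake (x_p, G(x_p)); an L1 generation loss ties G(x_p) to
  y_p; and a background refinement module R — a second network with the same
  U-shape but independent parameters — post-processes G's output, trained
  with its own L1 refinement loss ||y_p − R(G(x_p))||₁.
* **Unpaired regime.** Disjoint pools of corrupted images x_u and clean
  images y_u with no correspondence. An unconditional discriminator D2
  scores single images as real clean images versus generated G(x_u). Only G
  and D2 learn from these steps; R and the paired losses are untouched
  because their definitions require a paired reference.

The total generator objective is

    L = L_ca + λ1·L1 + L_uca + λ2·L_ref,      λ1 = 100, λ2 = 10,

where L_ca and L_uca are the conditional/unconditional adversarial terms.
All losses are means over map elements, pixels, channels and batch, so the
weights are independent of image and confidence-map size. Discriminator
losses are binary cross-entropy pushing real maps toward 1 and fake maps
toward 0, averaged over the two halves; an uninformative discriminator sits
exactly at ln 2. The generator minimizes the non-saturating surrogate
−log D(fake) by default; a flag restores the literal minimax form
log(1 − D(fake)), which saturates early in training and is provided for
completeness only.

Inference runs R(G(x)) (or G(x) for variants without the refiner).

### Architectures

G and R are U-shaped encoder/decoders with symmetric skip connections.
Each of the `depth` (default 8) encoder stages is a 4×4 stride-2 convolution
with batch normalization and leaky ReLU (slope 0.2); the deepest stage drops
normalization and uses ReLU. Decoder stages are 4×4 stride-2 transposed
convolutions with batch normalization and ReLU; the last stage drops
normalization and squashes through tanh, so outputs live in (−1, 1) on the
model scale x = pixel/127.5 − 1. Channel widths follow base·2^i capped at
512 (the canonical 64…512 schedule at full scale). The stochastic input of
the adversarial formulation enters as dropout (rate 0.5) in the first three
decoder stages, active only during training; `noise_mode="none"` disables
it. Batch normalization bypasses itself when a channel has fewer than two
elements (the 1×1 bottleneck with batch size 1), where batch statistics are
degenerate.

D1 and D2 are PatchGAN-style stacks of five 4×4 convolutions with strides
(2, 2, 2, 1, 1), padding 1, batch normalization in stages 2–4, leaky ReLU,
and a final sigmoid producing a confidence map — for a 256² input, a 30×30
map whose elements each judge one receptive field. D1 sees 6 input channels
(input ⊕ candidate); D2 sees 3.

### Numerical engine

The layer stack (convolution, transposed convolution as its exact adjoint,
batch normalization, activations, dropout, Adam) is implemented directly on
NumPy arrays with hand-derived backward passes; convolutions reduce to 16
BLAS `tensordot` calls (one per 4×4 kernel offset). Gradients are validated
against finite differences in float64 in the test suite. Training arithmetic
is float32.

### Optimization

Adam with learning rate 2·10⁻⁴ and β = (0.5, 0.999) — the low first moment
is the standard choice for adversarial training — for all four networks.
Paired and unpaired steps alternate 1:1 (paired first; configurable ratio).
Random horizontal flips (p = 0.5) augment paired batches, applied
identically to the corrupted and clean image of a pair. Discriminator and
generator updates are strictly isolated: gradients pushed through a
discriminator during a generator update are discarded before that
discriminator's own next update (verified by parameter hashing in tests).
Each epoch ends with validation PSNR/SSIM on a held-out 10% paired split
(fixed by seed), and the parameters with the best validation PSNR are the
ones returned. At full scale the regime is 1024×1024 patches, batch 15, 200
epochs (`full_scale_config()`); the learning rate is constant, with an
optional linear decay left off by default.

### Ablation variants

`cgan_sub` (G + D1: conditional adversarial + L1), `cgan_ref` (adds R and
the refinement loss), `cgan_gan` (adds D2 and the unconditional loss), and
`full` (all components). Variant gating is enforced: e.g. an unpaired step
under `cgan_sub` is a `VariantError`, and R's parameters are bit-identical
before and after unpaired steps.

## Synthetic phantoms

The simulator emulates the appearance of UWF fundus patches, not any
specific device's photometry:

* **Clean phantom**: a bright elliptical field of view (semi-axes ≈ 0.46 and
  0.40 of the image) on a near-black surround, a warm base color
  (192, 112, 58) with a radial intensity falloff (35% at the rim), additive
  Gaussian texture noise (σ = 4 intensity units), and a recursive binary
  vessel tree: roots on the rim pointing inward, each branching level
  multiplying the width by 0.7 (root width 6 px at 256²) and darkening the
  background by 55% where it passes.
* **Eyelash strokes**: quadratic Bézier curves rooted exactly on a border
  (top/bottom with probability 0.45 each — lashes hang from the eyelids —
  left/right 0.05), pointing inward within ~50° of the border normal.
  Per-image stroke count is uniform in [15, 35]; arc length uniform in
  [130, 290] px at 256² (strokes are uniformly rescaled about their root so
  the Bézier arc length equals the sampled target exactly); root width
  uniform in [4, 9] px tapering to 30% at the tip; opacity uniform in
  [0.6, 0.95]. Widths and opacity are chosen so the artifact is a prominent
  occlusion, as real lashes are, rather than a hairline.
* **Compositing**: per-stroke hard rasterizations scaled by opacity combine
  by union (max), are blurred (σ = 1 px at 256²), and receive a faint wide
  halo (Gaussian at 4σ + 3 px, weight 0.12) before clipping to [0, 1]; the
  corrupted image is (1 − α)·clean + α·shade with the dark shade
  (16, 10, 10). Linear alpha compositing is the simplest law that leaves
  off-artifact pixels bitwise identical to the clean image; blur tails below
  10⁻³ are clamped to exact zero to keep that guarantee meaningful. The
  ground-truth artifact mask is α > 0.05, small enough to include halos.

All pixel quantities rescale linearly with image size (`scaled_to`), with
256² as the reference scale and 1024² matching full training patches.
Per-sample seeds derive from the master seed and sample index through
`numpy.random.SeedSequence`, so datasets are bit-reproducible and extensible
without reshuffling; paired, unpaired-corrupted and unpaired-clean pools use
disjoint seed namespaces, so the unpaired pools share no underlying phantom.

What the simulator does **not** model: device photometry, lesions and
pathology, eye movement or montage seams, the statistics of real retinal
texture, and real eyelashes' fine structure (barbs, clumping, specular
reflection). A model that restores phantoms is therefore demonstrated to
remove *this family* of synthetic occlusions; transfer to clinical images
must be established on clinical data.

## Metrics

* **PSNR** = 10·log₁₀((2ⁿ−1)²/MSE) dB on the 8-bit scale (n = 8), +∞
  sentinel for identical images.
* **SSIM** with stability constants c₁ = (0.01·255)², c₂ = (0.02·255)².
  The default mode computes the formula once from whole-image means,
  variances and covariance (population variance); a sliding-window mode
  (uniform 11×11, interior windows) is provided for cross-checks against
  common implementations. Note c₂ uses k₂ = 0.02 where most libraries
  default to 0.03; both are configurable. Color images average per-channel
  scores.
* **ENL** = μ²/σ² over a region of interest (grayscale = unweighted channel
  mean, population variance, minimum region 64 px). ENL rates the smoothness
  of a homogeneous area, so the evaluation region for artifact removal is
  the artifact's support restricted to bright background
  (`artifact_background_region`): including vessels or the dark surround
  would add structural variance unrelated to the artifact.

## Desk scale and defaults

Training defaults target a desk-scale experiment that a CPU can run in
minutes: 64×64 phantoms, network depth 6, base width 8, batch 4, 30 epochs,
48 paired + 48 unpaired training samples and 16 held-out test pairs (the
sizes used by `scripts/acceptance.py` and the end-to-end tests). At this
scale the full model's restoration gain on held-out pairs is about +3 dB
PSNR over the corrupted baseline, and ENL in homogeneous artifact regions
increases by an order of magnitude. Desk-scale numbers characterize the
method's mechanics on phantoms; they are not comparable to results on
clinical datasets at full scale.

## Known limitations

* Pure-CPU training: the full-scale 1024²/200-epoch regime is supported by
  the code but impractical without accelerator hardware.
* Single in-flight forward per network: the training loop is sequential by
  design; there is no multi-device or mixed-precision path.
* The global-statistics SSIM default follows the single-statistics formula;
  windowed SSIM values differ (as they do between published
  implementations) and should not be mixed in one comparison.
* GAN training at desk scale is noisy across seeds; the best-validation
  checkpoint and median-over-seeds reporting damp but do not remove this.
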