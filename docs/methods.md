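# Methods

## The problem and the model

Label-free microscopy modalities that derive contrast from intrinsic
absorption (for example mid-infrared photoacoustic imaging of proteins)
trade molecular specificity for spatial resolution: long illumination
wavelengths limit the lateral resolution to several micrometres, while
confocal fluorescence microscopy of the same cells resolves sub-micrometre
structure but requires staining. This package implements an unsupervised
inter-domain transformation that bridges the two: it learns, from *unpaired*
image sets, to map low-resolution label-free tiles (domain A) to
high-resolution virtually stained tiles (domain B, two fluorescence
channels: blue = nuclei, green = filamentous actin).

The learner is a cycle-consistent adversarial network with two additional
content-preservation terms. Two generators G_A : A→B and G_B : B→A and two
discriminators D_A, D_B are trained simultaneously with the objective

    L = L_GAN(G_A, D_B) + L_GAN(G_B, D_A)
        + λ L_CYC(G_A, G_B) + ξ L_SSIM(G_A, G_B) + ρ L_S(G_A, G_B, T_A, T_B)

with least-squares adversarial terms

    L_GAN(G_A, D_B) = E_b[(D_B(b) − 1)²] + E_a[D_B(G_A(a))²],

cycle consistency L_CYC = E_a‖G_B(G_A(a)) − a‖₁ + E_b‖G_A(G_B(b)) − b‖₁,
a structural term L_SSIM = E_a[1 − SSIM(a, G_B(G_A(a)))] + E_b[1 − SSIM(b,
G_A(G_B(b)))], and the saliency constraint

    L_S = E_a‖σ((a − T_A)·g) − σ((G_A(a) − T_B)·g)‖₁
        + E_b‖σ((b − T_B)·g) − σ((G_B(b) − T_A)·g)‖₁,

where σ is the logistic function and g = 100 the gain. The saliency term
exploits the fact that microscopy backgrounds are homogeneous: the soft
threshold mask of an image is a cheap content segmentation, and forcing the
mask of a translation to agree with the mask of its input pins the layout of
the content through the domain transfer. This is the model's
explainability device — the masks can be monitored during training, and
Grad-CAM heatmaps of the generator's residual blocks show where the model
attends. An identity loss is deliberately absent from the objective; it
does not help content preservation in this setting.

The generator-side adversarial target is E[(D(G(a)) − 1)²], the standard
least-squares split; the discriminator head is linear (no terminal sigmoid)
because least-squares scores regress to {0, 1} and a squashing nonlinearity
would saturate gradients.

### Two deployment frameworks

`run_uidt` supports the end-to-end configuration (one model, A→B directly)
and the pipeline configuration: a resolution-enhancement stage
(grayscale→grayscale) followed by a virtual-staining stage
(grayscale→two-channel), each a separately trained translation model. Stage
chaining re-normalises the intermediate image to [0, 1] and back to the
network range so the second stage sees its training distribution.

## Architecture

Generator: ResNet-style translator. A stride-1 3×3 convolution lifts the
3-channel input to 64 features (a small first kernel keeps fine detail);
two stride-2 Convolution–InstanceNorm–ReLU layers halve the spatial size
and double the channels (64→128→256); nine residual blocks operate at the
bottleneck; two upsampling stages each bilinearly double the tensor and
halve the channels, with skip connections from the matching downsampling
level merged by channel concatenation plus a 1×1 fusion convolution (the
merge rule is our choice; the skips themselves are part of the design);
a final 3×3 convolution restores 3 channels and tanh maps to [−1, 1].
Reflection padding everywhere (chosen over zero padding to avoid border
artefacts). Grayscale tiles are replicated to 3 channels and two-channel
stained tiles are embedded as RGB with the red plane zeroed, so both
generators are shape-symmetric.

Discriminator: five blocks of two 3×3 convolutions + leaky-ReLU (slope 0.2)
with channel doubling, each followed by stride-2 average pooling, then two
fully connected layers (hidden width 512) to a single unbounded score per
(sub)tile. The input may be subdivided into subtiles scored independently
with the image score their mean; the default scores the whole tile
(the subdivision size is configurable).

Grad-CAM: the mean of the generator output (or any scalar reduction) is
backpropagated to a chosen residual block; per-channel weights are the
spatially averaged gradients; the heatmap is the ReLU of the weighted
activation sum, bilinearly resized to the input and max-normalised. One
analytic caveat: the spatial mean of a gradient passing backward through
instance normalisation is exactly zero per channel (the normaliser removes
the constant mode), so with a linear scalar target the classical
global-average weights of a block that feeds an instance-normalised path
nearly cancel, and the map is carried by boundary effects of the padded
convolutions and the upsampler. Nonlinear targets (for example the sum of
squared outputs) or region-restricted targets give better-conditioned
maps; the target is a caller-supplied callable for exactly this reason.

## Numerical backend

The networks, backpropagation and Adam are implemented on numpy through a
small reverse-mode autodiff engine (`staincycle.nn`): tensors record their
parents and a backward closure, convolution uses im2col with explicit
column-gradient scatter, instance normalisation is a fused operator, and
bilinear upsampling is an explicit separable linear map (so its transpose is
exact). Gradient correctness of every operator is property-tested against
central finite differences. Training is pure CPU and bit-reproducible given
a seed; `no_grad` disables graph construction at inference.

## Training procedure

Per iteration: both generators are updated jointly on one batch from each
domain (adversarial + cycle + SSIM + saliency terms), then both
discriminators are updated on real images and a 50-image history pool of
past fakes (with 1/2 probability a remembered fake replaces a fresh one).
Optimiser: Adam, learning rate 2·10⁻⁴, β = (0.5, 0.999), constant for the
first half of training then linearly decayed — the established convention
for this family of models; the batch size defaults to 1. Domains are
shuffled independently every epoch from the run seed; pairing metadata is
structurally invisible to the trainer.

SSIM inside the loss uses the global (single-window) form of the index by
default — it is differentiable, cheap, and exactly matches the metric
module's oracle configuration; the windowed form is available. Images are
remapped from the network range to [0, 1] before the SSIM and saliency
terms; the cycle term operates in the native network range.

Thresholds T_A, T_B default to Otsu's method over the training tiles of
each domain at startup, with manual override — mirroring the practice of
hand-calibrating the masks until they segment content satisfactorily.
Loss weights default to λ = 10 (cycle-GAN convention), ξ = 1, ρ = 1; all
are configuration.

## Evaluation metrics

* PSNR: 10·log₁₀(MAX²/MSE) in dB, MSE averaged over all pixels (the
  rectangular generalisation of the square-image form). A `raw_ratio` mode
  computes the unlogged ratio 10·MAX²/MSE for completeness. Identical
  images report +∞.
* PCC: cross-covariance over the product of standard deviations, over all
  pixels; undefined (error) for constant images.
* SSIM: `(2μ_aμ_b+c₁)(2σ_ab+c₂)/((μ_a²+μ_b²+c₁)(σ_a²+σ_b²+c₂))` with
  c₁=(0.01L)², c₂=(0.03L)². Global mode evaluates it once per image;
  windowed mode (default for reporting) averages over 11×11 Gaussian
  windows (σ=1.5), using fully valid windows only, and is cross-checked
  against scikit-image's implementation.
* FID: Fréchet distance ‖μ_X−μ_Y‖² + Tr(Σ_X+Σ_Y−2(Σ_XΣ_Y)^{1/2}) between
  Gaussian fits of embedded feature sets; the matrix square root is taken
  with an εI (10⁻⁶) regularisation fallback and validated by squaring.
* KID: unbiased squared maximum mean discrepancy with the cubic polynomial
  kernel k(x,y) = (xᵀy/d + 1)³; optionally averaged over random subsets.

The feature embedding behind FID/KID is pluggable. The default shipped
embedding is a deterministic seeded random projection of 8×8
average-pooled patches (64 dimensions). It requires no pretrained weights,
is fully reproducible offline, and preserves coarse intensity layout —
sufficient for the relative comparisons made here. FID/KID values are only
comparable within one embedding and every report names the embedding used;
values computed with this embedding are not numerically comparable to
published scores obtained with pretrained-classifier activations.

## Synthetic microscopy scenes

The data generator emulates the structure of cultured-fibroblast imagery:
oval nuclei (random semi-axes, orientations and centres; optional
no-overlap placement by rejection sampling) rendered into the blue channel,
and curvilinear actin filaments (Catmull-Rom curves through random control
points, rasterised at fixed width and feathered by a 1-px Gaussian) into
the green channel. Nuclei render at unit amplitude with a 0.7-px edge
feather, so a 0.5 hard threshold recovers the analytic ellipse boundary and
pixel-count areas match πab to within rasterisation error.

From each stained scene, a label-free image is derived as the nonnegative
channel mixture 0.6·blue + 0.4·green plus a constant background (0.05) —
nuclei dominate the label-free signal — and the low-resolution counterpart
is a Gaussian blur with σ_px = FWHM / (2√(2 ln 2) · pixel size) plus
additive Gaussian noise (sd 0.01), clipped to [0, 1]. Defaults model a
6.6 μm optical FWHM against a 0.31 μm/pixel grid (σ ≈ 9.0 px). Boundary
handling is reflective, which conserves total intensity exactly (the
symmetric extension is preserved by a symmetric kernel), giving a sharp
test of kernel normalisation. Unpaired datasets render domains A and B
from disjoint scene seeds; paired mode reuses scenes and returns the
pairing index for evaluation only.

What the generator does **not** emulate: photoacoustic image formation
(the blur is an optical surrogate), spatially varying illumination, camera
noise statistics, out-of-focus light, touching/overlapping nuclei, or
texture within organelles. Tests passing on these scenes therefore
validate the machinery (losses, optimisation, composition, metrics,
morphometrics) — not biological image quality on real data.

## Scaled-down study condition

The desk-scale condition used by the tests and the acceptance script is 32
tiles of 64×64 px per domain, one residual block, base width 16 (generator)
/ 8 (discriminator), batch 1, 200 iterations. Tiles are rendered at a
4×-coarsened pixel size (1.24 μm/px) so one 64-px tile spans ~80 μm and
holds a few nuclei while the physical 6.6 μm PSF is kept. On one CPU a run
takes about a minute.

Two readouts are reported. First, the cycle term falls well below its
initial value (typically 1.7 → 0.2). Second, the saliency ablation: the
run is repeated with ρ = 1 and ρ = 0 over three seeds and the agreement
(mean IoU) between the hard content mask of each input (threshold T_A) and
that of its translation (threshold T_B) is compared; the constrained
setting must score at least as high. Two honest caveats, visible in the
reported numbers: at this tiny scale the adversarial pressure toward the
mostly dark target domain compresses output amplitudes below the
domain-calibrated thresholds within ~100 iterations, so the
fixed-threshold IoU is near zero for *both* settings and the ordering
holds only degenerately; and because the gain-100 sigmoid saturates
outside a ±0.05 band around the threshold, the saliency term receives
almost no gradient once the outputs have collapsed, so its protective
effect is not resolvable in 200 iterations. An amplitude-free variant
(translation mask thresholded by Otsu's method over the translated set
itself) is also computed and reported; it too does not separate the
settings at this scale. Demonstrating the separation would need
full-scale training, which is outside the desk budget; what the ablation
does establish here is the stated ordering and the optimisation's health
(cycle-term decrease) under both settings.

## Morphometrics

Stained tiles are split losslessly into blue and green planes. Nuclei:
hard threshold (default 0.5), removal of components under 20 px (~1.9 μm²
at 0.31 μm/px), 8-connected labelling; per component the area is the pixel
count times the squared pixel size and the aspect ratio is the major/minor
axis ratio of the moment-equivalent ellipse, clamped to ≥ 1. Fibroblast
footprint: supra-threshold pixel count of the green plane times the pixel
area. No watershed splitting is attempted: overlapping-nucleus scenes are
outside the validated envelope. Whether aggregation should be per tile or
per slide is left to the caller; records are per tile with a trivial
aggregation in the CLI.

## Numerical and design choices

* Intensities are [0, 1] at the I/O boundary and [−1, 1] inside networks
  (tanh convention); 16-bit integer inputs are scaled by their dtype
  maximum before percentile normalisation.
* Tiling is deterministic grid tiling by default; a seeded random-offset
  mode exists. Cross-validation folds partition slides contiguously in
  input order (deterministic); four slides with k = 4 give the
  3-train/1-validation rotation.
* An optional 3×3 median pre-filter is provided but off by default.
* Constant images: normalisation returns zeros with a warning; PCC raises;
  PSNR of identical images returns +∞.
* Percentile normalisation uses linear-interpolated quantiles.
* The KID estimator may be slightly negative (unbiasedness); this is not
  clipped.
* One global seed fans out to per-purpose substreams (scene sampling,
  weight initialisation, shuffling) via `SeedSequence`, so substreams are
  stable when unrelated configuration changes.

## Known limitations

* No GPU path; the numpy backend is practical for the desk-scale condition
  and for inference of moderately sized models, not for full-scale training.
* The default FID/KID embedding is not a pretrained perceptual network;
  absolute scores are not comparable to published tables.
* The saliency constraint's protective effect is not resolvable at the
  desk-scale training length (see the study-condition section); the
  full-size condition (hundreds of tiles, 9 blocks, many thousands of
  iterations) would be required to demonstrate the separation.
* Unpaired training cannot guarantee per-structure correspondence; the
  saliency term constrains layout, not identity.
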