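# Methods

## The model

`busynth` implements a two-stage generative pipeline for breast-ultrasound
(BUS) image synthesis that produces each image together with its tumor
segmentation mask, so synthetic data can feed both classification and
segmentation training without re-annotation.

**Mask stage (MGS).** A DCGAN-style generator G1 maps a latent vector
z ~ N(0, I) to a tumor-contour mask on the tanh scale [-1, 1].  G1 projects
z to a low-resolution seed grid (8x8x512 at 256 px; the seed side always
equals `image_size / 2^n_blocks`) and applies one 4x4 stride-2 transposed
convolution per block with batch normalization and ReLU, widths decreasing
along the stack, followed by a stride-1 smoothing convolution and tanh.
The discriminator D1 stacks 4x4 stride-2 convolutions — each spectrally
normalized, LeakyReLU(0.2), dropout — and collapses the remaining grid with
one valid convolution to a single sigmoid realism probability.  The losses
are the original minimax forms

    L_G1 = E_z[ log(1 - D1(G1(z))) ],
    L_D1 = E_y[ log D1(y) ] + E_z[ log(1 - D1(G1(z))) ],

exposed exactly as written (discriminator objectives are returned negated so
every optimizer minimizes).  Training defaults to the standard
non-saturating generator surrogate -E_z[log D1(G1(z))], which has the same
fixed points but usable early gradients; the literal saturating form is a
config switch.  Generated masks are binarized at threshold 0 on the tanh
scale before they enter the image stage.

**Image stage (IGS).** G2 translates a mask (presented as {-1,+1}) into a
textured image through an encoder-decoder: 1x1 channel adapter, four 3x3
stride-2 convolution blocks with instance normalization, `n_residual_blocks`
residual blocks (two stride-1 convolutions each), four mirrored transposed
convolution blocks, and a 1x1 tanh output adapter.  D2 is a patch
discriminator over the channel-concatenated (mask, image) pair: four
spectrally normalized 4x4 stride-2 blocks and a stride-1 score convolution
producing a grid of per-patch probabilities (16x16 at 256 px input).  Its
adversarial losses are the patch-averaged analogues of the MGS losses.

**Feature-matching loss (FML).** D2 doubles as the feature extractor: with
D2^(i) the activation of down-sampling block i (M = 4 blocks tapped) and
N_i its per-sample element count,

    L_FM = E[ sum_i (1/N_i) || D2^(i)(x, y) - D2^(i)(G2(y), y) ||_1 ],

and the full generator objective is L_G2 + lambda * L_FM with lambda = 10.
FML is computed on clean (un-augmented) pairs: the definition contains no
augmentation operator, and keeping it clean preserves the exact reduction
of the augmented objectives to the plain ones under the identity policy.

**Differentiable augmentation (DAM).** Every input the discriminators see —
real and generated alike — passes through the same augmentation policy with
independently drawn per-sample parameters; all ops are differentiable in
their input so generator gradients survive.  Identical parameter values
across the real and fake batch are neither possible (the batches differ)
nor intended by the underlying augmentation scheme.  Default policy:
brightness (uniform shift in ±0.5 on the [-1,1] scale) then translation
(±1/8 of the image side, zero-padded); contrast and cutout are implemented
and off by default.  No clipping happens inside the ops.  For IGS the
concatenated pair is augmented as one unit — spatial ops move mask and
image together, intensity ops touch the image channel only (a shifted image
with an unshifted mask would be an invalid pair).

**Training protocol.** Per-class training (separate benign and malignant
models), mask stage independent of the image stage; IGS trains on real
(mask, image) pairs only, and generated masks enter only at sampling time
(noise -> mask -> binarize -> image).  One discriminator step alternates
with one generator step per batch; Adam with betas (0.5, 0.999), batch 16.
Image-stage learning rates are 1e-4 (G) / 4e-4 (D).  The mask-stage rates
are not fixed by the protocol we follow; at desk scale the 4:1 ratio lets
D1 overpower G1 (generated masks fragment into several components), so the
mask stage defaults to lr_D = 2e-4.  Both are plain config fields.

Two further stabilizers apply to the mask stage, both configurable and
both off-switchable:

- **Target antialiasing.** The real contour images are smoothed with a
  sigma = 1.0 Gaussian before the tanh mapping.  Hard {-1,+1} edges lie
  outside a tanh generator's reachable set, and a discriminator that can
  win on edge saturation alone stops teaching the generator anything about
  shape; the smoothed targets keep the two distributions comparable.  The
  binarized statistics of the training masks are unchanged.
- **Tail weight averaging.** The returned generator carries an exponential
  moving average (decay 0.98) of its weights over roughly the final third
  of the run.  Adversarial updates oscillate around equilibria; the
  time-averaged iterate samples slightly more cleanly than whichever
  iterate the run happens to end on.  Averaging from the start is harmful
  (early iterates still move) and is not done.

## Tunable parameters that matter

| parameter | default | meaning |
| --- | --- | --- |
| `noise_dim` | 64 (desk) / 128 typical | latent dimension of the mask stage |
| `g1_channels` | (64, 32, 16, 8); (512…32) at 256 px | one up-block per entry; first entry = seed-grid channels |
| `d1_channels` | (16, 32, 64) | stride-2 D1 blocks before the scalar collapse |
| `out_kernel` | 5 | stride-1 smoothing kernel of G1's output layer |
| `n_residual_blocks` | 5 | G2 bottleneck depth (the experimentally validated setting) |
| `lambda_fm` | 10.0 | FML weight in the G2 objective |
| `dropout_rate` | 0.3 | discriminator dropout (0.2 used for the desk-scale mask stage) |
| `sn_power_iterations` | 1 per forward (+100 at init) | spectral-norm power iteration |
| `binarize_threshold` | 0.0 | tanh-scale mask binarization |
| batch / lr / betas | 16, 1e-4 / 4e-4 (2e-4 for D1), (0.5, 0.999) | optimizer settings |

Spectral normalization divides each discriminator weight matrix
(out_channels × everything-else) by its top singular value, estimated by
power iteration with a persistent left vector.  Random DCGAN-initialized
matrices have clustered top singular values, so a handful of iterations
underestimates sigma by more than 0.1%; the implementation therefore runs
100 warm-up iterations at layer construction and one per training forward,
keeping the effective top singular value within 1e-3 of 1 throughout
training.

## The phantom generator

Real BUS data cannot ship with the package, so a procedural phantom module
defines the study conditions.  Lesion contours are star-convex radial
curves r(θ) = r0 (1 + Σ_k a_k cos(kθ + φ_k)) drawn over an anisotropic
ellipse base, guaranteeing one simply-connected component; the harmonic
amplitudes scale with a roughness parameter that separates the classes
(benign: amplitude 0.05, 3 harmonics; malignant: 0.25, 8 harmonics — a
threshold on the isoperimetric ratio P²/4πA separates the default classes
with ≥90% accuracy).  The polygon is rescaled so its analytic area hits a
target fraction drawn from (0.04, 0.14) of the image, then rasterized and
rejection-checked.  Images are rendered as
clip(blur(base_tissue × lesion_darkening × speckle) × shadow): a layered
depth-graded background, a multiplicative interior darkening (hypoechoic
lesion, contrast 0.3–0.35), mean-one gamma-distributed multiplicative
speckle (shape 16; the noise-free limit is exact as shape → ∞), a Gaussian
point-spread blur (σ 0.8 px) and an optional posterior shadow under the
lesion.  Everything is a pure function of (spec, seed).

What the phantoms deliberately do not contain: physically propagated wave
fronts or scan-conversion geometry, operator annotations (calipers, text,
cross labels — present in real clinical exports), multi-lesion or
lesion-free fields, and realistic inter-patient texture variation.
Passing tests on phantoms therefore show that the pipeline learns the
mapping structure it claims to learn (noise → plausible single-lesion
masks; mask → consistently placed hypoechoic texture), not that it reaches
clinical image fidelity.

## Image-quality metrics

FID fits Gaussians to embedding sets and reports
||μa−μb||² + Tr(Σa+Σb−2(ΣaΣb)^{1/2}); the matrix square root uses the
symmetric eigen-route (Σa^{1/2} Σb Σa^{1/2}) with negative eigenvalues
clipped at numerical tolerance.  KID is the unbiased MMD² estimator under
the conventional polynomial kernel (degree 3, scale 1/d, offset 1), so
small negative values are legitimate; tables conventionally print KID×100
and the report layer does the scaling.  MS-SSIM follows the standard
pyramid: Gaussian 11x1.5 local statistics, stabilizers (0.01L)², (0.03L)²,
contrast/structure at every scale, luminance only at the coarsest, canonical
five-scale weights renormalized when fewer scales are used.  A 64 px image
supports at most 3 scales with the 11-tap window; the implementation refuses
larger M and names the required reduction.  Internal diversity is the mean
pairwise MS-SSIM over seeded sampled pairs of a generated set (lower =
more diverse).  Because no pretrained embedding network can be assumed,
embeddings come from a registry with two download-free extractors —
downsampled pixels and a fixed-seed untrained convolutional embedder —
and an adapter slot for an external pretrained embedder.  Absolute FID/KID
values are therefore not comparable to Inception-based numbers; only
within-extractor comparisons are meaningful.

## Downstream evaluation harness

Stratified 60/20/20 train/val/test split; minority-class oversampling with
replacement to the majority count; online augmentation at probability 0.3
per op (classification: translation, horizontal flip, rotation;
segmentation: rotation, blur, translation, gamma, scaling, additive
Gaussian noise; geometric ops co-transform the mask, which is then
re-binarized).  Conditions: baseline (no augmentation), traditional
augmentation (TA), TA + synthetic pairs (1:1 with the real training count by
default).  The classifier is a small from-scratch CNN (three stride-2
blocks, global pooling, linear head) rather than a pretrained VGG16 — the
harness measures the *relative* effect of augmentation conditions without
downloadable weights; a deeper classifier can be slotted in through the
config.  The segmenter is a width-reduced U-Net-style encoder-decoder with
skip connections, thresholded at 0.5.  Precision/recall/accuracy/F1 come
from hand-checked confusion-count formulas (degenerate denominators are
defined as 0 with a warning); Dice is 2TP/(2TP+FP+FN) with empty-vs-empty
defined as 1.  Classification reports mean±sd over stratified 3-fold
resampling.  A hard error is raised if any test sample object appears in
any training or synthetic pool.

Two evalkit-specific numerical choices: task models re-initialize at He
scale (the GAN-style N(0, 0.02) init collapses activations and stalls the
first epochs of plainly supervised training), and the segmentation BCE
weights lesion pixels by 8 (lesions cover ~8% of phantom pixels; unweighted
BCE traps some runs in the all-background minimum).  One honest caveat:
benign-vs-malignant classification on the default phantoms sits near chance
for the small classifier — the class difference is contour roughness, and
the unique per-image speckle dominates it at desk-scale sample counts (a
higher-capacity head reaches perfect training accuracy while staying at
chance on held-out data, i.e. it can only memorize).  The classification
arm therefore exercises the protocol (splits, oversampling, CV, metrics)
rather than demonstrating a detectable augmentation effect; the
segmentation arm shows both.

## Numerical and design choices

- **NumPy training core.** The networks run on a compact reverse-mode
  autodiff engine inside the package (`busynth.nn`): im2col/col2im
  convolutions arranged so each convolution is a single BLAS GEMM, fused
  normalization ops, Adam.  Float32 for training; all ops preserve dtype so
  float64 inputs give float64 results (the closed-form loss tests rely on
  this).
- **Residual-block count**: two counts circulate for this architecture
  family (9 vs 5); the default is 5, the experimentally validated setting,
  and it is configurable.
- **D1 width reading**: "widths decreasing 512 → 1 over six blocks" is
  realized as five stride-2 blocks (32…512 at 256 px) plus a final valid
  convolution to one channel — one consistent reading of an
  underdetermined description.
- **KID cross term**: the unbiased estimator's standard all-pairs cross
  term is used (an i≠j cross-term index sometimes printed for this
  estimator has no effect on off-diagonal-only sums and is not standard).
- **Mask convention**: lesion = 1, background = 0 everywhere in memory
  (inpainting-style descriptions sometimes invert this; the io layer owns
  the disk convention lesion = 255).
- **Desk scale**: the shipped defaults (64 px, thin width lists, hundreds
  of training steps, ~200-sample phantom datasets) are the study conditions
  for the test suite and the acceptance script; 256 px paper-scale configs
  are constructible (`MgsConfig.paper_scale()`, `IgsConfig.paper_scale()`)
  and shape-verified but not trained by the tests.
- **G1 output layer**: a 5x5 stride-1 smoothing convolution; with a 3x3
  output the thin full-resolution feature maps leave pixel-scale islands
  after binarization.
- **Degenerate inputs**: empty datasets, mismatched shapes, latent-dimension
  mismatches, scores outside (0,1), unknown augmentation ops and unknown
  config keys all raise immediately with named errors.

## Known limitations

- GAN training at a few hundred steps is noisy across seeds; the
  scaled-down recovery properties hold as medians over seeds, not
  per-seed guarantees.
- The NumPy core is single-process and CPU-bound; paper-scale (256 px,
  thousands of epochs) training is out of reach and out of scope.
- FID/KID absolute values depend on the bundled extractors and are not
  comparable across extractors or to published Inception-based numbers.
- Phantoms lack clinical artifacts; downstream gains measured on phantoms
  demonstrate harness correctness, not expected clinical effect sizes.
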