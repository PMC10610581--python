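# busynth

Two-stage GAN synthesis of **annotated** breast-ultrasound (BUS) images:
stage one maps Gaussian noise to a binary tumor-contour mask, stage two
translates the mask into a speckled B-mode-style image — so every synthetic
image arrives with its segmentation ground truth and can augment both
classification and segmentation training without re-annotation.

The package is aimed at researchers studying generative augmentation for
small, imbalanced medical imaging datasets.  It contains:

- **`busynth.mgs`** — the Mask Generation Stage: DCGAN-style generator G1
  (noise → mask, tanh output), spectrally normalized discriminator D1, the
  minimax losses `L_G1 = E[log(1 − D1(G1(z)))]`,
  `L_D1 = E[log D1(y)] + E[log(1 − D1(G1(z)))]` (returned negated for
  minimization).
- **`busynth.igs`** — the Image Generation Stage: encoder-decoder generator
  G2 with residual blocks (mask → image), patch discriminator D2 over
  (mask, image) pairs, and the feature-matching loss
  `L_FM = Σ_i (1/N_i)·‖D2⁽ⁱ⁾(x,y) − D2⁽ⁱ⁾(G2(y),y)‖₁` combined as
  `L_G2 + λ·L_FM`, λ = 10.
- **`busynth.diffaug`** — differentiable augmentation applied to every
  discriminator input (real and generated), with gradient flow back to the
  generators; brightness + translation by default.
- **`busynth.metrics`** — FID, unbiased KID, multi-scale SSIM and an
  internal-diversity protocol over pluggable, download-free feature
  extractors.
- **`busynth.evalkit`** — the downstream harness: stratified 60/20/20
  split, oversampling, online augmentation (p = 0.3), a small CNN
  classifier and U-Net-style segmenter, precision/recall/accuracy/F1/Dice.
- **`busynth.phantom`** — a procedural ultrasound-phantom generator
  (class-conditional star-convex lesion masks, hypoechoic interiors,
  multiplicative speckle) that makes the whole pipeline trainable and
  testable without any external dataset.
- **`busynth.nn`** — the compact NumPy autodiff/NN core the models run on
  (conv/transposed-conv as single-GEMM im2col, spectral normalization by
  power iteration, Adam).

The networks support the published full-scale layout (256×256, G1 seed grid
8×8×512 with five up-sampling doublings, D2 patch map 16×16, 5 residual
blocks) via `MgsConfig.paper_scale()` / `IgsConfig.paper_scale()`; the
shipped defaults are desk-scale (64×64, thin widths) so everything runs in
minutes on one CPU.

## Worked example

```bash
# 1. a BUSI-style phantom dataset (class folders, <stem>.png + <stem>_mask.png)
busynth make-phantoms --n-benign 40 --n-malignant 8 --size 64 --seed 7 --out data/

# 2. per-class two-stage training (desk scale)
busynth train-mgs --data data/ --class benign --max-steps 450 --epochs 100000 --seed 7 --out run/
busynth train-igs --data data/ --class benign --max-steps 300 --epochs 100000 --seed 7 --out run/

# 3. noise -> mask -> image sampling (annotated synthetic pairs)
busynth sample --n 12 --mgs-ckpt run/mgs_benign.npz --igs-ckpt run/igs_benign.npz \
               --class benign --seed 7 --out synth/

# 4. image-quality metrics between the real and synthetic folders
busynth eval-metrics --real data/ --generated synth/ --seed 7 --out metrics.json
```

With the commands above the metrics step prints

```json
{
 "extractor": "randconv",
 "n_real": 48,
 "n_generated": 12,
 "fid": 0.07433324009598982,
 "kid_x100": 0.14200111826827566,
 "ms_ssim_internal_diversity": 0.2268897898736685
}
```

`fid` and `kid_x100` are distances between the feature distributions of the
two folders under the bundled fixed-seed convolutional embedder (lower =
closer; values are comparable only within one extractor, not to published
Inception-based numbers).  `ms_ssim_internal_diversity` is the mean
pairwise MS-SSIM inside the generated set — lower means more diverse
samples; 1.0 would mean the generator collapsed onto one image.  A fifth
subcommand, `busynth eval-downstream`, trains the task models under
baseline / traditional-augmentation / TA+synthetic conditions and reports
Dice or precision/recall/accuracy/F1 per condition.

Checkpoints are NumPy `.npz` containers holding every weight and buffer
under `g::`/`d::` prefixes plus a JSON `meta` blob with the stage name and
config; `busynth.training.load_mgs_checkpoint` / `load_igs_checkpoint`
rebuild the models bit-exactly.

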