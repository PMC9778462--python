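# Methods

## Problem and model

`bpfuse` fuses two co-registered 2-D medical images — a structural
modality (MRI or CT, sharp anatomy) and a functional modality (PET or
SPECT, smooth pseudo-color activity on a mostly black background) — into
one image that keeps the anatomy's texture and the functional image's
color coding. Fusion acts only on luminance: a color companion is
decomposed with full-range BT.601 YCbCr, its Y plane is fused with the
structural image, and the untouched Cb/Cr planes are recombined
afterwards, so chroma passes through exactly (up to gamut clipping). A
grayscale CT companion skips the color step entirely.

The fusion map is a two-branch convolutional generator trained
adversarially without labels. Each branch applies two 3×3 conv-ELU
layers, a back-project dense block (BPDB), and a convolutional block
attention module (CBAM); the branches are concatenated, passed through a
composite BPDB+CBAM stage at doubled width, and reduced to one channel by
a conv-ELU head with a final logistic squashing into [0, 1]. All
convolutions are stride 1 with edge-mirrored "same" padding, so spatial
size is preserved end to end. The two branches have independent weights.

The BPDB is the black-background counter-measure. With `enc`, `diff`,
`dec` denoting 3×3 conv-ELU operators:

* enhance: `F_enc = enc(x)`, `d = diff(F_enc) − F_enc`,
  `F_add = dec(F_enc + d)`
* residual: `F_res = dec(|diff(F_add) − F_add|)`
* reconstruct: `out = dec(enc(F_res) + F_add)`

Flat regions, where a further convolution changes nothing, produce small
differences and therefore contribute little; textured regions are
re-projected and amplified. The prose description of this block admits
more than one wiring; the one above is the reading consistent with
"added to the encoding" in the enhance stage and "absolute value then
subtracted" in the residual stage, and it is isolated in one class so
alternative wirings can be swapped in tests.

CBAM gates channels (max- and average-pooled descriptors through a
shared bottleneck MLP, reduction 8) and then space (channelwise max/mean
maps through a 1×1 convolution). The gate nonlinearity is ELU by
default — as the architecture specifies, although unconventional — with
sigmoid as the standard alternative. Because an ELU gate is unbounded,
the last layer of each gate is initialized to zero with its bias chosen
so the gate opens at exactly 1 (pass-through); without this, stacked
multiplicative ELU gates saturate the output sigmoid at initialization
and kill the pixel-loss gradient.

## Adversarial mechanism in the gradient domain

The discriminator never sees images. Its "false" datum is
`Grad1 = |∇ G(M, Y)|`, the absolute Laplacian of the fused image; its
"true" datum is the joint gradient map
`Grad2 = max(|∇M|, |∇Y|)` — the pixelwise stronger of the two source
textures. ∇ is the 4-neighbour discrete Laplacian `[[0,1,0],[1,−4,1],[0,1,0]]`
with edge-mirrored boundaries (an 8-neighbour variant is available).
Mirrored boundaries matter here: zero padding would turn the border of a
black-background functional image into the strongest edge in the map and
corrupt the adversarial signal. Maps are fed to the discriminator
unnormalized; Laplacian responses of [0, 1] images are already O(1).

The discriminator itself is a stack of stride-2 3×3 conv-ELU layers
(1→16→32→64→64 at full scale), global average pooling and one logistic
unit. An optional spectral-norm mode divides each conv weight by its
power-iteration top singular value (treated as a constant in the
backward pass).

Losses (least-squares GAN form, labels a = 0 false, b = 1 true,
generator target c = 1):

* `L_Gan  = mean((D(Grad1) − 1)²)` — squared rather than log form so the
  generator keeps gradient early in training;
* `L_pixel = mean(Map1 (F − M)² + Map2 (F − Y)²)`;
* `L_grad  = mean(Map1 (∇F − ∇M)² + Map2 (∇F − ∇Y)²)`;
* generator total `L = L_Gan + λ1 L_pixel + λ2 L_grad`;
* `L_D = mean((D(Grad1) − 0)² + (D(Grad2) − 1)²)`.

`Map1`/`Map2` are complementary screening weights deciding which source
each pixel should resemble. The judgment rule is windowed-variance
saliency: in a 7×7 neighbourhood (edge-mirrored), the input with the
strictly larger local variance gets weight 1, the other 0, exact ties
0.5; a constant-0.5 mode provides a saliency-free fallback. The maps
depend only on the inputs, so they are computed once per pair and
cached. λ1 = λ2 = 1 by default; since the design intent is "equal
importance" of the three terms, a calibration utility can rescale them
on the first batch so all three match `L_Gan` in magnitude
(`calibrate_loss_weights: true`).

## Training protocol

Per optimization cycle: draw a mini-batch, update the discriminator
`p` times, then update the generator once; the counter identity
`disc_updates == p × gen_updates` is asserted at checkpoint time. The
published protocol is batch 32, p = 2, 300 epochs, Adam; learning rate
and betas are not pinned anywhere, so the package defaults to 1e-4 and
(0.9, 0.999), standard small-GAN settings. "Steps per iteration" K
defaults to ⌈n/batch⌉, i.e. one pass over the training set per epoch.
The 7:2:1 train/val/test split uses largest-remainder rounding and a
seeded shuffle.

One seed drives weight initialization (Kaiming fan-in), batch order and
phantom generation; runs are bit-reproducible, which is tested. Training
arithmetic runs in float32 by default (float64 available via
`dtype`) — determinism holds in either precision. A non-finite loss
aborts with `TrainingDivergedError`.

The desk profile used by the tests and the acceptance script is 64×64
phantoms, 8 base channels, batch 4, 200 generator updates — small enough
for a few minutes on one CPU core while still showing the adversarial
dynamics; `configs/paper_scale.yaml` keeps the full-scale settings.

## Metrics

* **AG** — implemented exactly as the source formula prints it, with the
  1/4 factor inside the square root over forward differences on the
  (H−1)×(W−1) grid; the common 1/2 convention (√2 larger) is a flag.
* **EI** — mean 3×3 Sobel magnitude, mirrored boundaries.
* **Q_abf** — per 8×8 window (stride 8, partial edge windows included),
  the Wang–Bovik universal quality index Q0 of (A,F) and (B,F) mixed by
  the variance-saliency weight λ = s_A/(s_A+s_B) (0.5 on ties), averaged
  over windows. Degenerate windows fall back to the luminance or
  structure factor of Q0 alone; two identical flat windows score 1. Note
  the label "Q_abf" usually denotes the Xydeas–Petrović edge-transfer
  metric in the fusion literature, but the formula implemented here is
  the windowed-quality (Piella-style) form, which is what the definition
  this package follows actually states.
* **Q_cv** — difference images A−F and B−F are band-filtered with a
  Gaussian (σ = 1.5) standing in for the human contrast-sensitivity
  band-pass; per 16×16 window their MSEs are weighted by mean Sobel
  saliency of the corresponding source and the weighted mean is
  returned. Lower is better. The printed definition leaves both the
  similarity function and the weights to its citations, so every choice
  (σ, window, saliency exponent) is explicit and configurable.

All four implementations are verified against independent per-pixel /
per-window loop oracles at 1e-6 relative tolerance. No numeric parity
with any published benchmark table is claimed: those numbers depend on a
proprietary-ish atlas dataset, full-scale GPU training and third-party
metric codes.

## Phantom generator

The synthetic data emulate exactly the statistics the method assumes:
structural phantoms are overlapping ellipses/rings with sharp borders,
oriented sinusoidal texture (0.12 cycles/pixel) and light Gaussian noise
(σ = 0.01); functional phantoms are Gaussian activity blobs (σ = 12 px
at 256×256, scaled for smaller phantoms) rendered through a
black→blue→green→yellow→red ramp with at least 70% exactly-black
background, enforced by zeroing sub-quantile intensities. Pairs are
co-registered by construction — blob centres are sampled inside the
structural shapes from the same seeded geometry — not by warping.
Generated data satisfy, and the tests rely on, two ground-truth
orderings: the structural member dominates AG/EI, and it wins the joint
gradient map on ≥90% of pixels.

What the phantoms do *not* emulate: anatomy, partial-volume effects,
modality-specific noise spectra, intensity non-uniformity, or
registration error. Passing tests therefore demonstrate that the
mechanism behaves as designed under its stated assumptions, not clinical
performance.

## Numerical and design notes

* The networks run on a package-internal reverse-mode autodiff core over
  numpy (float64 default, float32 for training); conv layers use
  im2col + BLAS. Gradients of the full generator+discriminator graph are
  verified against central finite differences.
* YCbCr is full-range BT.601; out-of-gamut inverse values are clipped,
  never rescaled, so unaffected pixels are preserved bit-for-bit.
* Elementwise `max` ties split gradients equally; `|·|` has gradient 0
  at 0.
* Whether the two generator branches share weights is not specified by
  the architecture description; they are independent here (the parallel
  branch layout suggests so), and the branch-swap test documents the
  asymmetry.
* Known limitations: single 2-D slices only (no volumes, no DICOM/NIfTI),
  no pretrained weights, CPU-scale defaults, and the BPDB wiring and
  CBAM gate activation follow a printed description that leaves room for
  interpretation (both are isolated behind small classes and flags).
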