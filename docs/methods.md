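# Methods

## Problem and model

Given two co-registered source MR volumes, the package learns a mapping to a
third (target) contrast. The model is a three-stage system:

**Feature extraction.** One symmetric U-Net auto-encoder per source modality
(identical architecture, independent weights, so both modalities' features
live in a shared latent geometry). Two pooling stages, skip connections at
both, batch normalisation after every convolution, LeakyReLU (slope 0.2) in
the encoder and ReLU in the decoder. The encoder taps export "unique"
feature maps at three depths: the two skip levels and the bottleneck.
Channel widths double per level from `base_channels` (32 at full scale; the
tiny profile uses 8). Kernel size is 3×3 everywhere; one conv block per
level keeps the CPU cost proportionate. Reconstruction uses a per-pixel mean
l1 loss (rather than an unreduced sum) so the loss scale — and with it a
given learning rate — is independent of patch size; the sum over modalities
is kept.

**Self-supervised pretraining.** Two pretext tasks, trained jointly by
default (one optimizer, summed losses):

* *Inpainting*: four square masks (non-overlapping, uniform-random placement;
  the mask fill is 0, the midpoint of the [-1,1] intensity range) cover 25 %
  of the patch; the auto-encoder restores the original under the same l1
  loss as plain reconstruction. Mask geometry scales with the patch (32×32
  masks on 128×128 patches, 16×16 on the 64×64 tiny profile) so the masked
  fraction stays 1/4.
* *Slice-index regression*: the input is three adjacent axial slices,
  compressed to one channel by an extra 3→1 front convolution; a branch on
  the first decoder stage (four conv–BN–ReLU layers, global average pooling,
  one fully connected layer) regresses the centre slice's index, normalised
  to [0,1] by depth−1 for scale stability. Squared-error weight 1 by
  default; weight 0 reduces the objective exactly to plain reconstruction.

When the encoder is transferred to the synthesis stage the front compression
layer is dropped: synthesis consumes single slices. The edge slices of a
volume are handled by replicating the first/last slice in their triplets.

**Fusion.** Three chained multimodal attention feature fusion blocks
(MAFFB_1..3), one per tap depth. Each block computes the element-wise sum,
product and maximum of the two unique maps, stacks them (3C channels),
gates channels with `σ(MLP(avgpool) + MLP(maxpool))` — a shared 1×1-conv
bottleneck MLP with reduction ratio r = 8 (floored at one hidden channel for
narrow configurations) — then conv–BN–ReLU; the previous block's output is
average-pooled (stride 2) to the next depth, concatenated, and a second
conv–BN–ReLU emits the block's common features. Common widths equal the
corresponding unique widths. All three fusion operators are symmetric, so
the whole fusion network — and the generator below — is exactly invariant
to swapping the two source streams.

**Generation.** The generator starts from the deepest common features,
compressed by two conv–BN–ReLU layers to the smallest common width, then
runs three more MAFFBs (MAFFB_4..6) in decoder direction — deepest to full
resolution — each consuming the two modalities' unique features at its depth
plus the upsampled previous output concatenated with the fusion network's
common features at that depth, ending in a 3×3 convolution and tanh.
MAFFB_k and MAFFB_{7−k} therefore share the same unique inputs, which is
what the interpretability comparison below exploits.

**Discriminators and losses.** Two independent five-stage conv–BN networks
(channels 32, 64, 128, 256, 1; strides 2, 2, 2, 2, 1; LeakyReLU(0.2) for
the pixel-level one, ReLU for the feature-level one; a 128×128 input maps to
an 8×8 response). The pixel-level discriminator sees raw patches; the
feature-level one sees only Canny edge maps, tying the synthesis to
anatomical contours. The total generator-side objective is

    L = L_pixel-adv + L_feature-adv + λ1 ‖y − G(x1,x2)‖₁ + λ2 L_Rec,

λ1 = 100, λ2 = 10 by default (strong direct supervision in the pix2pix
tradition; both exposed in config). The backbones keep reconstructing their
own inputs during adversarial training (the λ2 term), which stabilises the
shared encoders. Adversarial terms use the standard minimax convention with
a non-saturating generator (real → log D, fake → log(1−D), generator
maximises log D on fakes), computed as means over the response map with a
sigmoid folded into a numerically stable softplus form. Discriminator logits
are unbounded; probabilities exist only inside the loss.

Canny involves non-maximum suppression and hysteresis, which have no usable
gradient, so the generator's feature-level term is computed on a smooth
surrogate — tanh-squashed Sobel gradient magnitude — while the feature-level
discriminator itself trains on hard Canny maps of real and synthesized
patches. Training alternates: both discriminators step first (on detached
synthesis), then the generator side (generator + both backbones + fusion).
Adam with β = (0.5, 0.999) throughout.

## Preprocessing geometry

Axis order is (slice, row, col), 0-based, half-open windows. Volumes are
centrally cropped in-plane (240×240 → 160×180 for the brain-data geometry;
an odd margin rounds the leading side down), each slice is cut into the four
corner-anchored overlapping patches (row offsets {0, H−p}, col offsets
{0, W−p}; duplicates de-duplicated when the patch equals the plane), and
stitched back by averaging overlaps — an exact round trip. Intensities are
scaled per volume by min–max to [−1, 1]; a constant (background-only) volume
maps to all zeros rather than erroring, and the scale parameters are kept so
the map is invertible. Per-slice and fixed-range (dataset-level)
modes are available alternatives; per-volume is the default because it is
invertible case by case. At inference the synthesized [-1,1] output is mapped back with
the ground-truth scale when evaluating, or with the mean of the two source
scales when no truth exists (the target's true range is unknowable at pure
inference time; this choice is recorded in the output metadata).

## Metrics

MSE is the plain pixel mean. PSNR's default ("peak") mode takes the peak as
the maximum intensity over both images, making it invariant to joint
positive rescaling; a fixed-data-range "standard" mode is provided for
comparability. Identical images report a +inf sentinel, never an exception.
SSIM's default mode is the single global-statistics formula with
c1 = (0.01 L)², c2 = (0.03 L)², L the joint data range; an 11×11
Gaussian-windowed mean-SSIM (scikit-image) is the alternate. Volume pairs
are scored slice by slice on stitched, unscaled data and averaged; all-zero
identical slices would have infinite PSNR and are excluded from the PSNR
average.

## Synthetic phantoms

The generator emulates what the method needs from multi-contrast brain MR,
nothing more: shared anatomy as a composite of 3-D Gaussian blobs (identical
across modalities — perfect co-registration by construction); per-modality
monotone intensity transfers (gain/gamma) standing in for tissue-contrast
differences; an exact-zero in-plane background margin like the empty border
of a skull-stripped slice; inter-slice continuity from the 3-D blobs plus a
smooth monotone intensity gain along the slice axis (0.7 → 1.3, a
coil-sensitivity-like modulation) that keeps the axial position recoverable
from content. The target is a known voxel-wise function of the two sources:
`blend`, 0.5(s1+s2) + 0.4·s1·s2, a smooth nonlinearity, by default, or
`mean` for exact linear oracles. The default geometry is 16×160×180 (so the
crop/patch pipeline is exercised at its native in-plane size); the tiny
profile is 12×64×64 with 5 blobs.

What the phantoms do *not* model: anatomy, lesions, noise, bias fields,
partial-volume effects, registration error. Passing the phantom suite shows
the machinery is correct and the optimisation works at small scale; it does
not certify synthesis quality on clinical data.

## Training profile and problem sizes

The default configuration is the tiny profile: ten phantom cases (8 train /
2 test, split at case level so adjacent slices never straddle the split),
64×64 patches, base width 8, discriminator widths (8, 16, 32, 64, 1), batch
4, 60 joint pretraining steps per modality, 400 adversarial steps, Adam at
lr 1e-3. The learning rate is larger than the 2e-4 convention because the
scaled-down networks and data tolerate it and converge in far fewer steps;
at full scale 2e-4 remains the default in `GANOptimizers`. The full-scale
architecture (base 32, tabulated discriminator widths) is config, not code.

Evaluation reports slice-averaged MSE/PSNR/SSIM on the held-out cases, next
to the copy-source-1 baseline — a deliberately strong reference on phantoms,
since each source is a monotone transform of the same anatomy as the target.

## Interpretability

For each MAFFB the per-sample feature maps are reduced to vectors by global
average pooling per channel (full flattening would make dimensions depend on
spatial size and would dominate the PCA with spatial layout), labelled
unique-1 / unique-2 / common, and projected by PCA (2-D or 3-D); principal
axes have their sign fixed by making the largest-magnitude loading positive,
so plots are reproducible. The centrality diagnostic reports
‖centroid(common) − midpoint(centroids(unique))‖ / ‖centroid separation‖:
0 means the common cloud sits exactly between the modalities, 0.5 on top of
one of them. It is descriptive of a particular trained model and is
deliberately not a test gate.

## Numerical choices and degenerate inputs

* All computation is float64 on a built-in NumPy reverse-mode autodiff
  engine; forward passes in eval mode build no graph, so inference is pure
  NumPy and bit-reproducible.
* Elementwise-max gradients split equally on exact ties; max-pool gradients
  split equally among tied window maxima.
* Batch norm uses batch statistics in training and running statistics
  (momentum 0.1) in evaluation; evaluation is always run in eval mode.
* Attention MLP hidden width is max(1, 3C // r).
* Zero-blob phantoms, constant volumes, empty masks, and patch size equal to
  plane size are all defined, not errors (see the module docstrings).
* NaN in any training loss aborts the step with a diagnostic rather than
  propagating.

## Known limitations

* CPU NumPy training limits practical problem sizes; the full 240×240×155
  multi-case setting is configurable but not practical here.
* 2-D slice method: 3-D context enters only through the slice-index pretext
  task.
* Exactly two source modalities; single-modal synthesis is done by feeding
  the same image to both streams.
* The edge surrogate (Sobel magnitude) only approximates the hard Canny map
  the feature discriminator sees; generator gradients through that path are
  correspondingly approximate.
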