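# Methods

## Problem

Limited-view CT acquires projections over an incomplete set of view angles —
either the trailing block of a 180-view parallel-beam scan is missing
(`cut_post`) or a centered block is (`cut_mid`). Filtered back projection
(FBP) of such data produces severe streak and shading artifacts. `limitedct`
restores these reconstructions with a three-stage, coarse-to-fine pipeline
that works in both the Radon (sinogram) domain and the image domain, and
exploits the strong spatial correlation between consecutive slices of a
scanned object.

## Pipeline

Given limited-view Radon data `R_lv` for each slice of a volume:

1. **Merge (deterministic completion).** Reconstruct `R_lv` by FBP, forward
   project the reconstruction on the full angle grid, and splice the
   reprojected rows into the missing block. Measured rows are kept verbatim.
   The merged sinogram `R_merge` is provably closer to the true full
   sinogram than zero-filling (asserted over randomized phantoms) and gives
   the stage-one network a far better starting point.
2. **Stage one — sinogram restoration.** A fully convolutional
   encoder–decoder with a discriminator (an adversarial autoencoder) maps
   `R_merge` to an estimate of the full sinogram. At inference the measured
   rows are re-imposed on the network output (data consistency), so the
   network only ever replaces the synthesized block; this keeps the exactly
   known views exact and was adopted as a package design choice. The result
   is reconstructed by FBP.
3. **Stage two — spatially-correlated image restoration.** For slice `s_i`,
   the 5-stack `S = {s_{i-2} … s_{i+2}}` is split into the three overlapping
   triplets `S1={s_{i-2},s_{i-1},s_i}`, `S2={s_{i-1},s_i,s_{i+1}}`,
   `S3={s_i,s_{i+1},s_{i+2}}`; a shared AE block `G1` maps each triplet
   (stacked as 3 channels) to one image, and a second block `G2` fuses the
   three outputs: `s_i'' = G2(concat(G1(S1), G1(S2), G1(S3)))`. The cascade
   implicitly captures inter-slice motion without explicit motion
   estimation. At volume boundaries the edge slice is replicated to fill
   the stack. `G1` is trained first on triplet→center-truth pairs, then
   frozen while `G2` is trained on its concatenated outputs.
4. **Stage three — patch-wise texture refinement.** The image is split into
   its four corner quadrants, each restored by a shared AE block, and
   reassembled. Corner cropping without flips is the default (flipping all
   patches to a common orientation is available as `corner_flip`, plus
   `random` and `none` for ablations); the fixed corner pattern is easier
   to learn and the non-flipped variant acts as mild augmentation.

Any stage can be disabled; disabled stages pass data through, which yields
the classical baselines (plain FBP; FBP of merged data) and per-stage
ablations from the same code path.

## Architectures

The shared AE block is U-Net-like: encoder blocks of two 3×3 convolutions
(each followed by batch normalization and ReLU), 2×2 max pooling between
blocks — every pooling halves H×W and the next block doubles the channel
count — and a mirrored decoder of 2×2-stride-2 transposed convolutions with
concatenative skip connections at equal resolution, closed by a
three-convolution head (base→12→1 channels, final convolution linear). The
default full-width schedule is 32-64-128-256-512 over four poolings; at a
192×512 sinogram input the bottleneck is 512 channels at 12×32 and the
output is 1×192×512. Inputs must be divisible by `2**depth`; 180-view
sinograms are zero-padded along the view axis to the next multiple and
cropped back after (192 for the full-width depth-4 network).

The discriminator reuses the encoder, its deepest block widened to three
convolutions with output channels 512, 64 and 1; an element-wise sigmoid on
the final map is averaged into a single realness score per image. Each
stage has its own independently trained discriminator.

All network code runs on a compact reverse-mode autodiff core written on
numpy (`limitedct/_autodiff.py`): im2col convolution, transposed
convolution, max pooling, batch normalization, and Adam, in float64.
Computation is deterministic: identical seeds and inputs reproduce
bit-identical parameters, loss histories and metric tables.

## Losses and optimization

The autoencoder objective is `l_AE = α1·l_MSE + α2·l_Adv + α3·l_Reg` with
defaults `(α1, α2, α3) = (1, 1e-3, 2e-8)`:

* `l_MSE = (1/WH) Σ (I_GT − G(I_in))²`,
* `l_Adv = 1 − D(G(I_in))`,
* `l_Reg = (1/WH) Σ ‖∇G(I_in)‖` — total variation with forward
  differences, replicate boundary (last difference zero) and isotropic
  magnitude `sqrt(dx² + dy² + ε)`, `ε = 1e-8`, for differentiability.

The discriminator minimizes `l_Dis = (1 − D(I_GT)) + D(G(I_in))`, bounded
in [0, 2]. Both are optimized with Adam (β = (0.9, 0.999), ε = 1e-8),
learning rate 1e-4 by default, alternating one discriminator step with one
autoencoder step per batch; an optional step decay (`lr_decay_steps`,
`lr_decay_factor`) is off by default. Gradients of `l_MSE` and `l_Reg`
agree with central finite differences to better than 1e-4 relative (tested).

## Geometry

The forward projector is pixel-driven: each pixel center is projected onto
the detector axis (`t = x cosθ + y sinθ`, unit bin width, one bin per pixel
width by default) and its value is splatted onto the two nearest bins with
linear weights. Per-view bin sums therefore equal the image mass exactly
(for objects inside the field of view), and the unfiltered back projector
built from the same weights is the exact transpose of the forward operator,
so ⟨Rx, y⟩ = ⟨x, By⟩ holds to machine precision. FBP applies the discrete
band-limited ramp kernel in the frequency domain (Shepp-Logan and Hann
windows available) and scales the back projection by π/(2·n_views). View
angles are uniform on [0°, 180°), view *i* at `i·180/n_views`; `cut_post`
removes the trailing block, `cut_mid` a centered block with ties toward the
lower index. Parallel-beam data determine the image only inside the
inscribed circle; metrics may optionally be restricted to that mask, but
default to whole-image values.

Known discretization behavior: pixel-driven splatting aliases most strongly
near 45°, where a uniform disk's projection deviates up to ~7% from the
analytic chord profile in a single view; the global sinogram error stays
below 2% relative L2 and the mean view error near 1%.

## SART-TV baseline

SART runs per-view updates in natural angle order (relaxation 1.0 default)
with the standard row/column-sum normalizations, a nonnegativity projection
after every sweep, then `tv_inner_steps` gradient-descent steps on smoothed
isotropic TV with backtracking halving so a TV step never increases TV
(the TV-minimization-with-POCS pattern). Defaults: 50 iterations,
`tv_weight` 0.1, 10 inner steps. `tv_weight = 0` skips the TV stage
entirely and is bitwise plain SART. Data fidelity ‖Rx − p‖² decreases
monotonically over early sweeps on consistent data (asserted per sweep).

## Synthetic data

`phantoms.generate_volume` draws a body ellipse plus 3–6 internal ellipses
with random centers, axes, orientations and intensities in [0.15, 0.5],
rasterized with 4× supersampling and clipped to [0, 1]. Along the slice
axis all ellipse parameters perform a bounded Gaussian random walk with
per-slice scale `z_drift` (default 0.01; the body stays centered, intensity
drift halved). Adjacent-slice Pearson correlation exceeds 0.9 at the
default drift — the assumption stage two exploits — and the mean adjacent
difference grows monotonically with `z_drift`. `generate_dataset` forward
projects every slice on the full 180-view grid, applies the view mask,
builds the merged sinogram, and keeps both FBP images; volumes are split
train:val:test 1:1:3 by default. Optional Gaussian sinogram noise is off by
default (the simulation protocol is noiseless limited views).

What the generator does *not* emulate: anatomical texture, HU calibration,
scanner blur, scatter, or realistic noise statistics. Passing tests
demonstrate the pipeline's mechanics and relative orderings on piecewise-
smooth objects, not clinical-grade restoration quality.

## Desk-scale study conditions

The end-to-end checks train all three stages at a reduced problem size
chosen once for a single-CPU workstation: 64×64 images, 180 views, 64
detector bins, `cut_post` 60, twenty volumes of six slices (16 train /
1 val / 3 test), the sinogram network at `base_channels=8, depth=3` and the
image-domain networks at `base_channels=16, depth=3`, Adam at 1e-3 with
step halving, schedules of 300 / 450 / 1500 steps for stages one / two /
three, batch size 2 (4 for patches).

Two desk-scale adaptations matter. First, stage-one inference re-imposes
the measured rows on the network output (data consistency; see Pipeline
above). Second, the patch refiner trains **without** its discriminator at
this scale: a discriminator trained from scratch on a few hundred
32×32 patches overfits and its gradient injects noise that a small
training set cannot average out, which measurably degrades held-out
refinement, while the plain reconstruction objective refines reliably.
Stages one and two keep their discriminators (the sinogram completion and
spatial stages have more signal per sample); at full scale all three
stages are adversarial and `stage3_adversarial=True` restores that
configuration.

At these conditions the measured orderings mirror the full-scale results
in direction: FBP of merged data < stage one < stage two ≤ stage three on
held-out volumes, and merged completion beats zero-filling in sinogram L2.
Absolute PSNR/SSIM values at this scale are far below what full-scale
training on a large clinical corpus attains and are not comparable to it.

## Numerical choices and edge cases

* Min-max normalization per volume (per-slice for single sinograms),
  recorded for exact inversion; constant inputs map to zeros and are
  flagged degenerate.
* Infinite PSNR (identical images) is reported as a finite sentinel
  (default 99 dB) to keep CSV tables numeric. SSIM uses the 11×11 Gaussian
  window, σ = 1.5, K1 = 0.01, K2 = 0.03, population covariance, and crops
  the half-window border; it matches scikit-image's implementation to 1e-4.
* Weight initialization is Kaiming-uniform from a recorded seed.
* The view-axis zero-padding for the networks is split evenly, extra row at
  the bottom.
* All-zero sinograms reconstruct to all-zero images through both FBP and
  SART (fixed point).

## Known limitations

* The numpy engine is single-threaded and float64; it is built for
  correctness and determinism at desk scale, not speed. Full-width training
  at 512×512 is out of reach without an accelerator framework.
* Pixel-driven projection aliases near diagonal angles (see above);
  detector bin spacing is fixed at one pixel width.
* SART-TV hyperparameters are generic defaults, not tuned per dataset.
* Stage-two training treats triplet targets as the common center slice;
  joint fine-tuning of the two blocks is available only as a flag-off
  sequential procedure (G1 then G2).
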