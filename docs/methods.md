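# Methods

## Problem and model

`spectgan` synthesizes 64x64 axial cerebral-blood-flow SPECT slices
conditioned on an anatomical level — cerebellum (CER), basal ganglia
(BG), cortex (COR) — and a perfusion pattern — normal, unilateral defect,
bilateral defect.  The model is a conditional light-weight GAN in the
few-shot FastGAN family: a compact generator with one skip-layer
excitation module, and a discriminator regularized by a self-supervised
reconstruction task, trained with the hinge adversarial loss:

    L_G    = -E[ D(G(z|y)) ]
    L_real = -E[ min(0, -1 + D(x)) ]
    L_fake = -E[ min(0, -1 - D(x_hat)) ]
    L_D    = L_real + L_fake + L_recon

where z is a 256-dimensional standard-normal latent, y the one-hot
condition, and L_recon the mean absolute error of two "simple decoder"
reconstructions computed from discriminator feature maps of real images
only: a regional decoder reconstructs a random half-size crop of the
input from the matching crop of the second down-sampling block's 8x8
feature map, and a global decoder reconstructs the whole input from the
third block's 4x4 map.  Reconstruction targets live in the normalized
[0, 1] count range.

Condition encoding ('variant A'): 6 bits, the first three one-hot in the
level, the last three one-hot in the pattern.  'Variant B' restricts the
data to cortical slices and encodes the pattern alone (3 bits).  The
generator receives y concatenated with z before its fully connected
embedding; the discriminator receives y as spatially constant image
channels concatenated with the input image (6 or 3 extra channels).

## Networks

All networks are implemented on a small reverse-mode autodiff engine
(`spectgan.nn`) written on NumPy (float32, im2col convolutions, Adam).

Generator: FC embedding of (z, y) to 64 dimensions; an input block lifts
the embedding to a 4x4 map through a learned linear map (equivalent to a
4x4 transposed convolution from 1x1) followed by batch normalization and
GLU; four up-sampling blocks (nearest-neighbour x2 upsampling, 3x3
same-padded convolution, batch norm, GLU) grow the map through 8, 16, 32
to 64 px; a 3x3 output convolution with tanh emits one channel.  Channel
widths halve per scale from `base_channels` (default 256) at 4x4, with
the 64-px stage reusing the 32-px width.  The single skip-layer
excitation gates the 32x32 map channelwise by a sigmoid signal computed
from the 8x8 map through two unpadded convolutions (4x4 stride 2, then
3x3) with a leaky-ReLU between them — a mid-to-late self-gating shortcut.

Discriminator: the (image, condition channels) stack passes an input
block (4x4 stride-2 convolution to `base_channels`, default 32) and
three further stride-2 down-sampling blocks doubling the width each
time, so the second block's output B1 is 8x8 and the third's B2 is 4x4;
an output block (3x3 convolution, then an unpadded 4x4 convolution)
produces the scalar logit.  Leaky-ReLU slope is 0.1 everywhere.  All
critic-path convolutions carry spectral normalization (one power
iteration per weight update, singular vectors cached between updates so
repeated forwards are deterministic).  Each decoder has two
upsample+conv stages: nearest-neighbour upsampling by (4, 2) for the
regional path (4x4 crop -> 32x32) and (4, 4) for the global path
(4x4 -> 64x64); pure x2 stages cannot bridge those scale gaps in two
stages, hence the mixed factors.

Coordinate conventions: array axis 0 is anteroposterior (rows), axis 1
left-right; "left hemisphere" is the left half of the stored array
(columns 0-31).  Whether a display uses the radiological convention is
unknowable from slice data alone, so evaluation functions accept a
`radiological` flag that swaps the halves.

## Training procedure

Real slices are max-normalized, augmented, and linearly mapped from
[0, 1] to the tanh range [-1, 1].  Augmentation per sampled slice:
weighted average with its adjacent craniocaudal neighbor
(z = w z1 + (1-w) z2, w uniform on [0, 1]); anteroposterior translation
by a random integer t in [-2, 2] with zero fill; horizontal flip with
probability 0.5 for normal and bilateral patterns only (flipping a
unilateral slice would swap its defect side).  Each step synthesizes a
batch, computes the discriminator losses on real (including the
reconstruction term) and generated images and the generator loss, and
updates both networks by Adam (beta1 = 0.9, beta2 = 0.999, learning
rate 2e-4).  Defaults: 1000 epochs, batch size 4.  L_real and L_fake are nonnegative by construction and
L_D additivity is asserted at every step.

Updates are strictly sequential: the discriminator steps first on
detached generated images, then the generator's loss is evaluated
through the freshly updated discriminator and the generator steps.  (In
development, taking both gradients against pre-update parameters left
the generator chasing a stale critic and never approached equilibrium at
desk scale; strict alternation reaches a stable l_G near 0.5-1 within a
few thousand steps.)  Conditions for generated batches reuse the labels
of the real batch, so the generated class distribution follows the
(imbalanced) data distribution.

Epoch selection: the original protocol delegated checkpoint choice to a
physician reading the samples.  The package replaces this with an
automatic criterion: for each checkpoint, per-class means of MC (mean
counts) and LR (left/right hemisphere count ratio) of generated samples
are compared to the real per-class means, and the checkpoint minimizing
the summed absolute differences is selected, ties breaking toward the
later epoch.

## Phantom simulator

Clinical tracer scans cannot be shipped, so `spectgan.phantom`
synthesizes slices with the same statistical structure.  Each phantom is
an elliptical head with level-dependent internal anatomy (CER: two
paramedian cerebellar lobes; BG: cortical rim plus two central
high-uptake nuclei; COR: cortical rim with a lower-uptake interior).
Hypoperfusion multiplies the expected counts of the affected hemisphere
half-plane (or the whole slice, bilateral) by (1 - contrast); the
default contrast is drawn per slice from [0.3, 0.55], a moderate-severe
ischemia range.  Structure positions are jittered (sigma ~0.5 px) per
slice, the count scale varies uniformly in [80, 160] so pre-normalization
maxima differ across slices, counts are Poisson-distributed, and the
count map is low-pass filtered (Gaussian, sigma 1.2 px) because clinical
reconstructions are post-filtered — counting noise in real slices is
spatially correlated, not pixelwise independent.  Neighbors (the
adjacent craniocaudal slice) are modelled as a smooth random deformation
(~1.5 px) of the parent with a fresh Poisson draw; the clinical
inter-slice correlation is not known quantitatively, so the deformation
scale is a design choice giving parent-neighbor correlation ~0.9.

The default dataset composition reproduces the reference study's class
table exactly (938 slices: 551 normal / 291 unilateral / 96 bilateral
across the three levels, with no cerebellar bilateral cell);
`DatasetComposition.scaled(n)` rescales it by largest-remainder rounding,
preserving the imbalance.  Defect side is assigned 50/50 at random since
no laterality distribution is reported.  Rest and stress scans are not
modelled separately; all slices are treated as independent.

What the phantoms do not emulate: reconstruction artifacts, scanner
resolution anisotropy, anatomical variation beyond affine jitter,
partial-volume structure, or realistic lesion topography (defects are
hemisphere-wide multiplicative factors).  Passing tests therefore show
the pipeline trains and conditions on this family of images, not that it
reproduces clinical image quality.

## Evaluation protocol

Fidelity statistics per image: MC = mean over all 4096 pixels (no brain
mask); LR = sum of left-hemisphere counts over sum of right-hemisphere
counts.  Images are max-normalized before metrics so real counts and
generated outputs share the [0, 1] scale.  Per pattern, pixelwise mean
and standard-deviation maps (population convention, ddof = 0) summarize
structure and diversity; the scalar "SD" is the mean of the SD map.
Real / variant-A / variant-B groups are compared per metric and pattern
by one-way ANOVA followed by Tukey HSD for the real-vs-A and real-vs-B
pairs, significance at P < 0.05.  The report emits both pooled
(all-level) and per-level statistics are available by filtering the
input sets; the default report pools levels within a pattern.

## Numerical and design choices

* Eq. norm for the reconstruction loss: mean absolute error (scale
  stable at 64x64; the norm type is not prescribed).
* Real slices in [0, 1] are mapped to [-1, 1] to match tanh output;
  generated images map back to [0, 1] for evaluation.
* Parameter init: normal(0, 0.02) everywhere, biases zero.
* All randomness flows from one root seed through named SeedSequence
  substreams (init, augmentation, latent, shuffling, cropping).
* Degenerate inputs are labeled errors: all-zero slices cannot be
  normalized, ANOVA with zero within-group variance and unequal means is
  rejected, empty logit batches are rejected.

## Desk-scale profile

Full-size training (base widths 256/32, 1000 epochs on 938 slices) is a
GPU-days workload.  The test suite and the acceptance script use a
desk-scale profile chosen once: a 90-slice phantom set with the scaled
reference composition, generator base 64, discriminator base 8, and runs
of about two thousand steps per seed.  The profile keeps every
mechanism (losses, augmentation, conditioning, checkpointing, epoch
selection) identical to the full model; only widths and step counts
shrink.  Adversarial convergence and conditional adherence measured
under this profile are smoke-level evidence, far from the equilibrium a
full run reaches.

## Known limitations

* The autodiff engine is CPU-only and single-threaded beyond BLAS.
* Batch normalization uses batch statistics at sampling time, so a
  sampled batch is not independent across images; fidelity statistics
  treat images as exchangeable draws, which is adequate at n >= 50.
* The hinge discriminator dominates for the first few hundred steps of
  a run; loss trajectories become informative once the generator
  reaches the data manifold's gross statistics.
* No 3-D generation, no continuous severity conditioning, no
  latent-space editing.
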