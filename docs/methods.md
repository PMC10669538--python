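# Methods

## The segmentation model

`latentgrow` segments a 2-D medical image from a single user click, with no
segmentation-specific training.  The model rests on one empirical property of
convolutional autoencoders: when two images are averaged in the latent space
of a bottlenecked encoder/decoder pair and the average is decoded, the result
is not the pixel average — the decoder produces a distorted blend whose
artifacts ("reconstruction noise") spread spatially, and they spread
preferentially within regions whose appearance supports them.  A tiny seed
mask blended into a bright, homogeneous organ therefore "diffuses" outward
through the organ, and much less readily across its boundary.

One growth step from the current mask g (starting at g0, the 5-pixel unit
disk around the click) is:

1. **Density remap** (intensity adjustment).  Dilate g 7× with a 3×3 element,
   crop the image to the dilation's bounding box, fit a Gaussian KDE to the
   nonzero pixel values of the crop, and replace every pixel value v of the
   full image by KDE(v), rescaled to peak at 1.  The clicked organ dominates
   the crop, so its intensity mode maps to ≈1 and dissimilar tissue to ≈0:
   the output x is a soft indicator of "looks like the clicked organ".
   Zero-valued pixels (air clipped to the window floor) are excluded from the
   fit but still remapped.
2. **Feature mixing.**  Encode x and the mask rendered as a {0,1} image;
   average the two latents element-wise and decode: a(x, g).  Do the same
   with an all-black reference image o: a(x, o).
3. **Thresholding.**  d = max(a(x, g) − a(x, o), 0) isolates the brightening
   attributable to the mask's presence.  Otsu's threshold (256-bin,
   between-class variance, lowest maximizing bin on ties) binarises d, and
   only 8-connected components intersecting the previous mask are kept.

The iteration stops when two consecutive masks are bitwise identical
(converged), when any earlier mask recurs (the map is deterministic, so a
recurrence proves a limit cycle; the run stops, flagged not-converged), or at
`max_iterations` (default 50).

**Refinement.**  A positive click re-runs the growth from the new click and
unions the result with the current mask (never shrinks it).  A negative click
removes mask regions in a purely geometric way: mask pixels are partitioned
by nearest click; each partition defines an isotropic Gaussian centred on its
click with sigma equal to the standard deviation of pixel distances to that
click (floored at 1 px); every pixel where the negative density strictly
exceeds the best positive density is removed (ties keep the pixel; with
several positive clicks the positive density is their pointwise maximum).
The nearest-click partition is our resolution of a genuinely open design
point: some rule must pick the pixels whose spread defines each sigma before
the densities exist.

**Evaluation protocol.**  A simulated annotator computes false-negative and
false-positive components of the current prediction, takes the largest, and
clicks its interior-most pixel (Euclidean distance-transform argmax; lowest
row, then column, on ties; optional seeded jitter is off by default so
sessions are replayable bit-for-bit).  Sessions record Dice after every
click; the best-Dice-per-click curve is the running maximum.

## The autoencoder

The encoder is the convolutional stem of VGG19 up to the first convolution of
block 3 (conv0 1×1, conv1_1, conv1_2, pool, conv2_1, conv2_2, pool, conv3_1),
ReLU after every convolution; the decoder mirrors it with nearest-neighbour
2× upsampling in place of pooling and ends in a mirrored 3×3 projection to 3
channels plus a 1×1 projection with no ReLU, clamped to [0, 1].  All 3×3
convolutions use reflection padding 1 so spatial size is preserved; a
published variant of this table lists padding 0, which would shrink the maps
and break the mirrored reconstruction, so we follow the standard
size-preserving convention.  With two pooling steps the latent of an H×W
image is C × ⌈H/4⌉ × ⌈W/4⌉; grayscale input is replicated to three channels
and the decoded output channel-averaged back.  At full width
(64/128/256 channels) the architecture has 1,110,427 parameters by this
layer list (the fixture variant has 17,867); published parameter counts for
this family differ and cannot be reconciled with the printed layer table, so
we document our own count.

The forward pass, backpropagation, and Adam are implemented in NumPy
(`_nn.py`): the model is small enough that im2col convolutions on one CPU
cover both fixture training (minutes) and interactive inference
(~0.1 s per growth step at 128×128).

## The fixture autoencoder and what it emulates

The reference system decodes through features of a frozen, classification-
trained encoder: its reconstructions are systematically imperfect, and that
imperfection is the signal the method grows masks with.  A small autoencoder
trained end-to-end to minimise pixel MSE is the wrong stand-in — it learns a
nearly invertible code, reconstructs boundaries crisply, and the seed's
influence dies within two or three pixels, so the growth stalls.

The fixture therefore keeps the identical topology at reduced channel widths
(8/16/32, `width_divisor=8`) and is trained denoising-style: Gaussian noise
scaled by 0.5× the latent's standard deviation is injected at the bottleneck
during training, so the decoder learns to reconstruct plausible content from
degraded codes — precisely the property the growth step exploits when it
hands the decoder a half-magnitude mixture of two codes.  The noise scale
trades off two failure modes we characterised explicitly: with little or no
noise the decoder is near-invertible, the seed's halo dies within ~2 px and
growth stalls far below organ size; with strong noise the halo loses its
boundary gating and masks leak into the background.  0.5 with 12 epochs sits
between them.  The corpus is CT-like phantoms, gradients and filtered-noise
textures; training runs a few minutes on one CPU at 128×128 and is
bit-reproducible for a fixed seed.  Externally trained full-width weights
remain a drop-in via `load_weights` and are never a test dependency.

Even at this operating point the fixture only partially reproduces the
reference behaviour: on 128×128 single-organ phantoms the initial click
typically recovers Dice ≈ 0.3–0.5 and five simulated clicks reach ≈ 0.7 on
average, with only occasional sessions above 0.9.  The corresponding
acceptance-level recovery test encodes the stronger target (Dice ≥ 0.9 on
most phantoms) and is expected to fail with the bundled fixture; the
mechanism tests around it (growth from the seed, boundary containment,
monotone refinement, determinism, replay) pass.  See the test suite for the
exact properties.

## The phantom generator

`generate_phantom` renders what the method's working regime looks like on a
windowed abdominal CT slice:

- **Target organs**: Fourier-perturbed ellipses (≤5 harmonics, so boundaries
  are smooth but not circular) with per-pixel Normal(mean, 0.03) intensity;
  defaults three organs at means 0.70/0.45/0.30 on a 256×256 grid.
- **Air base**: mean 0.02 with smooth spatial noise, clipped at 0 — most of
  the base is exactly 0, as sub-window CT values are after clipping, and
  exact zeros are excluded from the KDE fit.
- **Distractor tissue**: a few blobs at varied intensities (means in
  [0.2, 0.9], kept ≥0.15 away from every target mean, spatially separated
  from targets) with broader internal spread (0.06), standing in for the
  heterogeneous non-target anatomy that makes the clicked organ the local
  density mode.  An organ directly abutting same-intensity tissue is the
  method's documented failure mode and is deliberately not the baseline
  scenario.
- **Global pixel noise**: Gaussian, std 0.02; organ means are separated from
  each other and from distractor means by ≥3× this noise so the KDE remap is
  well-posed.

What the phantoms do **not** emulate: partial-volume boundary blur,
spatially correlated reconstruction-kernel noise, anatomy-specific shape
priors, and contact between the target and equal-intensity neighbours.
Passing tests on phantoms therefore demonstrate the mechanism (seeded growth,
boundary gating, refinement, protocol bookkeeping), not clinical-grade
accuracy on real scans.

## Numerical choices

- KDE: Gaussian kernel, Scott's rule bandwidth n^(−1/5)·std floored at 0.01,
  evaluated on a 256-point lookup grid over [0, 1] with linear interpolation
  (exact at the grid nodes; interpolation error bounded by the grid
  resolution and tested).
- Otsu: 256 equal bins between the input's min and max; exhaustive
  between-class-variance maximisation; lowest maximising boundary on ties;
  constant input raises a degenerate-input error and the caller keeps the
  previous mask with a warning flag.
- Difference image: signed difference clamped at 0 (mask-induced
  *brightening* is the growth signal); the absolute difference also admits
  darkened artifacts and is available behind a flag.
- Convergence: exact bitwise mask equality; cycle detection by hashing every
  visited mask (sound because the step map is deterministic).
- Degenerate inputs: empty masks raise input errors; a crop with fewer than
  two nonzero pixels falls back to an indicator density around the masked
  pixels' mean value; negative-click refinement may legally empty the mask
  (flagged).
- All NN arithmetic is float32; encode/decode are bitwise deterministic for
  fixed weights.

## Problem sizes

Fixture training uses 150 corpus images at 128×128 for 12 epochs (Adam,
lr 2·10⁻³, batch 8).  Phantom evaluations run at 128×128 with organ radii
0.12–0.20 of the image side; interactive sessions use at most 5 simulated
clicks.  These sizes keep a full training-plus-evaluation cycle within
minutes on a single CPU while leaving every mechanism (growth, convergence,
refinement, replay) observable.

## Known limitations

- The fixture autoencoder's reconstruction-noise profile only approximates
  that of a frozen classification encoder; recovery quality on phantoms is
  sensitive to it, and organs much larger than a few percent of the frame
  are under-segmented by the initial growth (the full-scale reference system
  shows the same qualitative behaviour: large organs need several clicks).
- Growth can stall in a limit cycle (flagged not-converged) on strongly
  textured organs; refinement clicks are the intended recovery path.
- The negative-click model is purely geometric (isotropic Gaussians); it
  cannot carve non-convex leaks precisely.
- 2-D only; volumes are handled one slice at a time.
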