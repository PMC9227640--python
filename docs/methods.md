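# Methods

## Problem and model

`egan3d` learns a mapping from 3D FDG-PET volumes to co-registered
T1-weighted MRI volumes with a conditional GAN.  The design premise is
that FDG uptake is dominated by grey-matter metabolism, so a PET volume
carries enough tissue information to reconstruct structural contrast —
provided the geometry lost to the PET point-spread function is
reintroduced.  The generator therefore splits into a *content* pathway
(the Elicit encoder: per-view separable convolutions collapsed to 2D
and fused) and a *geometry* pathway (a fixed 3D Sobel gradient
magnitude of the PET, rescaled by one learnable 3×3×3 convolution).
The decoder sees exactly two channels: the fused 2D map tiled along
the axial axis, and the processed edge field.  All volumetric detail
along the axial direction therefore flows through the edge channel;
ablating it collapses the translation to an essentially axially
uniform prediction, which is what makes the ablation experiment sharp.

Assumptions inherited by the model:

* inputs are already spatially registered and resampled to a common
  cubic grid (registration is out of scope);
* PET intensities are normalised by their global mean, both modalities
  rescaled to [−1, 1];
* paired training data (same subject, both modalities) is available.

## Architectural choices where the design was open

* **Encoder block topology.**  Per view, the two separable blocks run
  in *parallel*: a long-range branch (kernel = full axis extent,
  collapsing the axis in one step) and a local branch (kernel = half
  extent, stride = kernel, then a length-2 collapse).  Their outputs
  concatenate as channels and two 3×3 2D convolutions reduce them to
  one c×c map with c equal to the in-plane extent.  A sequential
  arrangement would make the second block's "local" kernel act on an
  already collapsed axis, which is vacuous — hence parallel.
* **Fusion normaliser.**  The column sum in the fusion runs over the
  row index only, as a column-wise normalisation; a signed ε = 1e-8 in
  the denominator keeps the division finite when tanh terms cancel.
  The fusion is intentionally not scale invariant (tanh saturates);
  the test-suite guards against replacing it with a softmax.
* **2D→3D bridge.**  The fused map is tiled along the axial axis —
  the minimal-parameter reading of a "two-channel" decoder input.
* **Decoder.**  Four 3×3×3 stride-1 convolutions, channel schedule
  2→64→32→16→1 at reference scale, BatchNorm + LeakyReLU(0.2) after
  the first three, tanh output (matching the [−1, 1] target).  The
  output layer carries no BatchNorm: normalising the pre-tanh
  activations would force the output distribution toward saturation.
* **Discriminator.**  2→64→128→256 4×4×4 stride-2 convolutions with
  LeakyReLU, a 1×1×1 projection, global average, sigmoid — one
  conditional probability per (PET, MRI) pair.
* **Borders.**  Sobel uses symmetric (edge-inclusive) reflection
  padding, avoiding spurious boundary edges; network convolutions use
  zero padding.
* **Optimisation.**  One discriminator step per generator step, Adam
  lr 1e-4, β=(0.5, 0.999), weights i.i.d. N(0, 0.02²).  The generator
  uses the non-saturating adversarial term by default; the `kl`
  loss-variant switches to the saturating minimax form and `mse`
  disables the adversarial game, reproducing the objective ablation
  axes.  L2 is the voxel *mean*, so α₂ = 0.5 is resolution
  independent.

## Differentiation core

No deep-learning framework is used.  `egan3d.autodiff` is a small
tape-based reverse-mode engine over numpy arrays: elementwise ops,
reductions, shape ops, a two-operand einsum (the separable
convolutions), and 2D/3D convolutions (shift-accumulate for stride 1,
im2col + BLAS for strided).  Every operation is checked against
central finite differences in the test-suite; the network trains in
float32, gradient checks run in float64.

## Phantom generator

The paired-phantom module is the package's stand-in for clinical data.
Each "subject" is a nested-ellipsoid head — CSF shell, grey-matter
shell, white-matter core — with per-subject random semi-axes and
rotation.  The pseudo-MRI assigns T1-like means (CSF 0.25, GM 0.55,
WM 0.9) plus Gaussian noise (σ = 0.03).  The pseudo-PET applies
GM-dominant uptake weights (CSF 0.15, GM 1.0, WM 0.45) to the same
label map, blurs it with the scanner PSF and adds the same noise.

Geometry is physical: the field of view is fixed at 180 mm — the
reference 90-voxel grid at 2 mm spacing — so a grid of extent `E` has
voxels of 180/E mm, and the PET PSF is specified as 6 mm FWHM (typical
clinical PET) and converted to voxels per grid.  Shrinking the extent
coarsens the sampling without changing the simulated physics; an early
voxel-specified blur over-smoothed coarse grids about fourfold and was
replaced by this parameterisation.

What the phantom does *not* emulate: real cortical folding, bias
fields, partial-volume mixtures beyond Gaussian blur, inter-tissue
intensity overlap beyond additive noise, or registration error.
Passing the desk-scale experiments therefore demonstrates that the
architecture, losses, optimisation and metrics are implemented
coherently and that the edge channel carries recoverable geometry —
not that clinical-grade synthesis quality would be reached on a real
cohort, which requires clinical paired data and GPU-scale training.

## Desk-scale learning experiment

The liveness experiment trains the translator under the `desk` profile
narrowed to a compact problem size chosen so the whole experiment
(three seeds, plus the Sobel ablation with the same seeds) runs in
minutes on one CPU: grid 24³, 8 training and 4 held-out phantoms,
batch 4, 200 epochs.  Measured quantities:

* the generator L2 term at the final epoch relative to epoch 1
  (expected well below 50%);
* held-out PSNR of the translation versus the *no-learning baseline*
  — scoring the pseudo-PET itself against the pseudo-MRI (expected
  gain ≥ 3 dB);
* the same PSNR with the edge channel ablated, same seeds (expected
  no higher than the full model; in practice the ablated model barely
  beats the baseline, confirming the volumetric information flows
  through the Sobel pathway).

Metrics are computed on a *common* [0, 1] scale: preprocessed inputs
and the generator's tanh output all live on [−1, 1], and the fixed
affine map (x + 1)/2 carries them to [0, 1] with `data_range = 1`.
(Rescaling each volume by its own min/max would silently normalise
away contrast errors of the translation.)  MAE can additionally be
reported on a native intensity scale via explicit `data_range`
configuration, since absolute MAE magnitudes are scale-bound by
construction.

## Numerical details and degenerate inputs

* Probabilities are clamped to [1e-7, 1−1e-7] before logs.
* PSNR of identical volumes returns `inf` (sentinel), cross-correlation
  of a constant volume raises (undefined), rescaling a constant volume
  raises, PET mean-normalisation requires a positive mean.
* GLCM discretisation is equal-width over the per-volume [min, max];
  the co-occurrence accumulation is symmetric, so the counts matrix
  equals its transpose.  The single 60° in-plane direction at
  distance 3 is the lattice offset (2, 3, 0); texture summaries
  default to the 13-direction average.
* The three-class segmenter is k-means (k = 3, fixed seed) on
  intensities with labels sorted by class mean; an optional head mask
  excludes air, which otherwise joins the CSF-like class.
* BatchNorm uses batch statistics in training and running statistics
  in eval; translation outputs are defined in eval mode, so repeated
  translation of the same volume is bitwise reproducible.

## Known limitations

* The reference (`paper`) profile at 90³ trains only at GPU-scale
  wall-times; on CPU it is usable for single forward passes.
* The compact experiment sizes trade statistical power for runtime:
  three seeds bound seed-to-seed variability but do not estimate it
  precisely.
* The phantom's intensity-separable tissues make the three-class
  k-means segmenter near-perfect; on real MRI a dedicated
  segmentation tool should be used instead.
* The engine is single-threaded numpy; it favours clarity and
  testability over throughput.
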