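# egan3d — 3D FDG-PET → T1-weighted MRI translation

`egan3d` synthesises a structural T1-weighted MRI volume from a
co-registered FDG-PET volume of the same subject.  It is aimed at
neuroimaging groups who have metabolic PET but lack the paired
structural scan — e.g. to drive partial-volume correction or
tissue-based analyses — and at methodologists who want a compact,
CPU-runnable testbed for volumetric cross-modality GANs.

## The model

The translator `G : P → M` is a conditional GAN with an unusual,
deliberately shallow generator:

* **Elicit encoder.**  The PET volume (extent `E`, default 90³) is
  collapsed into three 2D feature maps — sagittal `x`, coronal `y`,
  axial `z`, each `c × c` — by *separable* convolutions per view: a
  long-range branch whose 1D kernel spans the whole axis (extent `E`)
  and a local branch with kernel `E/2` (stride `E/2`) plus a length-2
  collapse, followed by two 3×3 2D convolutions.
* **Fusion.**  The view maps are mixed by a tanh-normalised Hadamard
  product (self-attention-like, no learned projections):

  `g(i,j) = tanh(x(i,j) ⊙ ȳ(i,j)) / Σᵢ tanh(x(i,j) ⊙ ȳ(i,j))`,

  then `l = fuse(g, z̄)` the same way (bars denote transposes).  Columns
  of `g` and `l` sum to 1.
* **Geometric channel.**  A fixed 3×3×3 Sobel operator (separable
  `[1,2,1]⊗[1,2,1]⊗[1,0,−1]`) supplies the per-voxel gradient
  magnitude of the PET; a learnable 3×3×3 convolution rescales it.
* **Decoder.**  The fused map `l`, tiled along the axial axis, and the
  edge channel form a two-channel 3D input decoded by four 3×3×3
  convolutions (BatchNorm + LeakyReLU(0.2), final tanh) into an MRI in
  [−1, 1].
* **Objective.**  `α₁·L_GAN + α₂·L2` with `α₁ = 1`, `α₂ = 0.5`; the
  discriminator is a 3D fully-convolutional classifier over the
  (PET, MRI) channel pair, and the generator uses the non-saturating
  adversarial form.  At discriminator optimality the adversarial value
  equals `2·JSD(p_g‖p_r) − 2 ln 2`, which the test-suite verifies
  numerically.  Training uses Adam (lr 1e-4, β = (0.5, 0.999)), weights
  initialised N(0, 0.02²), batch 12, 1000 epochs in the reference
  profile.

The evaluation suite implements PSNR, SSIM (3D Gaussian window), MAE,
normalised cross-correlation, a 3D grey-level co-occurrence matrix
(8 levels, distance 3, single-direction or 13-direction average) with
Haralick energy/homogeneity/dissimilarity/contrast, and a three-class
intensity segmentation for per-tissue mean comparisons.

Because clinical paired data cannot ship with a package, `egan3d`
includes a paired-phantom generator: nested-ellipsoid heads (CSF shell,
GM shell, WM core) rendered as a T1-like MRI and as a grey-matter-
dominated, PSF-blurred, noisy pseudo-PET on a physically scaled grid
(180 mm field of view, 6 mm PET PSF).  Everything — training,
translation, every metric — runs on these phantoms on one CPU.

## Worked example

```python
import egan3d as eg

# a desk-scale cohort of paired phantoms (24^3 grid)
train, heldout = eg.experiments.make_experiment_pairs(
    extent=24, n_train=8, n_heldout=4, data_seed=1100)

model = eg.EGAN(train, config=eg.make_config(
    "desk", extent=24, epochs=200, batch_size=4, val_fraction=0.0, seed=1))
res = model.fit()
print(res.summary(heldout))
```

prints (abridged):

```
E-GAN translation results
=========================================
extent: 24^3   epochs: 200   batch: 4
objective: mse_jsd  (alpha1=1.0, alpha2=0.5)
generator L2:  epoch 1 = 0.84253   final = 0.04764
discriminator loss (final): 1.42427
saturated-batch fraction (final): 0.000
-----------------------------------------
held-out metrics (mean over pairs):
  psnr    18.8981
  ssim     0.6871
  mae      0.0719
  xcorr    0.9082
```

The generator's voxelwise L2 term falls from 0.84 to 0.05 over
training, and the held-out PSNR of ~18.9 dB compares with ~15.8 dB for
the no-learning baseline that scores the pseudo-PET itself against the
real pseudo-MRI — the translation recovers about 3 dB of structural
fidelity on this seed — and `res.evaluate(...)` gives the same metrics
per subject.

## Command line

```bash
egan3d phantom --n 16 --extent 32 --seed 7 --out data/
egan3d train --manifest data/manifest.tsv --profile desk --out run/
egan3d translate --checkpoint run/ckpt_best.npz --in pet.nii.gz --out mri_hat.nii.gz
egan3d evaluate --checkpoint run/ckpt_best.npz --manifest data/manifest.tsv --out report.json
egan3d sobel --in pet.nii.gz --out edges.nii.gz
```

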