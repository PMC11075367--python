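# Methods

This note documents the models, assumptions, parameter conventions, and
numerical choices behind `petac`. The package translates non-attenuation-
corrected (NAC) PET volumes into attenuation-corrected (AC) estimates with a
conditional GAN, and ships the simulation, preprocessing, metric, and
statistics machinery needed to study that translation quantitatively.

## 1. Phantom simulator (`petac.phantom`)

### Anatomy

`make_phantom` builds a 2-D (single axial slice, promoted to a 3-D grid of
shape `(1, H, W)`) whole-body-analog section:

- an elliptical soft-tissue body (background SUV `background_suv`, default 1),
- a posterior spine analog (bone attenuation, no excess uptake),
- two kidney analogs and one bladder analog with high physiological uptake
  (`organ_suv_range`, default 120–250 SUV — these act as the hot organs that
  motivate clipping, see §2),
- a prostate-analog region,
- `n_lesions` spherical lesions (SUV in `lesion_suv_range`, default 4–30)
  placed inside location-specific habitats (`prostate`, `bone`,
  `lymph_node`, `other`). Lesion centers are drawn from the habitat's own
  voxel set so small habitats are hit reliably; placement retries up to 200
  times and raises a descriptive error if the habitat cannot accommodate the
  requested lesion.

Attenuation is a three-material map: air (0), soft tissue (`mu_tissue`,
default 0.096 cm⁻¹), bone analog (`mu_bone`, default 0.17 cm⁻¹), all at
511 keV. A Hounsfield-unit map is derived affinely from μ with water at 0 HU
and air at −1000 HU.

### Attenuation physics

For annihilation photons, the detection probability of an event at voxel x
along a line of response at angle θ is `exp(−∫ μ dl)` over the **full**
line through x (both photons must escape). `attenuation_factors` computes

A(x) = (1/N) · Σ_θ exp(−∫_line(x, θ) μ dl),  θ = πk/N, k = 0…N−1

with `n_angles` N = 8 by default. Integrals are ray-marched at step
h = 0.5 · min(in-plane voxel size), sampling μ at midpoint offsets
±(k+0.5)h with bilinear interpolation (`scipy.ndimage.map_coordinates`,
`order=1`, `mode='grid-constant'` so out-of-grid values blend to zero the
same way a zero-padded bilinear lookup does — plain `'constant'` mode does
not blend at the border and disagrees with a brute-force oracle at edge
voxels). Voxel sizes are mm; μ is cm⁻¹; the integral converts via h/10.

### PET pair synthesis

`simulate_pair` produces:

- **AC-PET**: the activity map blurred with a Gaussian point-spread function
  (`psf_fwhm`, default 4.1 mm, σ = FWHM/2.355 converted to voxels per axis),
- **NAC-PET**: the activity multiplied by A(x) first, then blurred,

each with optional Poisson noise at `count_scale` expected counts per SUV
per voxel (default 2000), using independent seeded generators for the two
scans. NAC ≤ AC holds voxelwise in the noise-free case.

## 2. Preprocessing (`petac.preprocess`)

- **SUV conversion**: SUV = c·w / D_decayed with activity concentration c
  (Bq/mL), patient weight w (grams), and injected dose decayed to scan time,
  D_decayed = D · 2^(−Δt/T½), fluorine-18 T½ = 6586.2 s.
- **V1 (clip/scale)**: `np.clip(suv, 0, 100) / 100`. The clip bounds the
  influence of physiological hot spots (bladder, kidneys) whose SUVs dwarf
  lesion uptake; the result is the (0, 1) network intensity space. The
  inverse (`unscale`) multiplies by the clip threshold.
- **V2 (Nyul + clip/scale)**: piecewise-linear histogram standardization of
  the NAC image before clip/scale; the AC training target is always
  V1-style.

### Nyul standardization details

- Landmarks are the 20 foreground percentiles 80, 81, …, 99 (foreground =
  voxels > 0, because air dominates a whole-body histogram). The standard
  landmark vector is the mean over training images.
- The intensity map is linear between adjacent landmarks. **Below** the
  first landmark it is anchored through the origin: zero activity is zero in
  every intensity space, and this keeps mapped foreground values positive,
  so the foreground set is invariant under the transform. (End-slope
  extrapolation downward can cross zero; clamping would then silently move
  voxels into the background and shift all foreground percentiles — we
  observed up to 16% error at the 99th landmark before anchoring.)
  **Above** the last landmark the end segment's slope extrapolates.
- Idempotence tolerance: mapping a training image and re-measuring its
  landmarks reproduces the standard landmarks exactly (≈1e-15) when the
  image's landmark vector is a linear rescaling of the standard, because
  the piecewise map is then globally linear. For generic images there is an
  inherent order-statistics gap — percentiles of the mapped image are
  interpolations between mapped order statistics, not the mapped
  percentiles — leaving a residual of order 1e-3 on 64×64 foregrounds.
  Tests assert the linear case at 1e-6 and the generic case at 5e-3.

## 3. Networks (`petac.nn`, `petac.model`)

The GAN is implemented directly on numpy (im2col convolutions,
transposed convolutions, instance normalization, manual backpropagation,
Adam with β₁ = 0.5). Compute runs in `petac.nn.DTYPE` (float32 by default;
module-level so finite-difference gradient checks can switch to float64).
All layer and end-to-end gradients are verified against central
differences.

- **Generator**: U-Net with skip connections; kernel-4/stride-2/pad-1
  convolutions, LeakyReLU(0.2) down / ReLU up, instance norm (omitted at
  the innermost bottleneck), sigmoid output so the (0, 1) scaled-SUV
  contract holds by construction. Channels double per level from
  `base_channels`, capped at 8×. Default config is 256×256 input with 8
  levels; the desk-scale preset (`GeneratorConfig.small()`) is 64×64,
  4 levels, base 16.
- **Output bias initialization**: the final pre-sigmoid bias is
  initialized to `out_bias` (−2.5 in the small preset, sigmoid ≈ 0.08).
  Scaled PET slices are mostly near-zero background, and a 0.5-initialized
  sigmoid output spends most of early training closing that gap; the
  standard sparse-target bias initialization removes the transient.
- **Discriminator**: PatchGAN conditioned by channel-concatenating the NAC
  slice — three stride-2 blocks plus a 1×1 head, per-patch sigmoid, patch
  responses averaged to one score per image (a 256×256 input yields a
  32×32 patch map).
- **Losses**: BCE adversarial terms plus λ·L1 reconstruction (λ = 100).

Input sizes must match the configured `in_size` exactly; the generator
refuses to resample silently.

## 4. Training and inference (`petac.train`)

Studies are visited in seeded random order each epoch; slices within a
study are fed in consecutive batches of at most `batch_size` (25). Each
batch performs one discriminator update (real pair toward 1, fake toward 0)
and one generator update (fresh discriminator pass; adversarial gradient
plus λ-weighted L1 sign gradient). Defaults: lr 2e-4, Adam(0.5, 0.999),
25 epochs. After every epoch each validation scan is translated and its
NMSE recorded; the checkpoint minimizing the **median** per-scan validation
NMSE (mean by configuration) is kept. `infer_volume` translates a scaled
NAC volume slice-by-slice and multiplies by the clip threshold (100) to
return to SUV space.

### Desk-scale study conditions

The package's own end-to-end experiments run at: 64×64 single-slice
phantoms at 2.73×2.73×3.27 mm voxels; 40 training studies × 5 slices
(= 200 slices; many small studies give more optimizer updates per epoch
than few large ones, since batching is per-study); 4 validation and 6 test
studies; small generator/discriminator presets; 8–25 epochs. Under these
conditions the trained generator reaches a median held-out NMSE below 1%
against a preprocessed-NAC baseline of ≈34%.

### Realism limits

The simulator and desk-scale GAN are a controlled physics analog, not a
clinical model: single 2-D slices, three-material attenuation, angular
subsampling (8 angles), no scatter/randoms, no inter-patient anatomy
variation beyond random ellipse/organ geometry, and a small generator.
Absolute clinical SUV-error magnitudes should not be read off these
experiments; the pipeline's value is that every stage is verifiable
against oracles.

## 5. Image metrics (`petac.metrics`)

On scaled (0, 1) volumes unless noted:

- NMSE (%) = 100·Σ(g−r)²/Σr² (reference energy; all-zero reference is an
  error),
- MAE (%) = 100·mean|g−r|,
- PSNR (dB) = 10·log₁₀(range²/MSE), `inf` for identical inputs,
- SSIM: Gaussian window σ = 1.5 (truncate 3.5, 11×11), K₁ = 0.01,
  K₂ = 0.03, population covariance, means over the window-valid region;
  cross-checked against `skimage.metrics.structural_similarity`
  (`gaussian_weights=True, use_sample_covariance=False`) to 1e-6. Volume
  SSIM is the mean over axial slices.

## 6. Lesion statistics (`petac.lesionstats`)

- SUV_max/SUV_mean over boolean lesion masks; relative difference
  100·(AC − Gen)/AC (positive = underestimation by the generated image).
- **Repeatability**: bias = mean, stdev (ddof = 1), RC = 1.96·√2·stdev
  (the 95% test–retest bound under normality).
- **ICC**: two-way random-effects, absolute-agreement, single-measure
  ICC(2,1) via its ANOVA closed form
  (MSR−MSE)/(MSR+(k−1)MSE+(k/n)(MSC−MSE)), clipped to [0, 1];
  cross-checked against `pingouin.intraclass_corr` (labelled ICC(A,1) in
  McGraw–Wong naming). Targets are lesions; patient clustering is handled
  by the Wilcoxon and mixed-model machinery, not the ICC.
- **Clustered Wilcoxon** (Rosner–Glynn–Lee signed rank): signed midranks
  summed per patient cluster; the null distribution flips cluster signs.
  With ≤ 14 clusters all 2^m flips are enumerated exactly (this makes the
  one-lesion-per-patient case match scipy's exact Wilcoxon); otherwise
  Z = T/√(ΣS_i²) with a normal reference.
- **Covariate models**: `statsmodels` MixedLM with a random intercept per
  patient, ML fit; categorical covariates use treatment coding
  (lymph_node / PSMA-RADS 4 reference levels); the reported comparison
  p-value is a likelihood-ratio test against the intercept-only model.

## 7. I/O (`petac.io`)

NIfTI volumes with a diagonal affine from voxel spacing; in-memory arrays
are (slice, y, x) and files are (x, y, slice). The value space
(counts / SUV / scaled) travels in the NIfTI `descrip` field. Acquisition
metadata (dose, weight, times) lives in a JSON sidecar; `load_study`
raises a descriptive error when SUV conversion is requested without the
sidecar. CT-to-PET resampling is trilinear with −1000 HU (air) fill and
refuses disjoint fields of view. `render_difference_map` writes a coronal
mid-plane AC-minus-generated map (red = underestimation).
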