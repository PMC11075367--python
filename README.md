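# petac — deep-learning attenuation correction for PET, end to end

PET scanners need an attenuation map (usually from CT) to correct for the
photons absorbed on their way out of the body; without it, activity deep in
the body is underestimated — by a third or more of the image energy in our
phantoms. `petac` studies whether a conditional GAN can learn that
correction directly from the uncorrected image: it translates
non-attenuation-corrected (NAC) PET volumes into attenuation-corrected (AC)
estimates with a Pix-2-Pix-style model (U-Net generator, PatchGAN
discriminator, BCE + L1 losses), and ships everything needed to test the
idea quantitatively:

- a **phantom simulator** with real attenuation physics (line integrals of
  μ at 511 keV over full lines of response, Poisson counting noise,
  Gaussian point spread),
- **preprocessing**: SUV conversion with isotope decay, clip/scale
  normalization (V1), and Nyul histogram standardization (V2),
- the **GAN** itself, implemented directly on numpy with verified manual
  backpropagation — no deep-learning framework required,
- **image metrics** (NMSE, MAE, PSNR, SSIM) and a **lesion-statistics
  battery** (SUV_max/SUV_mean, repeatability coefficients, ICC, clustered
  Wilcoxon tests, mixed-effects covariate models),
- **NIfTI I/O** and a `petac` command-line interface.

See [docs/methods.md](docs/methods.md) for models, assumptions, and
numerical choices.

## Worked example

Simulate one phantom study and measure how much the missing attenuation
correction costs:

```python
from petac import PhantomSpec, generate_sample
from petac.preprocess import clip_scale
from petac.metrics import evaluate_scan

sample = generate_sample(PhantomSpec(seed=7))
nac, ac = clip_scale(sample.nac_pet), clip_scale(sample.ac_pet)

print("AC SUV max: ", round(float(sample.ac_pet.voxels.max()), 2))
print("NAC SUV max:", round(float(sample.nac_pet.voxels.max()), 2))
print(evaluate_scan(nac.voxels, ac.voxels))
```

Output:

```
AC SUV max:  227.16
NAC SUV max: 58.18
ScanMetrics(nmse=36.512440535474475, mae=2.4993404541015627, psnr=19.576532764365254, ssim=0.7291597071461711)
```

Attenuation suppresses the peak uptake almost fourfold and leaves a 36.5%
NMSE between the uncorrected and corrected images. Training the GAN on 200
such slices closes that gap:

```python
from petac.model import DiscriminatorConfig, GeneratorConfig
from petac.preprocess import preprocess_pair
from petac.train import TrainConfig, train_model, infer_volume
from petac.metrics import nmse

# train_pairs / val_pairs: lists of (nac, ac) PETVolume pairs in SUV space
tp = [preprocess_pair(n, a, "v1") for n, a in train_pairs]
vp = [preprocess_pair(n, a, "v1") for n, a in val_pairs]
ckpt, log = train_model(tp, vp, TrainConfig(epochs=25, seed=1),
                        GeneratorConfig.small(), DiscriminatorConfig.small())

gen_suv = infer_volume(ckpt, test_nac_scaled)        # SUV-space volume
print(nmse(gen_suv.voxels / 100.0, test_ac_scaled.voxels))
```

At desk scale (40 studies × 5 slices of 64×64 phantoms, small presets,
25 epochs, ~1 minute of training on one CPU) the trained generator reaches
a median held-out NMSE of **0.88%** against the **34.3%**
preprocessed-NAC baseline.

The same pipeline is available from the command line:

```sh
petac simulate --out data --n 40 --seed 17
petac preprocess --data data --out prep --strategy v1
petac train --data prep --out run
petac infer --ckpt run/checkpoint.npz --in prep/study000_nac.nii.gz --out gen.nii.gz
petac evaluate --gen gen_dir --ref ref_dir --out metrics.csv
petac lesion-stats --records lesions.csv --out stats
```

## Testing

```sh
python -m pytest
```

The suite covers unit arithmetic, property-based checks (hypothesis), and
independent oracles: a scalar brute-force ray integrator for the
attenuation factors, `skimage` for SSIM, `pingouin` for the ICC, scipy's
exact Wilcoxon and Monte-Carlo permutation for the clustered signed-rank
test, and finite differences for every network gradient.

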