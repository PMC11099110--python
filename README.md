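# zsdeconv

Zero-shot, self-supervised denoising and deconvolution for fluorescence
microscopy. Given a single noisy image (or 3D stack) and the microscope's
point-spread function, `zsdeconv` trains a small dual-stage neural network on
that image alone — no clean ground truth, no extra acquisitions — and returns
both a denoised image and a super-resolved deconvolution.

## Who this is for

Microscopists and image-analysis folk working at low photon budgets (live-cell
TIRF, light-sheet, confocal, wide-field volumes), where acquiring paired
high-SNR training data is impractical and classical deconvolution amplifies
shot noise.

## The method

Deconvolution is posed as an unsupervised inverse problem regularized by the
imaging physics. A network `f_θ` is trained so that its output, re-blurred by
the PSF and downsampled back to the camera grid, matches the data:

    argmin_θ  || y − (f_θ(y) ∗ PSF)↓ ||²

Trained naively this amplifies noise, so the data term never compares against
the raw image itself:

- **2D — recorrupted pairs.** From one noisy image `y`, two images with
  independent noise are synthesized: `ŷ = y + αg`, `ỹ = y − g/α`, with
  `g ~ N(0, σ²)` and the pixelwise variance `σ² = β₁·H(y − b) + β₂` matching a
  mixed Poisson–Gaussian camera (`b` offset, `β₂` read-noise variance, `H` a
  5-px mean filter). At unit gain the optimal hyperparameters are
  `α = β₁ = 1`, which this package verifies by Monte-Carlo: the correlation of
  the two noise residuals vanishes exactly there. `ŷ` is the training input,
  `ỹ` the target.
- **3D — interleaved slices.** A stack is split into odd and even z-slices;
  the odd substack is the input and the even one the target, with a
  gap-amending regularization (GAR) correcting the systematic offset between
  adjacent planes.

The dual-stage model (two sequentially connected U-Nets in 2D, two RCAN-style
channel-attention stages in 3D) outputs a denoised image `f_θ′` and a
deconvolved image `f_θ`, trained with

    L = μ·||f_θ′(ŷ) − ỹ||² + (1−μ)·( ||(f_θ(ŷ) ∗ PSF)↓ − ỹ||² + λ·R_Hessian(f_θ(ŷ)) )

where `R_Hessian` penalizes second spatial derivatives (μ = 0.5; λ = 0.02 in
2D, 0.1 in 3D). Networks, backprop and Adam are implemented in numpy inside
the package (`zsdeconv.nn`) with hand-written adjoints, verified against
finite differences in the test suite.

## Worked example

```python
import numpy as np
import zsdeconv as z

# simulate one low-light acquisition: filaments at 15 photons on average
sigma = 275.0 / (2 * np.sqrt(2 * np.log(2)))       # PSF FWHM 275 nm
psf   = z.make_gaussian_psf(sigma, pixel_size=62.5, support=13)
cam   = z.CameraModel(background_offset_b=100.0, gaussian_variance_beta2=4.0)
truth = z.generate_filaments((128, 128), 6, seed=3, pixel_size=62.5)
img   = z.render_noisy(truth, psf, cam, mean_photons=15.0, seed=7)

# zero-shot training on this single image (reduced desk preset, ~5 min CPU)
psf_sr = z.simulator.upsample_psf(psf, 2)          # PSF on the 2x output grid
est = z.ZSDeconvNet2D(psf=psf_sr, iterations=800, n_patches=400,
                      batch_size=3, patch_size=64, initial_lr=2e-4,
                      seed=0).fit(img)
deconvolved = est.transform(img)                   # 256x256, super-resolved

# compare against the classical baseline
from zsdeconv.evaluation import LinearMatch
rl = z.richardson_lucy(img.counts, psf, 20, background=100.0)
x = (img.clean - img.clean.min()) / np.ptp(img.clean)      # normalized reference
m = LinearMatch.fit(img.counts, x)
raw_psnr = 10 * np.log10(1 / np.mean((m.apply(img.counts) - x) ** 2))
print("PSNR raw       :", round(raw_psnr, 2), "dB")
print("PSNR RL-20     :", round(z.psnr_degradation_matched(rl, img.clean, psf, 1), 2), "dB")
print("PSNR zsdeconv  :", round(z.psnr_degradation_matched(deconvolved, img.clean, psf_sr, 2), 2), "dB")
```

On this simulation the run prints

```
PSNR raw       : 27.11 dB
PSNR RL-20     : 38.84 dB
PSNR zsdeconv  : 39.79 dB
```

i.e. the zero-shot model beats both the raw input and 20-iteration
Richardson–Lucy under the degradation-matched PSNR protocol (the output is
re-blurred with the PSF, downsampled and affinely matched to the normalized
clean reference before scoring). On a held-out straight filament the
deconvolved profile FWHM shrinks from ~267 nm (raw) to ~163 nm.

A command-line interface covers the same pipeline:

```bash
zsdeconv simulate --structure filaments -p 15 --seed 3 -o img.tif
zsdeconv train -i img.tif --psf img_psf.tif --dim 2 -o run/
zsdeconv predict -m run/ -i img.tif -o out/
zsdeconv evaluate --pred out/deconvolved.tif --ref img_clean.tif \
                  --psf img_psf.tif --report report.json
```

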