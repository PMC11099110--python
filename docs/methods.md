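# Methods

## Model and assumptions

`zsdeconv` treats a fluorescence microscope as a linear shift-invariant
system with mixed Poisson–Gaussian camera noise:

    y = gain · Poisson(s ∗ PSF) + N(b, β₂),

where `s` is the fluorophore density, `b` a spatially constant camera offset
and `β₂` the read-noise variance in counts². Restoration is learned from the
noisy data alone by making the network's deconvolved output explain the data
through the same forward model — convolution with the PSF followed by
downsampling to the camera grid — while a noise-independent target prevents
the network from fitting the noise.

Assumptions worth stating explicitly: the PSF is spatially invariant and
known (measured or parametric); the offset is a scalar, not an sCMOS
per-pixel map; noise is independent across pixels (fixed-pattern stripe
noise violates this and is handled separately by Fourier apodization after
inference); in 3D, adjacent z-planes sample nearly the same structure, which
is what makes odd/even interleaving a valid input/target pairing and what the
gap-amending regularization (GAR) corrects where it fails.

## Self-supervision

**2D recorruption.** From `y`, draw `g ~ N(0, σ²)` pixelwise with
`σ² = β₁·max(H(y − b), 0) + β₂` (`H` = 5-px mean filter, reflective
boundary; the clamp keeps the variance nonnegative below background) and
form `ŷ = y + αg` (input), `ỹ = y − g/α` (target). The added components are
anticorrelated by construction, and at unit gain the total noise residuals
of `ŷ` and `ỹ` decorrelate exactly at `α = β₁ = 1` — the package's
`independence_sweep` measures this and `scripts/acceptance.py` reports the
grid argmin. `β₂` comes from calibration or from a user-designated
sample-free region (`estimate_beta2`); an automatic background-region finder
is deliberately out of scope. A fresh `g` is drawn every time a training
patch is served: this is the strongest form of the recorruption
augmentation and costs nothing, whereas caching a fixed number of
pre-recorrupted copies would only approximate the same distribution.

**3D interleaving.** Slices are numbered 1-based, so the "odd" substack
starts at the first slice; an unmatched trailing slice is dropped with a
warning. The GAR reference `f_θ′(z)` — the stage-1 output on the full-depth
stack — is recomputed each step and treated as a constant (no gradient),
since it acts as an estimate of the systematic odd/even expectation gap,
not as a trainable path. Patch geometry (flips, in-plane quarter-turn
rotations) is applied jointly to input, target and GAR reference; axis
exchanges involving z are excluded because of axial anisotropy.

## Objective

    L = μ·L_den + (1−μ)·L_dec
    L_den = ||f_θ′(ŷ) − ỹ||²                                (2D)
    L_dec = ||(f_θ(ŷ) ∗ PSF)↓ − ỹ||² + λ·R_Hessian(f_θ(ŷ))

with the 3D variant using odd/even pairs and adding GAR terms (weight γ) to
both the denoising and deconvolution parts. All squared-error terms are
pixel **means**, not sums, so μ, λ, γ transfer across patch sizes; λ was
calibrated under this convention (0.02 in 2D, 0.1 in 3D; μ = 0.5; γ = 1).
`R_Hessian` sums squared second differences along each spatial axis plus
mixed terms with weight 2, normalized by pixel count; an `axial_weight`
knob rescales z-terms (default 1).

The downsampling operator is non-overlapping block averaging (camera pixel
integration); the convolution boundary is reflective padding followed by
cropping — microscopy fields of view are not periodic — with periodic and
zero-padding modes available for tests. In 2D the deconvolved output lives
on a 2× lateral grid and the forward model maps it back (the PSF must be
sampled at the output pixel size; `simulator.upsample_psf` does this); in
3D the output stays on the input grid and the resolution gain comes from
deconvolution alone.

## Networks and optimization

Both backbones are dual-stage: stage 1 denoises on the input grid, stage 2
consumes stage 1's output and deconvolves. Stages use global residual
connections and a final ReLU (intensities are nonnegative); channel
attention gates in the 3D model are zero-initialized so they start neutral
at 0.5. Every stage's head convolution is zero-initialized so the stage
begins as the identity mapping: with a random head, the ReLU-clamped
output can collapse to zero on sparse low-signal data early in training,
after which no gradient flows; the identity start removes this
dead-output failure mode. Because no autodiff framework is a dependency, layers implement
explicit forward/backward passes in numpy (im2col convolutions, GEMM); the
loss operators expose exact adjoints (including the reflective-padding
convolution, whose adjoint folds border contributions back via a scatter
add). Correctness is enforced by finite-difference gradient checks over
both full networks in the test suite.

Optimization is Adam with the step schedule lr(i) = lr₀ · 0.5^⌊i/10000⌋,
lr₀ = 0.5·10⁻⁴, batch 4 (2D) / 3 (3D), gradient clipping at global norm 1
as a divergence guard, and patch sampling without replacement per epoch.
A NaN loss aborts training and restores the last good snapshot.

**Presets.** The full-scale configuration (depth-4 U-Nets, 50,000
iterations with 128×128 patches in 2D; 10,000 iterations with 64×64×13
patches in 3D) is shipped as `FULL_SCALE_PRESET_*` but is a GPU-scale workload.
The tests and examples use a reduced desk preset — depth-2 U-Net /
single-residual-group RCAN, 16 or 8 channels, 64×64 or 24×24×8 patches,
250–800 iterations — with the learning rate raised to 2·10⁻⁴ to reach a
useful optimum within the shorter schedule. Test-time adaptation clones a
fitted model and fine-tunes it for ~50 steps on a single new timepoint;
the pretrained weights are never modified in place.

## Synthetic benchmark

The simulator renders two structure classes: sub-pixel point emitters
(bilinear splatting, mass-conserving, rejection-sampled minimum separation
so puncta stay resolvable) and persistent-random-walk filaments rasterized
at 0.25-px steps with ~1 px cross-section. Defaults follow the
characterization conditions: mean photon counts of 5–25 over the
structure's support (15 in the standard fixtures), offset b = 100 counts,
read-noise variance β₂ = 4 counts², gain 1 count/photon, PSF FWHM 275 nm
laterally (800 nm axially in 3D) at 62.5 nm pixels / 200 nm z-step. The
photon level is defined as the mean over nonzero-phantom pixels; averaging
over the whole frame would make the level depend arbitrarily on empty
background. The offset and β₂ values are fixture choices standing in for
typical sCMOS constants, not measurements of any particular camera.

What passing tests show: the self-supervision statistics are correct (the
β₁ optimum, recombination identity, noise moments), the losses implement
their definitions exactly, and on blur + mixed-noise data the zero-shot
pipeline improves degradation-matched PSNR over the raw input and a
20-iteration Richardson–Lucy baseline while narrowing filament profiles.
What they do not show: performance on real cameras (fixed-pattern noise,
per-pixel gain maps, PSF aberrations and depth variation), structures
unlike the two phantom classes, or full-scale training quality.

## Evaluation protocols

Degradation-matched PSNR re-blurs the output with the PSF, block-downsamples
to the reference grid, min–max normalizes the reference to [0, 1], fits the
least-squares affine match, and scores with peak 1 (capped at 100 dB for
exact matches) — by construction invariant to affine rescaling of the
input. The 3D variant skips the re-blur and restricts both fit and error to
voxels where the normalized reference exceeds 0.02 (at threshold 0 the mask
is the whole volume). FWHM uses the profile minimum as baseline and linear
interpolation at the half level. Fourier ring correlation uses 1-bin rings
and the fixed 1/7 criterion, returning Nyquist with a flag when no crossing
exists. The Richardson–Lucy baseline runs multiplicative updates on the
background-subtracted image; with periodic boundaries each iteration
conserves flux, which the tests assert to 0.1%.

## Numerical choices and edge cases

- Percentile normalization uses numpy's linear interpolation between order
  statistics; dialects differ, so this is pinned in tests. Constant images
  normalize to zeros with a warning rather than dividing by zero.
- Tiled inference pads reflectively by an 8-px lateral margin (plus 2 blank
  z-slices for stacks), feathers tile overlaps linearly with zero weight at
  tile borders (border pixels carry padding artifacts and are covered by the
  neighboring tile), and crops back to input-aligned geometry.
- The stripe-suppression mask attenuates a Gaussian-tapered 1-bin band
  around the zero-frequency plane along the stripe axis, excluding DC so the
  image mean is preserved.
- Training normalizes counts as (y − b)/scale with scale the 99.5th
  percentile of the background-subtracted first image; outputs are returned
  on the background-subtracted count scale.
- `estimate_beta2` warns when the designated background region's mean sits
  more than 3 standard deviations above the offset.

## Known limitations

Single-threaded CPU training limits practical model sizes well below the
full-scale preset. The recorruption derivation assumes unit gain (β₁
absorbs gain otherwise, but the optimum then shifts). Only in-plane
rotations augment 3D patches. The Born–Wolf and vector PSF models, SIM
reconstruction variants, and sCMOS per-pixel calibration are out of scope.
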