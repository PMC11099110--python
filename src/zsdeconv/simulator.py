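"""Synthetic fluorescence-microscopy image generation.

Ground-truth phantoms (sub-diffraction puncta and filamentous curves),
parametric Gaussian point-spread functions, and a mixed Poisson-Gaussian
camera model are combined to render noisy wide-field images at a
prescribed mean photon count.  These renderings drive every
characterization in the package: training fixtures, metric self-tests,
and the hyperparameter sweeps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import convolve as _nd_convolve


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GroundTruthPhantom:
    """Noise-free fluorophore-density map (arbitrary units, >= 0)."""

    pixels: np.ndarray
    pixel_size: tuple[float, ...] = (50.0, 50.0)  # nm per axis, (y, x) or (z, y, x)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim not in (2, 3):
            raise ValueError("phantom must be 2D or 3D")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("phantom contains non-finite values")
        if np.any(self.pixels < 0):
            raise ValueError("phantom values must be nonnegative")
        if len(self.pixel_size) != self.pixels.ndim:
            raise ValueError("pixel_size must give one length per axis")


@dataclass
class PSFKernel:
    """Normalized point-spread-function kernel with pixel-size metadata.

    The kernel sums to one, has odd side lengths and its peak at the
    geometric center; ``parametric_spec`` records Gaussian sigmas (nm)
    when the kernel was built parametrically.
    """

    kernel: np.ndarray
    pixel_size: tuple[float, ...]
    parametric_spec: dict | None = None

    def __post_init__(self) -> None:
        k = np.asarray(self.kernel, dtype=np.float64)
        if np.any(k < 0):
            raise ValueError("PSF kernel must be nonnegative")
        if any(s % 2 == 0 for s in k.shape):
            raise ValueError("PSF kernel side lengths must be odd")
        s = k.sum()
        if s <= 0:
            raise ValueError("PSF kernel must have positive mass")
        self.kernel = k / s
        center = tuple(s // 2 for s in k.shape)
        if not np.isclose(k[center], k.max()):
            raise ValueError("PSF peak must be at the kernel center")

    @property
    def ndim(self) -> int:
        return self.kernel.ndim


@dataclass
class CameraModel:
    """Mixed Poisson-Gaussian camera: counts = gain*Poisson + N(b, beta2)."""

    background_offset_b: float = 100.0
    gaussian_variance_beta2: float = 4.0
    photon_gain: float = 1.0

    def __post_init__(self) -> None:
        if self.gaussian_variance_beta2 < 0:
            raise ValueError("beta2 must be >= 0")
        if self.background_offset_b < 0:
            raise ValueError("background offset must be >= 0")
        if self.photon_gain <= 0:
            raise ValueError("photon gain must be > 0")


@dataclass
class NoisyImage:
    """Simulated or acquired 2D camera image in counts.

    ``clean`` (available for simulated data only) is the expected
    signal ``gain * lambda`` without background or noise -- the reference
    every evaluation protocol compares against.
    """

    counts: np.ndarray
    camera: CameraModel = field(default_factory=CameraModel)
    mean_photon_level: float | None = None
    clean: np.ndarray | None = None
    pixel_size: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if not np.all(np.isfinite(self.counts)):
            raise ValueError("counts contain non-finite values")


@dataclass
class NoisyStack:
    """3D stack of camera counts, axes (z, y, x)."""

    counts: np.ndarray
    camera: CameraModel = field(default_factory=CameraModel)
    z_step: float = 200.0  # nm
    mean_photon_level: float | None = None
    clean: np.ndarray | None = None
    pixel_size: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.counts.ndim != 3:
            raise ValueError("stack must be 3D (z, y, x)")
        if not np.all(np.isfinite(self.counts)):
            raise ValueError("counts contain non-finite values")


# ---------------------------------------------------------------------------
# PSF construction
# ---------------------------------------------------------------------------


def make_gaussian_psf(
    sigma_lateral: float,
    sigma_axial: float | None = None,
    pixel_size: float | tuple[float, ...] = 50.0,
    support: int = 15,
    support_axial: int | None = None,
) -> PSFKernel:
    """Separable Gaussian PSF.

    Parameters
    ----------
    sigma_lateral : float
        Lateral standard deviation in nm. The diffraction-limited FWHM
        relates to it as FWHM = 2*sqrt(2*ln 2)*sigma.
    sigma_axial : float, optional
        Axial sigma in nm; when given, a 3D kernel is produced.
    pixel_size : float or tuple
        nm per pixel; a scalar is applied to all axes, a tuple is
        (z, y, x) for 3D or (y, x) for 2D.
    support : int
        Odd kernel side length (lateral axes).
    support_axial : int, optional
        Odd kernel depth for 3D (defaults to ``support``).
    """
    if sigma_lateral <= 0:
        raise ValueError("sigma_lateral must be > 0")
    if support % 2 == 0:
        raise ValueError("support must be odd")
    ndim = 2 if sigma_axial is None else 3
    if np.isscalar(pixel_size):
        px = (float(pixel_size),) * ndim
    else:
        px = tuple(float(p) for p in pixel_size)
        if len(px) != ndim:
            raise ValueError("pixel_size length does not match dimensionality")

    def axis_profile(sigma_nm: float, n: int, step_nm: float) -> np.ndarray:
        sigma_px = sigma_nm / step_nm
        if n < 6 * sigma_px:
            warnings.warn(
                f"support {n} px is smaller than 3 sigma on each side "
                f"(sigma = {sigma_px:.2f} px); PSF tails will be truncated",
                stacklevel=3,
            )
        x = np.arange(n) - (n - 1) / 2.0
        return np.exp(-0.5 * (x / sigma_px) ** 2)

    if ndim == 2:
        py, pxx = px
        k = np.outer(axis_profile(sigma_lateral, support, py),
                     axis_profile(sigma_lateral, support, pxx))
        spec = {"sigma_lateral_nm": sigma_lateral}
    else:
        nz = support_axial if support_axial is not None else support
        if nz % 2 == 0:
            raise ValueError("support_axial must be odd")
        pz, py, pxx = px
        k = (
            axis_profile(sigma_axial, nz, pz)[:, None, None]
            * axis_profile(sigma_lateral, support, py)[None, :, None]
            * axis_profile(sigma_lateral, support, pxx)[None, None, :]
        )
        spec = {"sigma_lateral_nm": sigma_lateral, "sigma_axial_nm": sigma_axial}
    return PSFKernel(kernel=k, pixel_size=px, parametric_spec=spec)


# ---------------------------------------------------------------------------
# phantoms
# ---------------------------------------------------------------------------


def _splat_points(img: np.ndarray, coords: np.ndarray, flux: np.ndarray) -> None:
    """Bilinear (2D) / trilinear (3D) sub-pixel splatting, mass-conserving."""
    ndim = img.ndim
    base = np.floor(coords).astype(int)
    frac = coords - base
    for corner in range(2**ndim):
        offs = np.array([(corner >> d) & 1 for d in range(ndim)])
        w = np.prod(np.where(offs, frac, 1.0 - frac), axis=1)
        idx = base + offs
        ok = np.all((idx >= 0) & (idx < np.array(img.shape)), axis=1)
        np.add.at(img, tuple(idx[ok].T), flux[ok] * w[ok])


def generate_puncta(
    shape: tuple[int, ...],
    n_points: int,
    intensity_range: tuple[float, float] = (0.5, 1.0),
    seed: int | None = None,
    min_separation: float = 5.0,
    pixel_size: float | tuple[float, ...] = 50.0,
) -> GroundTruthPhantom:
    """Isolated sub-pixel point emitters with rejection-sampled spacing.

    Points are drawn uniformly with a minimum pairwise separation so
    that each punctum forms its own connected component after blur-free
    thresholding; sub-pixel placement uses mass-conserving bilinear
    splatting.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if n_points > int(np.prod(shape)):
        raise ValueError("n_points exceeds pixel count")
    rng = np.random.default_rng(seed)
    ndim = len(shape)
    lo = 1.0
    hi = np.array(shape, dtype=float) - 2.0
    placed: list[np.ndarray] = []
    max_tries = 10000 * n_points
    tries = 0
    while len(placed) < n_points:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                "could not place points with the requested separation; "
                "reduce n_points or min_separation"
            )
        p = rng.uniform(lo, hi, size=ndim)
        if all(np.linalg.norm(p - q) >= min_separation for q in placed):
            placed.append(p)
    coords = np.array(placed)
    flux = rng.uniform(*intensity_range, size=n_points)
    img = np.zeros(shape, dtype=np.float64)
    _splat_points(img, coords, flux)
    if np.isscalar(pixel_size):
        pixel_size = (float(pixel_size),) * ndim
    return GroundTruthPhantom(pixels=img, pixel_size=tuple(pixel_size))


def render_curve(
    shape: tuple[int, int],
    points: np.ndarray,
    intensity: float = 1.0,
    step: float = 0.25,
) -> np.ndarray:
    """Rasterize a polyline with ~1 px cross-section.

    The polyline is resampled at ``step``-px spacing and each sample is
    bilinearly splatted with mass ``intensity * step`` so line density
    is uniform (one intensity unit per pixel of arclength).
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("points must be (n, ndim) with n >= 2")
    seg = np.diff(pts, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seglen)])
    total = arclen[-1]
    n_samples = max(2, int(np.ceil(total / step)))
    t = np.linspace(0.0, total, n_samples)
    coords = np.stack(
        [np.interp(t, arclen, pts[:, d]) for d in range(pts.shape[1])], axis=1
    )
    ds = total / (n_samples - 1)
    img = np.zeros(shape, dtype=np.float64)
    _splat_points(img, coords, np.full(n_samples, intensity * ds))
    return img


def generate_filaments(
    shape: tuple[int, int],
    n_curves: int,
    curvature_scale: float = 0.15,
    seed: int | None = None,
    intensity_range: tuple[float, float] = (0.7, 1.0),
    pixel_size: float | tuple[float, float] = 50.0,
) -> GroundTruthPhantom:
    """Smooth random tubular curves (microtubule-like) on a 2D canvas.

    Each curve is a persistent random walk: the heading angle performs
    a mean-reverting random walk whose step scale is ``curvature_scale``
    (radians per px of arclength); larger values give wigglier curves.
    """
    if n_curves < 1:
        raise ValueError("n_curves must be >= 1")
    if len(shape) != 2:
        raise ValueError("filament phantoms are 2D")
    rng = np.random.default_rng(seed)
    img = np.zeros(shape, dtype=np.float64)
    h, w = shape
    for _ in range(n_curves):
        pos = rng.uniform([2, 2], [h - 3, w - 3])
        theta = rng.uniform(0, 2 * np.pi)
        n_steps = int(0.9 * max(h, w))
        pts = [pos.copy()]
        for _ in range(n_steps):
            theta += curvature_scale * rng.standard_normal()
            pos = pos + np.array([np.sin(theta), np.cos(theta)])
            if not (1 <= pos[0] < h - 2 and 1 <= pos[1] < w - 2):
                break
            pts.append(pos.copy())
        if len(pts) < 2:
            continue
        img += render_curve(shape, np.array(pts), intensity=rng.uniform(*intensity_range))
    if np.isscalar(pixel_size):
        pixel_size = (float(pixel_size),) * 2
    return GroundTruthPhantom(pixels=img, pixel_size=tuple(pixel_size))


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def upsample_psf(psf: PSFKernel, factor: int) -> PSFKernel:
    """Resample a PSF kernel onto a ``factor``-times finer lateral grid.

    The deconvolution stage of a 2D model produces output on a
    super-resolved grid, so its forward model needs the PSF sampled at
    the output pixel size.  Parametric kernels are re-evaluated
    analytically; measured kernels are spline-interpolated, clipped at
    zero and renormalized.
    """
    if factor == 1:
        return psf
    new_px = tuple(
        p / factor if i >= psf.ndim - 2 else p for i, p in enumerate(psf.pixel_size)
    )
    if psf.parametric_spec is not None:
        spec = psf.parametric_spec
        support = psf.kernel.shape[-1] * factor + 1 - (psf.kernel.shape[-1] * factor) % 2
        return make_gaussian_psf(
            spec["sigma_lateral_nm"],
            spec.get("sigma_axial_nm"),
            pixel_size=new_px,
            support=support,
            support_axial=psf.kernel.shape[0] if psf.ndim == 3 else None,
        )
    from scipy.ndimage import map_coordinates

    # symmetric resampling grid so the peak stays exactly centered
    out_shape = tuple(
        (s * factor + 1 - (s * factor) % 2) if ax >= psf.ndim - 2 else s
        for ax, s in enumerate(psf.kernel.shape)
    )
    axes_coords = []
    for ax, (n_in, n_out) in enumerate(zip(psf.kernel.shape, out_shape)):
        step = 1.0 / factor if ax >= psf.ndim - 2 else 1.0
        axes_coords.append((n_in - 1) / 2.0 + (np.arange(n_out) - (n_out - 1) / 2.0) * step)
    mesh = np.meshgrid(*axes_coords, indexing="ij")
    k = map_coordinates(psf.kernel, np.array(mesh), order=3, mode="nearest")
    k = np.maximum(k, 0.0)
    return PSFKernel(kernel=k, pixel_size=new_px)


def blur(phantom: np.ndarray, psf: PSFKernel) -> np.ndarray:
    """Convolve a phantom with the PSF (reflective boundary)."""
    if psf.kernel.ndim != phantom.ndim:
        raise ValueError("PSF and phantom dimensionality differ")
    return _nd_convolve(phantom, psf.kernel, mode="reflect")


def render_noisy(
    phantom: GroundTruthPhantom,
    psf: PSFKernel,
    camera: CameraModel,
    mean_photons: float,
    seed: int | None = None,
):
    """Render a diffraction-limited noisy camera image of a phantom.

    The phantom is blurred with the PSF and globally rescaled so that
    the blurred signal averaged over the phantom's support (nonzero
    pixels) equals ``mean_photons``; counts are then drawn as
    ``gain * Poisson(lambda) + Normal(b, beta2)``.

    Returns a :class:`NoisyImage` (2D phantom) or :class:`NoisyStack`
    (3D phantom) with the pre-noise expected signal stored in ``clean``.
    """
    if mean_photons <= 0:
        raise ValueError("mean_photons must be > 0")
    rng = np.random.default_rng(seed)
    blurred = blur(phantom.pixels, psf)
    mask = phantom.pixels > 1e-12
    if not mask.any():
        raise ValueError("phantom is empty")
    scale = mean_photons / blurred[mask].mean()
    lam = scale * blurred
    counts = (
        camera.photon_gain * rng.poisson(lam).astype(np.float64)
        + camera.background_offset_b
        + np.sqrt(camera.gaussian_variance_beta2) * rng.standard_normal(lam.shape)
    )
    clean = camera.photon_gain * lam
    if phantom.pixels.ndim == 2:
        return NoisyImage(
            counts=counts,
            camera=camera,
            mean_photon_level=mean_photons,
            clean=clean,
            pixel_size=phantom.pixel_size,
        )
    return NoisyStack(
        counts=counts,
        camera=camera,
        z_step=phantom.pixel_size[0],
        mean_photon_level=mean_photons,
        clean=clean,
        pixel_size=phantom.pixel_size,
    )
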