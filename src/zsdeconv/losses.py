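"""Physics-informed training objectives.

The deconvolution stage is supervised by the optical forward model: its
output is convolved with the PSF, downsampled back to the camera grid,
and compared against the noise-independent target image.  A Hessian
penalty on second spatial derivatives regularizes the inverse problem.
The composite 2D loss is

    L = mu * ||f_den - ytilde||^2
        + (1 - mu) * ( ||(f_dec * PSF)_down - ytilde||^2
                       + lambda * R_Hessian(f_dec) ),

and the 3D loss replaces the recorrupted pair by odd/even slice pairs
and adds a gap-amending regularization (GAR) term that corrects the
systematic offset between adjacent planes using a full-stack denoised
reference treated as a constant.

All squared-error terms are pixel means so the default weights transfer
across patch sizes.  Every operator here exposes its exact adjoint,
which is what makes gradient-based training possible without an
autodiff framework (see :mod:`zsdeconv.nn`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .recorruption import RecorruptedPair
from .simulator import PSFKernel


@dataclass
class LossWeights:
    """mu balances denoising vs deconvolution; lambda_hessian weights the
    smoothness penalty (0.02 for 2D, 0.1 for 3D by default in the
    trainers); gamma_gar weights the 3D gap-amending term."""

    mu: float = 0.5
    lambda_hessian: float = 0.02
    gamma_gar: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must be in [0, 1]")
        if self.lambda_hessian < 0 or self.gamma_gar < 0:
            raise ValueError("weights must be >= 0")


# ---------------------------------------------------------------------------
# linear operators
# ---------------------------------------------------------------------------


def _reflect_index_map(shape: tuple[int, ...], pad: tuple[int, ...]) -> np.ndarray:
    """Flat source indices realizing reflective (symmetric) padding."""
    idx_axes = []
    for n, p in zip(shape, pad):
        i = np.arange(-p, n + p)
        # numpy 'symmetric' reflection: ... 1 0 | 0 1 ... n-1 | n-1 n-2 ...
        period = 2 * n
        i = np.mod(i, period)
        i = np.where(i >= n, period - 1 - i, i)
        idx_axes.append(i)
    mesh = np.meshgrid(*idx_axes, indexing="ij")
    return np.ravel_multi_index(mesh, shape)


def convolve_psf(img: np.ndarray, psf: PSFKernel, boundary: str = "reflect") -> np.ndarray:
    """Linear convolution with the PSF, output shape = input shape.

    ``boundary`` is one of 'reflect' (default; microscopy images are not
    periodic), 'periodic' or 'zero'.
    """
    img = np.asarray(img, dtype=np.float64)
    k = psf.kernel
    if k.ndim != img.ndim:
        raise ValueError("PSF and image dimensionality differ")
    if any(ks > s for ks, s in zip(k.shape, img.shape)):
        raise ValueError("PSF kernel is larger than the image")
    if boundary == "periodic":
        out = np.real(np.fft.ifftn(np.fft.fftn(img) * np.fft.fftn(_centered_embed(k, img.shape))))
        return out
    if boundary == "zero":
        return fftconvolve(img, k, mode="same")
    if boundary == "reflect":
        pad = tuple(s // 2 for s in k.shape)
        idx = _reflect_index_map(img.shape, pad)
        padded = img.ravel()[idx]
        full = fftconvolve(padded, k, mode="same")
        sl = tuple(slice(p, p + n) for p, n in zip(pad, img.shape))
        return full[sl]
    raise ValueError(f"unknown boundary mode {boundary!r}")


def _centered_embed(k: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Embed an odd-sized kernel into ``shape`` with its peak at index 0."""
    out = np.zeros(shape)
    sl = tuple(slice(0, s) for s in k.shape)
    out[sl] = k
    shifts = tuple(-(s // 2) for s in k.shape)
    return np.roll(out, shifts, axis=tuple(range(k.ndim)))


def downsample(img: np.ndarray, factor: int) -> np.ndarray:
    """Non-overlapping block average over the lateral (last two) axes.

    Models camera pixel integration.  Factor 1 is the identity; images
    whose lateral sizes are not divisible by the factor are edge-padded
    first.
    """
    img = np.asarray(img, dtype=np.float64)
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return img.copy()
    pads = [(0, 0)] * img.ndim
    for ax in (-2, -1):
        rem = img.shape[ax] % factor
        if rem:
            pads[ax] = (0, factor - rem)
    if any(p != (0, 0) for p in pads):
        img = np.pad(img, pads, mode="edge")
    h, w = img.shape[-2] // factor, img.shape[-1] // factor
    new_shape = img.shape[:-2] + (h, factor, w, factor)
    return img.reshape(new_shape).mean(axis=(-3, -1))


def _downsample_adjoint(v: np.ndarray, factor: int, out_shape: tuple[int, ...]) -> np.ndarray:
    if factor == 1:
        return v.copy()
    up = np.repeat(np.repeat(v, factor, axis=-2), factor, axis=-1) / (factor**2)
    sl = tuple(slice(0, s) for s in out_shape)
    return up[sl]


@dataclass
class ForwardModel:
    """The imaging operator A(x) = downsample(x * PSF) and its adjoint."""

    psf: PSFKernel
    downsample_factor: int = 2
    boundary: str = "reflect"

    def __post_init__(self) -> None:
        if self.downsample_factor < 1:
            raise ValueError("downsample factor must be >= 1")

    def apply(self, img: np.ndarray) -> np.ndarray:
        img = np.asarray(img, dtype=np.float64)
        f = self.downsample_factor
        if f > 1 and (img.shape[-2] % f or img.shape[-1] % f):
            raise ValueError(
                f"lateral shape {img.shape[-2:]} not divisible by factor {f}"
            )
        return downsample(convolve_psf(img, self.psf, self.boundary), f)

    def adjoint(self, v: np.ndarray, out_shape: tuple[int, ...]) -> np.ndarray:
        """Exact adjoint of :meth:`apply` for the configured boundary."""
        v = np.asarray(v, dtype=np.float64)
        u = _downsample_adjoint(v, self.downsample_factor, out_shape)
        k = self.psf.kernel
        kf = k[tuple(slice(None, None, -1) for _ in range(k.ndim))]
        if self.boundary == "zero":
            return fftconvolve(u, kf, mode="same")
        if self.boundary == "periodic":
            return np.real(
                np.fft.ifftn(np.fft.fftn(u) * np.conj(np.fft.fftn(_centered_embed(k, u.shape))))
            )
        # reflect: adjoint of (crop . conv . reflect-pad)
        pad = tuple(s // 2 for s in k.shape)
        padded_shape = tuple(n + 2 * p for n, p in zip(out_shape, pad))
        emb = np.zeros(padded_shape)
        sl = tuple(slice(p, p + n) for p, n in zip(pad, out_shape))
        emb[sl] = u
        corr = fftconvolve(emb, kf, mode="same")
        idx = _reflect_index_map(out_shape, pad)
        flat = np.zeros(int(np.prod(out_shape)))
        np.add.at(flat, idx.ravel(), corr.ravel())
        return flat.reshape(out_shape)


# ---------------------------------------------------------------------------
# Hessian regularization
# ---------------------------------------------------------------------------


def _hessian_value_grad(
    img: np.ndarray, axial_weight: float = 1.0, mixed_weight: float = 2.0
) -> tuple[float, np.ndarray]:
    x = np.asarray(img, dtype=np.float64)
    n = x.size
    grad = np.zeros_like(x)
    total = 0.0
    ndim = x.ndim
    axes = list(range(ndim))

    def axis_weight(ax: int) -> float:
        return axial_weight if (ndim == 3 and ax == 0) else 1.0

    for ax in axes:
        if x.shape[ax] < 3:
            continue
        sl = [slice(None)] * ndim

        def take(a, b):
            s = list(sl)
            s[ax] = slice(a, b)
            return tuple(s)

        r = x[take(None, -2)] - 2.0 * x[take(1, -1)] + x[take(2, None)]
        w = axis_weight(ax)
        total += w * float(np.sum(r * r))
        rr = (2.0 * w / n) * r
        grad[take(None, -2)] += rr
        grad[take(1, -1)] -= 2.0 * rr
        grad[take(2, None)] += rr
    for i in range(ndim):
        for j in range(i + 1, ndim):
            if x.shape[i] < 2 or x.shape[j] < 2:
                continue
            w = mixed_weight * axis_weight(i) * axis_weight(j)

            def take(ai, bi, aj, bj):
                s = [slice(None)] * ndim
                s[i] = slice(ai, bi)
                s[j] = slice(aj, bj)
                return tuple(s)

            r = (
                x[take(1, None, 1, None)]
                - x[take(1, None, None, -1)]
                - x[take(None, -1, 1, None)]
                + x[take(None, -1, None, -1)]
            )
            total += w * float(np.sum(r * r))
            rr = (2.0 * w / n) * r
            grad[take(1, None, 1, None)] += rr
            grad[take(1, None, None, -1)] -= rr
            grad[take(None, -1, 1, None)] -= rr
            grad[take(None, -1, None, -1)] += rr
    return total / n, grad


def hessian_reg(img: np.ndarray, axial_weight: float = 1.0) -> float:
    """Mean squared second-derivative penalty.

    Sum over pixels of (d2/dxx)^2 + (d2/dyy)^2 [+ (d2/dzz)^2] plus mixed
    second derivatives with weight 2, normalized by pixel count.  For 3D
    inputs ``axial_weight`` rescales every term involving the z axis.
    """
    img = np.asarray(img, dtype=np.float64)
    val, _ = _hessian_value_grad(img, axial_weight)
    return val


# ---------------------------------------------------------------------------
# composite losses
# ---------------------------------------------------------------------------


@dataclass
class LossResult:
    total: float
    components: dict
    grad_denoised: np.ndarray | None = None
    grad_deconvolved: np.ndarray | None = None


def _target_of(pair) -> np.ndarray:
    if isinstance(pair, RecorruptedPair):
        return pair.target_ytilde
    return np.asarray(pair, dtype=np.float64)


def loss2d(
    pair,
    denoised: np.ndarray,
    deconvolved: np.ndarray,
    fm: ForwardModel,
    w: LossWeights,
    with_grads: bool = False,
) -> LossResult:
    """Composite 2D objective on one recorrupted pair.

    ``denoised`` is the first-stage output on the recorrupted input
    (same grid as the target); ``deconvolved`` is the second-stage
    output on the super-resolved grid (lateral size = target size times
    the forward model's downsample factor).
    """
    ytilde = _target_of(pair)
    denoised = np.asarray(denoised, dtype=np.float64)
    deconvolved = np.asarray(deconvolved, dtype=np.float64)
    if denoised.shape != ytilde.shape:
        raise ValueError(
            f"denoised shape {denoised.shape} != target shape {ytilde.shape}"
        )
    f = fm.downsample_factor
    expect = ytilde.shape[:-2] + (ytilde.shape[-2] * f, ytilde.shape[-1] * f)
    if deconvolved.shape != expect:
        raise ValueError(
            f"deconvolved shape {deconvolved.shape} != expected {expect} "
            f"(target shape x downsample factor {f})"
        )
    n = ytilde.size
    r_den = denoised - ytilde
    l_den = float(np.mean(r_den**2))
    proj = fm.apply(deconvolved)
    r_dec = proj - ytilde
    l_fid = float(np.mean(r_dec**2))
    l_hess, g_hess = _hessian_value_grad(deconvolved)
    l_dec = l_fid + w.lambda_hessian * l_hess
    total = w.mu * l_den + (1.0 - w.mu) * l_dec
    comps = {
        "denoising": l_den,
        "deconvolution": l_fid,
        "hessian": l_hess,
        "total": total,
    }
    res = LossResult(total=total, components=comps)
    if with_grads:
        res.grad_denoised = (2.0 * w.mu / n) * r_den
        g = fm.adjoint((2.0 / n) * r_dec, deconvolved.shape)
        res.grad_deconvolved = (1.0 - w.mu) * (g + w.lambda_hessian * g_hess)
    return res


def loss3d(
    odd_denoised: np.ndarray,
    odd_deconvolved: np.ndarray,
    even: np.ndarray,
    gar_reference: np.ndarray | None,
    fm: ForwardModel,
    w: LossWeights,
    with_grads: bool = False,
) -> LossResult:
    """Composite 3D objective on one odd/even interleaved pair.

    ``odd_denoised`` / ``odd_deconvolved`` are the two stage outputs on
    the odd substack; ``even`` is the even substack target.
    ``gar_reference`` is the denoised full-depth stack used by the
    gap-amending regularization; it is treated as a constant (no
    gradient flows through it) and may be None when gamma_gar == 0.
    """
    odd_denoised = np.asarray(odd_denoised, dtype=np.float64)
    odd_deconvolved = np.asarray(odd_deconvolved, dtype=np.float64)
    even = np.asarray(even, dtype=np.float64)
    if odd_denoised.shape != even.shape:
        raise ValueError("denoised output and even target shapes differ")
    f = fm.downsample_factor
    expect = even.shape[:-2] + (even.shape[-2] * f, even.shape[-1] * f)
    if odd_deconvolved.shape != expect:
        raise ValueError(
            f"deconvolved shape {odd_deconvolved.shape} != expected {expect}"
        )
    gamma = w.gamma_gar
    if gamma > 0:
        if gar_reference is None:
            raise ValueError("gar_reference required when gamma_gar > 0")
        ref = np.asarray(gar_reference, dtype=np.float64)
        if ref.shape[0] < 2 * even.shape[0]:
            raise ValueError("gar_reference must cover odd and even planes")
        gap = ref[0::2][: even.shape[0]] - ref[1::2][: even.shape[0]]
    else:
        gap = np.zeros_like(even)
    n = even.size
    # denoising term
    d1 = odd_denoised - even
    l_n2n = float(np.mean(d1**2))
    l_gar_den = float(np.mean((d1 - gap) ** 2))
    l_den = l_n2n + gamma * l_gar_den
    # deconvolution term
    proj = fm.apply(odd_deconvolved)
    d2 = proj - even
    l_fid = float(np.mean(d2**2))
    l_gar_dec = float(np.mean((d2 - gap) ** 2))
    l_hess, g_hess = _hessian_value_grad(odd_deconvolved)
    l_dec = l_fid + gamma * l_gar_dec + w.lambda_hessian * l_hess
    total = w.mu * l_den + (1.0 - w.mu) * l_dec
    comps = {
        "denoising": l_n2n,
        "gar_den": l_gar_den,
        "deconvolution": l_fid,
        "gar_dec": l_gar_dec,
        "hessian": l_hess,
        "total": total,
    }
    res = LossResult(total=total, components=comps)
    if with_grads:
        res.grad_denoised = (2.0 * w.mu / n) * (d1 + gamma * (d1 - gap))
        back = (2.0 / n) * (d2 + gamma * (d2 - gap))
        g = fm.adjoint(back, odd_deconvolved.shape)
        res.grad_deconvolved = (1.0 - w.mu) * (g + w.lambda_hessian * g_hess)
    return res
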