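"""Padded/tiled prediction and display post-processing.

Inference pads the input (reflective lateral margin, blank z-slices for
stacks) to suppress deconvolution edge artifacts, runs the network over
overlapping tiles when the image exceeds the tile size, and blends
overlaps with linear feathering.  Fixed-pattern (stripe) noise of sCMOS
sensors, which self-supervised schemes cannot remove and deconvolution
enhances, is suppressed by a Fourier-domain apodization notch; display
scaling uses percentile normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class TilingSpec:
    """Tiled-inference geometry.

    ``tile_size`` of None processes the image in one pass.  The lateral
    margin (default 8 px) is both the reflective padding added around
    the image and the feathered overlap between tiles; stacks are
    additionally padded with blank z-slices (default 2).
    """

    tile_size: int | None = None
    lateral_margin: int = 8
    z_pad_slices: int = 2
    blend: str = "feather"

    def __post_init__(self) -> None:
        if self.lateral_margin < 0 or self.z_pad_slices < 0:
            raise ValueError("margins must be >= 0")


def _lateral_divisor(model) -> int:
    cfg = getattr(model, "config", {})
    if cfg.get("kind") == "dual_unet2d":
        return 2 ** cfg["depth"]
    return getattr(model, "lateral_divisor", 1)


def _forward_single(model, arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    s1, s2 = model.forward(arr[None, None])
    return s1[0, 0].astype(np.float64), s2[0, 0].astype(np.float64)


def _feather_weight(n: int, margin: int, at_start_edge: bool, at_end_edge: bool) -> np.ndarray:
    w = np.ones(n)
    if margin > 0:
        # zero weight at the tile border: border pixels carry boundary
        # artifacts and are fully covered by the neighboring tile
        ramp = np.arange(margin) / margin
        if not at_start_edge:
            w[:margin] = ramp
        if not at_end_edge:
            w[-margin:] = ramp[::-1]
    return w


def predict(model, image: np.ndarray, tiling: TilingSpec | None = None):
    """Run the dual-stage model over a full image or stack.

    The input is padded by the reflective lateral margin (and blank
    z-slices for 3D), extended to the lateral divisibility the backbone
    requires, processed in tiles if requested, and cropped back so the
    outputs align with the input grid (deconvolved output lateral size =
    input size x the model's upsample factor).

    Returns ``(denoised, deconvolved)``.
    """
    tiling = tiling or TilingSpec()
    arr = np.asarray(image, dtype=np.float64)
    nd = model.ndim
    if arr.ndim != nd:
        raise ValueError(f"model is {nd}D but input has {arr.ndim} dimensions")
    f = model.upsample_factor
    m = tiling.lateral_margin
    div = _lateral_divisor(model)

    # pad: blank z-slices + reflective lateral margin + divisibility tail
    h0, w0 = arr.shape[-2], arr.shape[-1]
    pad_h = (-(h0 + 2 * m)) % div
    pad_w = (-(w0 + 2 * m)) % div
    pads = [(0, 0)] * arr.ndim
    pads[-2] = (m, m + pad_h)
    pads[-1] = (m, m + pad_w)
    padded = np.pad(arr, pads, mode="reflect" if m or pad_h or pad_w else "edge")
    if nd == 3 and tiling.z_pad_slices:
        zp = tiling.z_pad_slices
        padded = np.pad(padded, ((zp, zp), (0, 0), (0, 0)), mode="constant")

    ph, pw = padded.shape[-2], padded.shape[-1]
    t = tiling.tile_size
    if t is None or (t >= ph and t >= pw):
        den_p, dec_p = _forward_single(model, padded)
    else:
        if t % div:
            raise ValueError(f"tile_size must be divisible by {div}")
        if t <= 2 * m:
            raise ValueError("tile smaller than twice the margin")
        stride = t - 2 * m
        den_p = np.zeros(padded.shape)
        dec_shape = padded.shape[:-2] + (ph * f, pw * f)
        dec_p = np.zeros(dec_shape)
        wsum = np.zeros((ph, pw))
        ys = list(range(0, max(ph - t, 0) + 1, stride))
        if ys[-1] + t < ph:
            ys.append(ph - t)
        xs = list(range(0, max(pw - t, 0) + 1, stride))
        if xs[-1] + t < pw:
            xs.append(pw - t)
        for y0 in ys:
            for x0 in xs:
                tile = padded[..., y0 : y0 + t, x0 : x0 + t]
                d1, d2 = _forward_single(model, tile)
                wy = _feather_weight(t, m, y0 == 0, y0 + t == ph)
                wx = _feather_weight(t, m, x0 == 0, x0 + t == pw)
                wmap = np.outer(wy, wx)
                den_p[..., y0 : y0 + t, x0 : x0 + t] += d1 * wmap
                wf = np.repeat(np.repeat(wmap, f, 0), f, 1)
                dec_p[..., y0 * f : (y0 + t) * f, x0 * f : (x0 + t) * f] += d2 * wf
                wsum[y0 : y0 + t, x0 : x0 + t] += wmap
        den_p /= wsum
        dec_p /= np.repeat(np.repeat(wsum, f, 0), f, 1)

    # crop all padding back off
    if nd == 3 and tiling.z_pad_slices:
        zp = tiling.z_pad_slices
        den_p = den_p[zp:-zp]
        dec_p = dec_p[zp:-zp]
    den = den_p[..., m : m + h0, m : m + w0]
    dec = dec_p[..., m * f : (m + h0) * f, m * f : (m + w0) * f]
    return den, dec


# ---------------------------------------------------------------------------
# fixed-pattern-noise apodization
# ---------------------------------------------------------------------------


def apodization_mask(
    shape: tuple[int, int],
    stripe_axis: int = 0,
    notch_width: float = 1.0,
    taper: float = 1.0,
) -> np.ndarray:
    """Fourier mask suppressing stripe energy.

    Stripes extending along ``stripe_axis`` concentrate their spectral
    energy in the plane where the frequency along that axis is zero; the
    mask attenuates a Gaussian-tapered band of half-width
    ``notch_width * taper`` frequency bins around that plane, excluding
    the DC bin so the image mean is preserved.  ``notch_width = 0``
    yields an all-pass mask.
    """
    ny, nx = shape
    mask = np.ones(shape)
    if notch_width <= 0:
        return mask
    # frequency index along the stripe axis
    n_s = shape[stripe_axis]
    k_s = np.fft.fftfreq(n_s) * n_s
    sigma = notch_width * taper
    band = 1.0 - np.exp(-0.5 * (k_s / sigma) ** 2)
    if stripe_axis == 0:
        mask = np.tile(band[:, None], (1, nx))
    else:
        mask = np.tile(band[None, :], (ny, 1))
    mask[0, 0] = 1.0  # DC preserved
    return mask


def apodize_fpn(
    img: np.ndarray,
    stripe_axis: int = 0,
    notch_width: float = 1.0,
    taper: float = 1.0,
) -> np.ndarray:
    """Suppress camera fixed-pattern stripes by spectral apodization.

    Applied per xy-slice for 3D inputs.  Linear in the image; applying
    it twice equals applying the squared mask once.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim == 3:
        return np.stack(
            [apodize_fpn(s, stripe_axis, notch_width, taper) for s in img]
        )
    if img.ndim != 2:
        raise ValueError("expected a 2D slice or 3D stack")
    mask = apodization_mask(img.shape, stripe_axis, notch_width, taper)
    return np.real(np.fft.ifft2(np.fft.fft2(img) * mask))


def percentile_normalize(
    img: np.ndarray,
    p_low: float = 3.0,
    p_high: float = 100.0,
    clip: bool = False,
) -> np.ndarray:
    """Percentile display normalization.

    Norm(Y) = (Y - percentile(Y, p_low)) / (percentile(Y, p_high) -
    percentile(Y, p_low)); percentiles use linear interpolation between
    order statistics.  Values below zero are kept unless ``clip`` is set.
    A constant image has no dynamic range and maps to zeros (warning).
    """
    if not p_low < p_high:
        raise ValueError("p_low must be < p_high")
    img = np.asarray(img, dtype=np.float64)
    lo = np.percentile(img, p_low)
    hi = np.percentile(img, p_high)
    if hi - lo <= 0:
        warnings.warn("constant image: percentile range is zero, returning zeros",
                      stacklevel=2)
        return np.zeros_like(img)
    out = (img - lo) / (hi - lo)
    if clip:
        out = np.clip(out, 0.0, None)
    return out
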