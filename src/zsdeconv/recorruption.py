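"""Recorrupted-pair generation for self-supervised 2D training.

From a single noisy image ``y`` two images with independent added noise
are produced,

    yhat   = y + alpha * g
    ytilde = y - g / alpha,      g ~ N(0, sigma^2 I),

with the pixelwise variance map

    sigma^2 = beta1 * max(H(y - b), 0) + beta2,

where ``H`` is a small averaging filter, ``b`` the camera background
offset, ``beta1`` the Poissonian (shot-noise) factor and ``beta2`` the
Gaussian read-noise variance.  Under a mixed Poisson-Gaussian camera
with unit gain the added components cancel the correlation between the
two total noise residuals exactly when ``beta1 = alpha = 1``, which
makes (yhat, ytilde) a valid noise2noise input/target pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter

from .simulator import CameraModel, NoisyImage


@dataclass
class RecorruptionParams:
    """Hyperparameters of the recorruption scheme.

    alpha scales the added noise split between the two images (D = alpha*I);
    beta1/beta2 parametrize the variance map; filter_size is the side of
    the averaging filter H; background_b is the camera offset.
    """

    alpha: float = 1.0
    beta1: float = 1.0
    beta2: float = 4.0
    filter_size: int = 5
    background_b: float = 100.0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0 (D = alpha*I must be invertible)")
        if self.beta1 < 0 or self.beta2 < 0:
            raise ValueError("beta1 and beta2 must be >= 0")
        if self.filter_size % 2 == 0 or self.filter_size < 1:
            raise ValueError("filter_size must be odd and >= 1")

    @classmethod
    def from_camera(cls, camera: CameraModel, **kw) -> "RecorruptionParams":
        return cls(
            beta2=camera.gaussian_variance_beta2,
            background_b=camera.background_offset_b,
            **kw,
        )


@dataclass
class RecorruptedPair:
    """The (input, target) pair; recombining them recovers y exactly:
    (yhat + alpha^2 * ytilde) / (1 + alpha^2) = y."""

    input_yhat: np.ndarray
    target_ytilde: np.ndarray
    alpha: float
    seed: int | None = None

    def recombine(self) -> np.ndarray:
        a2 = self.alpha**2
        return (self.input_yhat + a2 * self.target_ytilde) / (1.0 + a2)


def _counts(y) -> np.ndarray:
    if isinstance(y, NoisyImage):
        return y.counts
    return np.asarray(y, dtype=np.float64)


def sigma_map(y, params: RecorruptionParams) -> np.ndarray:
    """Pixelwise variance of the recorruption noise g.

    sigma^2 = beta1 * max(H(y - b), 0) + beta2, with H a
    ``filter_size`` averaging filter (reflective boundary).  Negative
    smoothed signal is clamped at zero so the variance stays valid.
    """
    arr = _counts(y)
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite values")
    smoothed = uniform_filter(
        arr - params.background_b, size=params.filter_size, mode="reflect"
    )
    return params.beta1 * np.maximum(smoothed, 0.0) + params.beta2


def recorrupt(
    y,
    params: RecorruptionParams,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> RecorruptedPair:
    """Draw g ~ N(0, sigma^2) pixelwise and form (yhat, ytilde)."""
    arr = _counts(y)
    var = sigma_map(arr, params)
    if rng is None:
        rng = np.random.default_rng(seed)
    g = np.sqrt(var) * rng.standard_normal(arr.shape)
    return RecorruptedPair(
        input_yhat=arr + params.alpha * g,
        target_ytilde=arr - g / params.alpha,
        alpha=params.alpha,
        seed=seed,
    )


def estimate_beta2(y, region) -> float:
    """Sample variance of counts in a signal-free region.

    ``region`` is a boolean mask or a ``(y0, y1, x0, x1)`` rectangle.
    Warns if the region mean sits far above its own noise floor,
    suggesting it overlaps real signal.
    """
    arr = _counts(y)
    if isinstance(region, tuple) and len(region) == 4:
        y0, y1, x0, x1 = region
        vals = arr[y0:y1, x0:x1].ravel()
    else:
        mask = np.asarray(region, dtype=bool)
        vals = arr[mask]
    if vals.size < 100:
        raise ValueError("region must contain at least 100 pixels")
    var = float(np.var(vals, ddof=1))
    if isinstance(y, NoisyImage):
        b = y.camera.background_offset_b
        if vals.mean() - b > 3.0 * np.sqrt(max(var, 1e-12)):
            warnings.warn(
                "region mean is far above the background offset; it may "
                "overlap signal-carrying pixels and overestimate beta2",
                stacklevel=2,
            )
    return var


@dataclass
class SweepResult:
    """Grid sweep of the Poissonian factor beta1.

    ``table`` maps each beta1 to the Pearson correlation between the
    total noise of yhat and of ytilde relative to the clean signal;
    ``best_beta1`` is the grid argmin of |correlation|.
    """

    table: list[dict] = field(default_factory=list)
    best_beta1: float = float("nan")
    n_pixels: int = 0
    ci_halfwidth: float = float("nan")
    reliable: bool = True


def independence_sweep(
    clean_signal: np.ndarray,
    camera: CameraModel,
    beta1_grid,
    alpha: float = 1.0,
    n_pixels: int | None = None,
    seed: int | None = None,
) -> SweepResult:
    """Monte-Carlo sweep locating the beta1 that decorrelates the pair.

    A noisy image is simulated from a known expected-photon map
    (``clean_signal``, photons per pixel) under the camera model; for
    each beta1 on the grid the image is recorrupted and the Pearson
    correlation between (yhat - clean) and (ytilde - clean) is measured,
    where clean = gain*clean_signal + b.  The theoretical optimum under
    unit gain is beta1 = 1.
    """
    grid = [float(b) for b in beta1_grid]
    if len(grid) == 0:
        raise ValueError("beta1 grid must be non-empty")
    clean_signal = np.asarray(clean_signal, dtype=np.float64)
    if n_pixels is not None and clean_signal.size < n_pixels:
        reps = int(np.ceil(n_pixels / clean_signal.size))
        clean_signal = np.tile(clean_signal, (reps, 1))
    rng = np.random.default_rng(seed)
    b = camera.background_offset_b
    gain = camera.photon_gain
    counts = (
        gain * rng.poisson(clean_signal).astype(np.float64)
        + b
        + np.sqrt(camera.gaussian_variance_beta2) * rng.standard_normal(clean_signal.shape)
    )
    clean_counts = gain * clean_signal + b
    n = counts.size
    result = SweepResult(n_pixels=n)
    # Fisher-z 95% half-width for a correlation near zero
    result.ci_halfwidth = 1.96 / np.sqrt(max(n - 3, 1))
    result.reliable = result.ci_halfwidth < 0.02
    if not result.reliable:
        warnings.warn(
            f"correlation confidence interval +/-{result.ci_halfwidth:.3f} is "
            "wide at this pixel count; the argmin may be unreliable",
            stacklevel=2,
        )
    best = None
    for b1 in grid:
        params = RecorruptionParams(
            alpha=alpha,
            beta1=b1,
            beta2=camera.gaussian_variance_beta2,
            background_b=b,
        )
        pair = recorrupt(counts, params, rng=rng)
        r_hat = (pair.input_yhat - clean_counts).ravel()
        r_tilde = (pair.target_ytilde - clean_counts).ravel()
        corr = float(np.corrcoef(r_hat, r_tilde)[0, 1])
        result.table.append({"beta1": b1, "correlation": corr})
        if best is None or abs(corr) < best[0]:
            best = (abs(corr), b1)
    result.best_beta1 = best[1]
    return result
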