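"""TIFF input/output and run configuration.

Arrays follow the (z, y, x) axis convention with z slowest; single-page
files read as depth-1 stacks.  Configuration is a schema-validated
nested block structure that round-trips losslessly through YAML.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
import yaml
from pydantic import BaseModel, ConfigDict

from .simulator import CameraModel, NoisyImage, NoisyStack

_SUPPORTED = {"uint8", "uint16", "int16", "uint32", "float32", "float64"}


def read_stack(path, camera: CameraModel | None = None) -> NoisyStack:
    """Read a single- or multi-page TIFF as a (z, y, x) stack of floats.

    Integer inputs convert losslessly; single-page files come back with
    z-dimension 1.
    """
    arr = tifffile.imread(str(path))
    if str(arr.dtype) not in _SUPPORTED:
        raise ValueError(
            f"unsupported TIFF sample format {arr.dtype!r}; supported: "
            + ", ".join(sorted(_SUPPORTED))
        )
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"expected 2D or 3D TIFF, got {arr.ndim}D")
    return NoisyStack(counts=arr, camera=camera or CameraModel())


def read_image(path, camera: CameraModel | None = None) -> NoisyImage:
    """Read a single-plane TIFF as a 2D image (errors on true stacks)."""
    stack = read_stack(path, camera)
    if stack.counts.shape[0] != 1:
        raise ValueError("file contains multiple slices; use read_stack")
    return NoisyImage(counts=stack.counts[0], camera=stack.camera)


def write_stack(array, path, dtype: str = "float32", allow_nan: bool = False) -> None:
    """Write an array as TIFF (float32 default)."""
    arr = np.asarray(array)
    if not allow_nan and not np.all(np.isfinite(arr)):
        raise ValueError("array contains non-finite values (pass allow_nan=True to force)")
    if dtype not in _SUPPORTED:
        raise ValueError(f"unsupported output dtype {dtype!r}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(str(path), arr.astype(dtype))


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateConfig(_Block):
    structure: str = "filaments"
    shape: list[int] = [128, 128]
    n_objects: int = 8
    mean_photons: float = 15.0
    seed: int = 0


class CameraConfig(_Block):
    offset: float = 100.0
    beta2: float = 4.0
    gain: float = 1.0


class RecorruptionConfig(_Block):
    alpha: float = 1.0
    beta1: float = 1.0
    beta2: float | None = None
    offset: float | None = None
    filter_size: int = 5


class ModelBlock(_Block):
    dim: int = 2
    depth: int = 2
    base_channels: int = 16
    residual_groups: int = 1
    attention_blocks: int = 2
    upsample_factor: int = 2


class TrainBlock(_Block):
    iterations: int = 3000
    batch_size: int = 4
    patch_size: int = 64
    patch_depth: int = 8
    n_patches: int = 2000
    initial_lr: float = 0.5e-4
    lr_decay: float = 0.5
    lr_decay_every: int = 10000
    mu: float = 0.5
    lambda_hessian: float = 0.02
    gamma_gar: float = 1.0
    seed: int = 0


class TilingBlock(_Block):
    tile_size: int | None = None
    lateral_margin: int = 8
    z_pad_slices: int = 2


class EvaluateBlock(_Block):
    metrics: list[str] = ["psnr"]
    feature_threshold: float = 0.02
    frc_criterion: float = 1.0 / 7.0


class RunConfig(_Block):
    """Nested, schema-validated configuration; unknown keys are rejected."""

    simulate: SimulateConfig = SimulateConfig()
    camera: CameraConfig = CameraConfig()
    recorruption: RecorruptionConfig = RecorruptionConfig()
    model: ModelBlock = ModelBlock()
    train: TrainBlock = TrainBlock()
    tiling: TilingBlock = TilingBlock()
    evaluate: EvaluateBlock = EvaluateBlock()

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})
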