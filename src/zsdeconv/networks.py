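"""Backbone construction and single-image forward passes.

The dual-stage contract: a model maps one input image/stack to a
(denoised, deconvolved) pair, where the denoised output shares the input
grid and the deconvolved output is laterally upsampled by the model's
``upsample_factor``.  Any object honoring this contract (``ndim``,
``upsample_factor``, ``forward`` on a (N, 1, ...) batch) can be trained
by the loss modules and run through tiled inference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import DualStageRCAN3D, DualStageUNet2D


@dataclass
class ModelConfig:
    """Backbone hyperparameters.

    depth: number of down/up-sampling levels in each U-Net stage
    (full-scale preset uses 4; the reduced desk preset 2).
    residual_groups/attention_blocks size the 3D RCAN stages.
    upsample_factor: lateral super-resolution factor of the deconvolved
    output (2 in 2D; 1 in 3D where the gain comes from deconvolution).
    """

    depth: int = 2
    base_channels: int = 16
    residual_groups: int = 1
    attention_blocks: int = 2
    upsample_factor: int = 2
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("depth", "base_channels", "residual_groups", "attention_blocks",
                     "upsample_factor"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")


#: full-scale configurations (GPU-scale workloads; the tests use the reduced desk preset)
FULL_SCALE_PRESET_2D = ModelConfig(depth=4, base_channels=32, upsample_factor=2)
FULL_SCALE_PRESET_3D = ModelConfig(depth=1, base_channels=32, residual_groups=2,
                              attention_blocks=2, upsample_factor=1)


def build_dual_unet2d(cfg: ModelConfig | None = None) -> DualStageUNet2D:
    """Dual-stage simplified U-Net for 2D images."""
    cfg = cfg or ModelConfig()
    return DualStageUNet2D(
        depth=cfg.depth,
        base_channels=cfg.base_channels,
        upsample_factor=cfg.upsample_factor,
        seed=cfg.seed,
    )


def build_dual_rcan3d(cfg: ModelConfig | None = None) -> DualStageRCAN3D:
    """Dual-stage channel-attention residual network for 3D stacks."""
    cfg = cfg or ModelConfig(upsample_factor=1)
    if cfg.upsample_factor != 1:
        raise ValueError("the 3D backbone keeps the input grid (upsample_factor 1)")
    return DualStageRCAN3D(
        base_channels=cfg.base_channels,
        residual_groups=cfg.residual_groups,
        attention_blocks=cfg.attention_blocks,
        seed=cfg.seed,
    )


def forward(model, image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Single-image forward pass -> (denoised, deconvolved).

    Deterministic given the weights; raises on non-finite outputs.
    """
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != model.ndim:
        raise ValueError(f"model is {model.ndim}D but input is {arr.ndim}D")
    s1, s2 = model.forward(arr[None, None])
    return s1[0, 0].astype(np.float64), s2[0, 0].astype(np.float64)
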