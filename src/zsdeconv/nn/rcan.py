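"""Dual-stage 3D residual channel-attention network (RCAN-style).

Each stage is a shallow RCAN: an input convolution, residual groups of
channel-attention blocks, an output convolution with a global skip, and
a linear single-channel head.  Channel attention rescales feature maps
by a per-channel gate computed from globally pooled statistics; gates
are initialized neutral (0.5) and can be disabled to recover a plain
residual network.  Both stage outputs stay on the input grid: the 3D
resolution gain comes from deconvolution, not from a grid change.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .layers import Conv3d, LeakyReLU, Param


class ChannelAttention3d:
    """Squeeze-and-excitation gate: sigmoid MLP on globally pooled channels.

    The second dense layer is zero-initialized so freshly built models
    gate every channel uniformly at 0.5.
    """

    def __init__(self, channels: int, reduction: int = 4, rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng()
        hidden = max(channels // reduction, 1)
        self.w1 = Param(
            (rng.standard_normal((hidden, channels)) * np.sqrt(2.0 / channels)).astype(dtype)
        )
        self.b1 = Param(np.zeros(hidden, dtype=dtype))
        self.w2 = Param(np.zeros((channels, hidden), dtype=dtype))
        self.b2 = Param(np.zeros(channels, dtype=dtype))

    def params(self):
        return [self.w1, self.b1, self.w2, self.b2]

    def gate(self, x: np.ndarray) -> np.ndarray:
        gap = x.mean(axis=(2, 3, 4))
        z1 = gap @ self.w1.value.T + self.b1.value
        a1 = np.maximum(z1, 0.0)
        z2 = a1 @ self.w2.value.T + self.b2.value
        return 1.0 / (1.0 + np.exp(-z2))

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        gap = x.mean(axis=(2, 3, 4))
        z1 = gap @ self.w1.value.T + self.b1.value
        a1 = np.maximum(z1, 0.0)
        z2 = a1 @ self.w2.value.T + self.b2.value
        s = 1.0 / (1.0 + np.exp(-z2))
        self._cache = (gap, z1, a1, s)
        return x * s[:, :, None, None, None]

    def backward(self, g: np.ndarray) -> np.ndarray:
        x = self._x
        gap, z1, a1, s = self._cache
        ds = np.einsum("ncdhw,ncdhw->nc", g, x)
        dx = g * s[:, :, None, None, None]
        dz2 = ds * s * (1.0 - s)
        self.w2.grad += dz2.T @ a1
        self.b2.grad += dz2.sum(axis=0)
        da1 = dz2 @ self.w2.value
        dz1 = da1 * (z1 > 0)
        self.w1.grad += dz1.T @ gap
        self.b1.grad += dz1.sum(axis=0)
        dgap = dz1 @ self.w1.value
        spatial = x.shape[2] * x.shape[3] * x.shape[4]
        dx += dgap[:, :, None, None, None] / spatial
        return dx


class CAB:
    """Channel-attention block: conv-LReLU-conv -> gate -> residual add."""

    def __init__(self, channels: int, rng=None, dtype=np.float32, use_attention=True):
        self.conv1 = Conv3d(channels, channels, 3, rng, dtype)
        self.act = LeakyReLU(0.1)
        self.conv2 = Conv3d(channels, channels, 3, rng, dtype)
        self.ca = ChannelAttention3d(channels, rng=rng, dtype=dtype)
        self.use_attention = use_attention

    def params(self):
        p = self.conv1.params() + self.conv2.params()
        if self.use_attention:
            p += self.ca.params()
        return p

    def forward(self, x):
        h = self.conv2.forward(self.act.forward(self.conv1.forward(x)))
        if self.use_attention:
            h = self.ca.forward(h)
        return x + h

    def backward(self, g):
        h = g
        if self.use_attention:
            h = self.ca.backward(h)
        h = self.conv1.backward(self.act.backward(self.conv2.backward(h)))
        return g + h


class ResidualGroup:
    def __init__(self, channels, n_blocks, rng=None, dtype=np.float32, use_attention=True):
        self.blocks = [CAB(channels, rng, dtype, use_attention) for _ in range(n_blocks)]
        self.conv = Conv3d(channels, channels, 3, rng, dtype)

    def params(self):
        out = []
        for b in self.blocks:
            out.extend(b.params())
        out.extend(self.conv.params())
        return out

    def forward(self, x):
        h = x
        for b in self.blocks:
            h = b.forward(h)
        return x + self.conv.forward(h)

    def backward(self, g):
        h = self.conv.backward(g)
        for b in reversed(self.blocks):
            h = b.backward(h)
        return g + h


class RCAN3d:
    def __init__(
        self,
        channels=8,
        residual_groups=1,
        attention_blocks=2,
        rng=None,
        dtype=np.float32,
        use_attention=True,
    ):
        self.conv_in = Conv3d(1, channels, 3, rng, dtype)
        self.groups = [
            ResidualGroup(channels, attention_blocks, rng, dtype, use_attention)
            for _ in range(residual_groups)
        ]
        self.conv_out = Conv3d(channels, channels, 3, rng, dtype)
        # zero-init head: the stage starts as the identity mapping, keeping
        # the nonnegative (ReLU) output from dying at low signal levels
        self.head = Conv3d(channels, 1, 3, rng, dtype)
        self.head.w.value[...] = 0.0

    def params(self):
        out = self.conv_in.params()
        for grp in self.groups:
            out.extend(grp.params())
        out.extend(self.conv_out.params())
        out.extend(self.head.params())
        return out

    def forward(self, x):
        h0 = self.conv_in.forward(x)
        h = h0
        for grp in self.groups:
            h = grp.forward(h)
        h = h0 + self.conv_out.forward(h)
        return self.head.forward(h)

    def backward(self, g):
        g = self.head.backward(g)
        gh = self.conv_out.backward(g)
        for grp in reversed(self.groups):
            gh = grp.backward(gh)
        return self.conv_in.backward(g + gh)


class DualStageRCAN3D:
    """Dual (denoised, deconvolved) 3D model; both outputs on the input grid."""

    def __init__(
        self,
        base_channels: int = 8,
        residual_groups: int = 1,
        attention_blocks: int = 2,
        seed: int | None = None,
        dtype=np.float32,
        use_attention: bool = True,
    ):
        rng = np.random.default_rng(seed)
        self.config = {
            "kind": "dual_rcan3d",
            "base_channels": base_channels,
            "residual_groups": residual_groups,
            "attention_blocks": attention_blocks,
            "use_attention": use_attention,
        }
        self.dtype = dtype
        self.upsample_factor = 1
        self.stage1 = RCAN3d(base_channels, residual_groups, attention_blocks, rng, dtype, use_attention)
        self.stage2 = RCAN3d(base_channels, residual_groups, attention_blocks, rng, dtype, use_attention)

    @property
    def ndim(self) -> int:
        return 3

    def params(self) -> list[Param]:
        return self.stage1.params() + self.stage2.params()

    def n_params(self) -> int:
        return sum(p.value.size for p in self.params())

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """x: (N, 1, D, H, W) -> (denoised, deconvolved), same shapes."""
        x = x.astype(self.dtype, copy=False)
        h1 = self.stage1.forward(x)
        s1_pre = x + h1
        s1 = np.maximum(s1_pre, 0.0)
        self._m1 = s1_pre > 0
        h2 = self.stage2.forward(s1)
        s2_pre = s1 + h2
        s2 = np.maximum(s2_pre, 0.0)
        self._m2 = s2_pre > 0
        if not (np.all(np.isfinite(s1)) and np.all(np.isfinite(s2))):
            raise FloatingPointError("non-finite values in network outputs")
        return s1, s2

    def denoise_forward(self, x: np.ndarray) -> np.ndarray:
        """Stage-1 only forward (used for the constant GAR reference).

        Overwrites stage-1 caches; call it before any forward pass whose
        gradients are still needed.
        """
        x = x.astype(self.dtype, copy=False)
        return np.maximum(x + self.stage1.forward(x), 0.0)

    def backward(self, g_denoised: np.ndarray, g_deconvolved: np.ndarray) -> np.ndarray:
        g2 = (g_deconvolved * self._m2).astype(self.dtype)
        g_s1 = self.stage2.backward(g2) + g2 + g_denoised.astype(self.dtype)
        g1 = (g_s1 * self._m1).astype(self.dtype)
        return self.stage1.backward(g1) + g1

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.value for i, p in enumerate(self.params())}

    def save(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez(path.with_suffix(".npz"), **self.state_arrays())
        path.with_suffix(".json").write_text(json.dumps(self.config, indent=1))

    def load_state(self, arrays: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            val = arrays[f"p{i}"]
            if val.shape != p.value.shape:
                raise ValueError("checkpoint/model shape mismatch")
            p.value = val.astype(self.dtype)

    @classmethod
    def load(cls, path) -> "DualStageRCAN3D":
        path = Path(path)
        cfg = json.loads(path.with_suffix(".json").read_text())
        if cfg.pop("kind") != "dual_rcan3d":
            raise ValueError("checkpoint is not a dual 3D RCAN")
        model = cls(**cfg)
        with np.load(path.with_suffix(".npz")) as data:
            model.load_state(dict(data))
        return model

    def copy(self) -> "DualStageRCAN3D":
        cfg = {k: v for k, v in self.config.items() if k != "kind"}
        clone = DualStageRCAN3D(**cfg, dtype=self.dtype)
        for pc, ps in zip(clone.params(), self.params()):
            pc.value = ps.value.copy()
        return clone
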