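"""Dual-stage 2D U-Net: a denoiser followed by a deconvolver.

Stage 1 maps the noisy input to a denoised image on the same grid
(global residual connection, ReLU output so intensities stay
nonnegative).  Stage 2 consumes stage 1's output and produces the
deconvolved image, optionally on a laterally upsampled (super-resolved)
grid; its residual reference is the nearest-upsampled denoised image.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .layers import (
    AvgPool2d,
    Conv2d,
    LeakyReLU,
    Param,
    Sequential,
    upsample_nearest,
    upsample_nearest_adjoint,
)


def _conv_block(cin, cout, rng, dtype):
    return Sequential(
        Conv2d(cin, cout, 3, rng, dtype),
        LeakyReLU(0.1),
        Conv2d(cout, cout, 3, rng, dtype),
        LeakyReLU(0.1),
    )


class UNet2d:
    """Encoder-decoder with skip connections; linear single-channel head."""

    def __init__(
        self,
        cin: int = 1,
        depth: int = 2,
        base_channels: int = 16,
        out_upsample: int = 1,
        rng=None,
        dtype=np.float32,
    ):
        rng = rng or np.random.default_rng()
        self.depth = depth
        self.out_upsample = out_upsample
        ch = [base_channels * 2**i for i in range(depth + 1)]
        self.enc = []
        prev = cin
        for i in range(depth):
            self.enc.append(_conv_block(prev, ch[i], rng, dtype))
            prev = ch[i]
        self.pools = [AvgPool2d() for _ in range(depth)]
        self.bottleneck = _conv_block(prev, ch[depth], rng, dtype)
        self.reduce = []
        self.dec = []
        for i in reversed(range(depth)):
            self.reduce.append(Conv2d(ch[i + 1], ch[i], 3, rng, dtype))
            self.dec.append(_conv_block(2 * ch[i], ch[i], rng, dtype))
        if out_upsample > 1:
            self.post = Sequential(
                Conv2d(ch[0], ch[0], 3, rng, dtype), LeakyReLU(0.1)
            )
        else:
            self.post = None
        # zero-init head: the stage starts as the identity (via the global
        # residual), which keeps the ReLU output alive early in training
        self.head = Conv2d(ch[0], 1, 3, rng, dtype)
        self.head.w.value[...] = 0.0

    def params(self) -> list[Param]:
        out = []
        for blk in self.enc:
            out.extend(blk.params())
        out.extend(self.bottleneck.params())
        for r, d in zip(self.reduce, self.dec):
            out.extend(r.params())
            out.extend(d.params())
        if self.post is not None:
            out.extend(self.post.params())
        out.extend(self.head.params())
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        div = 2**self.depth
        if x.shape[-2] % div or x.shape[-1] % div:
            raise ValueError(
                f"lateral size {x.shape[-2:]} must be divisible by 2^depth = {div}; "
                "pad the input (reflective padding is typical) before the forward pass"
            )
        skips = []
        h = x
        for blk, pool in zip(self.enc, self.pools):
            h = blk.forward(h)
            skips.append(h)
            h = pool.forward(h)
        h = self.bottleneck.forward(h)
        self._skip_ch = []
        for r, d, skip in zip(self.reduce, self.dec, reversed(skips)):
            h = upsample_nearest(h, 2)
            h = r.forward(h)
            self._skip_ch.append(h.shape[1])
            h = np.concatenate([h, skip], axis=1)
            h = d.forward(h)
        if self.post is not None:
            h = upsample_nearest(h, self.out_upsample)
            h = self.post.forward(h)
        return self.head.forward(h)

    def backward(self, g: np.ndarray) -> np.ndarray:
        g = self.head.backward(g)
        if self.post is not None:
            g = self.post.backward(g)
            g = upsample_nearest_adjoint(g, self.out_upsample)
        skip_grads = []
        for r, d, ch in zip(
            reversed(self.reduce), reversed(self.dec), reversed(self._skip_ch)
        ):
            g = d.backward(g)
            skip_grads.append(g[:, ch:])
            g = r.backward(np.ascontiguousarray(g[:, :ch]))
            g = upsample_nearest_adjoint(g, 2)
        g = self.bottleneck.backward(g)
        # skip_grads were collected from the highest-resolution decoder first
        for blk, pool, gs in zip(
            reversed(self.enc), reversed(self.pools), reversed(skip_grads)
        ):
            g = pool.backward(g)
            g = blk.backward(np.ascontiguousarray(g) + gs)
        return g


class DualStageUNet2D:
    """Two sequentially connected U-Nets with dual (denoised, deconvolved)
    outputs.  ``upsample_factor`` > 1 puts the deconvolved output on a
    super-resolved lateral grid."""

    def __init__(
        self,
        depth: int = 2,
        base_channels: int = 16,
        upsample_factor: int = 2,
        seed: int | None = None,
        dtype=np.float32,
    ):
        rng = np.random.default_rng(seed)
        self.config = {
            "kind": "dual_unet2d",
            "depth": depth,
            "base_channels": base_channels,
            "upsample_factor": upsample_factor,
        }
        self.dtype = dtype
        self.upsample_factor = upsample_factor
        self.stage1 = UNet2d(1, depth, base_channels, 1, rng, dtype)
        self.stage2 = UNet2d(1, depth, base_channels, upsample_factor, rng, dtype)

    # -- api ---------------------------------------------------------------
    @property
    def ndim(self) -> int:
        return 2

    def params(self) -> list[Param]:
        return self.stage1.params() + self.stage2.params()

    def n_params(self) -> int:
        return sum(p.value.size for p in self.params())

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """x: (N, 1, H, W) -> (denoised (N,1,H,W), deconvolved (N,1,fH,fW))."""
        x = x.astype(self.dtype, copy=False)
        h1 = self.stage1.forward(x)
        s1_pre = x + h1
        s1 = np.maximum(s1_pre, 0.0)
        self._m1 = s1_pre > 0
        h2 = self.stage2.forward(s1)
        up = upsample_nearest(s1, self.upsample_factor)
        s2_pre = up + h2
        s2 = np.maximum(s2_pre, 0.0)
        self._m2 = s2_pre > 0
        if not (np.all(np.isfinite(s1)) and np.all(np.isfinite(s2))):
            raise FloatingPointError("non-finite values in network outputs")
        return s1, s2

    def backward(self, g_denoised: np.ndarray, g_deconvolved: np.ndarray) -> np.ndarray:
        """Accumulate parameter grads given output grads; returns input grad."""
        g2 = (g_deconvolved * self._m2).astype(self.dtype)
        g_s1 = self.stage2.backward(g2)
        g_s1 = g_s1 + upsample_nearest_adjoint(g2, self.upsample_factor)
        g_s1 = g_s1 + g_denoised.astype(self.dtype)
        g1 = (g_s1 * self._m1).astype(self.dtype)
        gx = self.stage1.backward(g1)
        return gx + g1

    # -- persistence ---------------------------------------------------------
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
    def load(cls, path) -> "DualStageUNet2D":
        path = Path(path)
        cfg = json.loads(path.with_suffix(".json").read_text())
        if cfg.pop("kind") != "dual_unet2d":
            raise ValueError("checkpoint is not a dual 2D U-Net")
        model = cls(**cfg)
        with np.load(path.with_suffix(".npz")) as data:
            model.load_state(dict(data))
        return model

    def copy(self) -> "DualStageUNet2D":
        clone = DualStageUNet2D(
            self.config["depth"],
            self.config["base_channels"],
            self.config["upsample_factor"],
            dtype=self.dtype,
        )
        for pc, ps in zip(clone.params(), self.params()):
            pc.value = ps.value.copy()
        return clone
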