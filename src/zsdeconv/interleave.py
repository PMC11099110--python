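"""Spatially interleaved pair construction for 3D stacks and joint
patch augmentation for 2D and 3D training.

A noisy z-stack is split into its odd and even slices (1-based slice
numbering, so "odd" starts with the first slice); the two substacks are
noise-independent renderings of nearly the same specimen planes and
serve as input/target pairs.  Patch augmentation applies identical
random crop / flip / 90-degree rotation transforms to both members of a
pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .simulator import NoisyStack


def _stack_counts(stack) -> np.ndarray:
    if isinstance(stack, NoisyStack):
        return stack.counts
    arr = np.asarray(stack, dtype=np.float64)
    if arr.ndim != 3:
        raise ValueError("stack must be 3D (z, y, x)")
    return arr


def split_odd_even(stack) -> tuple[np.ndarray, np.ndarray]:
    """Split a stack into odd and even slices (1-based numbering).

    Odd slices are zero-based indices 0, 2, 4, ...; even slices are
    1, 3, 5, ....  With an odd number of slices the last unmatched
    slice is dropped with a warning so both substacks stay equal-depth.
    """
    arr = _stack_counts(stack)
    nz = arr.shape[0]
    if nz < 4:
        raise ValueError("stack needs >= 4 z-slices for odd/even splitting")
    if nz % 2 == 1:
        warnings.warn(
            f"stack has an odd number of slices ({nz}); dropping the last one",
            stacklevel=2,
        )
        arr = arr[: nz - 1]
    return arr[0::2].copy(), arr[1::2].copy()


def interleave(odd: np.ndarray, even: np.ndarray) -> np.ndarray:
    """Inverse of :func:`split_odd_even` (up to any dropped tail slice)."""
    odd = np.asarray(odd)
    even = np.asarray(even)
    if odd.shape != even.shape:
        raise ValueError("odd and even substacks must have equal shapes")
    out = np.empty((2 * odd.shape[0],) + odd.shape[1:], dtype=odd.dtype)
    out[0::2] = odd
    out[1::2] = even
    return out


@dataclass
class AugmentationRecord:
    source_index: int
    origin: tuple[int, ...]
    flip_y: bool
    flip_x: bool
    rot90: int  # in-plane quarter turns


@dataclass
class TrainingPatchSet:
    """Augmented (input, target) patch pairs plus the transform log."""

    inputs: list[np.ndarray] = field(default_factory=list)
    targets: list[np.ndarray] = field(default_factory=list)
    log: list[AugmentationRecord] = field(default_factory=list)
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.inputs)


def _apply_geom(patch: np.ndarray, rec: AugmentationRecord) -> np.ndarray:
    # lateral axes are always the last two, for 2D and 3D alike
    if rec.flip_y:
        patch = np.flip(patch, axis=-2)
    if rec.flip_x:
        patch = np.flip(patch, axis=-1)
    if rec.rot90:
        patch = np.rot90(patch, k=rec.rot90, axes=(-2, -1))
    return np.ascontiguousarray(patch)


def augment_patches(
    pairs: list[tuple[np.ndarray, np.ndarray]],
    patch_shape: tuple[int, ...],
    n_patches: int,
    seed: int | None = None,
    transforms: bool = True,
) -> TrainingPatchSet:
    """Random crop + flip + 90-degree-rotation augmentation.

    The same geometric transform is applied to the input and the target
    of each pair; rotations are restricted to in-plane quarter turns so
    no interpolation is involved.  With ``transforms=False`` patches are
    verbatim crops.  Rotation by odd quarter turns is only drawn when
    the lateral patch is square.
    """
    if n_patches < 0:
        raise ValueError("n_patches must be >= 0")
    rng = np.random.default_rng(seed)
    out = TrainingPatchSet(seed=seed)
    if n_patches == 0:
        return out
    norm_pairs = []
    for inp, tgt in pairs:
        inp = np.asarray(inp, dtype=np.float64)
        tgt = np.asarray(tgt, dtype=np.float64)
        if inp.shape != tgt.shape:
            raise ValueError("input/target shapes differ within a pair")
        if inp.ndim != len(patch_shape):
            raise ValueError("patch_shape dimensionality does not match data")
        if any(s < p for s, p in zip(inp.shape, patch_shape)):
            raise ValueError(
                f"patch {patch_shape} larger than source {inp.shape}"
            )
        norm_pairs.append((inp, tgt))
    square = patch_shape[-1] == patch_shape[-2]
    for _ in range(n_patches):
        si = int(rng.integers(len(norm_pairs)))
        inp, tgt = norm_pairs[si]
        origin = tuple(
            int(rng.integers(0, s - p + 1)) for s, p in zip(inp.shape, patch_shape)
        )
        sl = tuple(slice(o, o + p) for o, p in zip(origin, patch_shape))
        if transforms:
            rec = AugmentationRecord(
                source_index=si,
                origin=origin,
                flip_y=bool(rng.integers(2)),
                flip_x=bool(rng.integers(2)),
                rot90=int(rng.integers(4)) if square else int(rng.integers(2)) * 2,
            )
        else:
            rec = AugmentationRecord(si, origin, False, False, 0)
        out.inputs.append(_apply_geom(inp[sl], rec))
        out.targets.append(_apply_geom(tgt[sl], rec))
        out.log.append(rec)
    return out
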