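"""Differentiable augmentation for data-efficient adversarial training.

Both the real and the generated batch entering a discriminator pass through
the same augmentation policy with independently drawn per-sample random
parameters, and every operation is differentiable with respect to the
input, so generator gradients flow through the augmented discriminator.
No clipping is applied inside the ops (outputs may leave [-1, 1]); the
augmented tensors exist only inside loss evaluation and are never returned
to the user.

Ops: brightness (additive per-sample shift), contrast (per-sample gain
about the per-sample mean), translation (integer shift, zero padding),
cutout (zeroed square).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .nn import Tensor, as_tensor

__all__ = ["AugPolicy", "apply", "identity_policy", "default_policy"]

_KNOWN_OPS = ("brightness", "contrast", "translation", "cutout")


@dataclasses.dataclass(frozen=True)
class AugPolicy:
    """Ordered augmentation policy; all-zero ranges give the identity.

    brightness_range: additive shift drawn from U(-b, b), intensity units on
    the [-1, 1] model scale.  contrast_range: gain drawn from
    U(1-c, 1+c) about the per-sample mean.  translation_fraction: max
    shift as a fraction of the image side.  cutout_fraction: zeroed-square
    side as a fraction of the image side.
    """

    ops: tuple[str, ...] = ("brightness", "translation")
    brightness_range: float = 0.5
    contrast_range: float = 0.0
    translation_fraction: float = 0.125
    cutout_fraction: float = 0.0

    def __post_init__(self):
        for op in self.ops:
            if op not in _KNOWN_OPS:
                raise ValueError(f"unknown augmentation op {op!r}; known: {_KNOWN_OPS}")
        for name in ("brightness_range", "contrast_range", "translation_fraction", "cutout_fraction"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def is_identity(self) -> bool:
        return all(
            getattr(self, n) == 0
            for n in ("brightness_range", "contrast_range", "translation_fraction", "cutout_fraction")
        )


def identity_policy() -> AugPolicy:
    return AugPolicy(ops=(), brightness_range=0.0, contrast_range=0.0, translation_fraction=0.0, cutout_fraction=0.0)


def default_policy() -> AugPolicy:
    """Brightness then translation — the two operations named for the
    augmentation module — with contrast/cutout off."""
    return AugPolicy()


def _brightness(x: Tensor, amount: float, rng: np.random.Generator) -> Tensor:
    n = x.shape[0]
    shift = rng.uniform(-amount, amount, size=(n, 1, 1, 1)).astype(x.data.dtype)
    return x + as_tensor(shift)


def _contrast(x: Tensor, amount: float, rng: np.random.Generator) -> Tensor:
    n = x.shape[0]
    gain = rng.uniform(1.0 - amount, 1.0 + amount, size=(n, 1, 1, 1)).astype(x.data.dtype)
    mean = x.mean(axis=(1, 2, 3), keepdims=True)
    return (x - mean) * as_tensor(gain) + mean


def _translation(x: Tensor, fraction: float, rng: np.random.Generator) -> Tensor:
    n = x.shape[0]
    side = x.shape[-1]
    lim = int(round(fraction * side))
    if lim == 0:
        return x
    shifts = rng.integers(-lim, lim + 1, size=(n, 2))
    return x.translate2d(shifts)


def _cutout(x: Tensor, fraction: float, rng: np.random.Generator) -> Tensor:
    n, _, h, w = x.shape
    side = int(round(fraction * w))
    if side == 0:
        return x
    keep = np.ones((n, 1, h, w), dtype=x.data.dtype)
    for i in range(n):
        cy = int(rng.integers(0, h))
        cx = int(rng.integers(0, w))
        y0, y1 = max(cy - side // 2, 0), min(cy + (side + 1) // 2, h)
        x0, x1 = max(cx - side // 2, 0), min(cx + (side + 1) // 2, w)
        keep[i, 0, y0:y1, x0:x1] = 0.0
    return x * as_tensor(keep)


_OP_TABLE = {
    "brightness": ("brightness_range", _brightness),
    "contrast": ("contrast_range", _contrast),
    "translation": ("translation_fraction", _translation),
    "cutout": ("cutout_fraction", _cutout),
}


_INTENSITY_OPS = ("brightness", "contrast")


def apply(
    policy: AugPolicy,
    batch: Tensor | np.ndarray,
    rng: np.random.Generator,
    intensity_channels: slice | None = None,
) -> Tensor:
    """Apply the policy's ops in order with per-sample random parameters.

    ``batch`` is NCHW on the [-1, 1] model scale; multi-channel inputs (e.g.
    a concatenated mask+image pair) receive each spatial op jointly across
    channels.  When ``intensity_channels`` is given, brightness/contrast
    touch only that channel slice (so a mask channel riding along with its
    image keeps its binary levels) while spatial ops still move the pair
    coherently.
    """
    from .nn import concat

    x = as_tensor(batch)
    if x.ndim != 4:
        raise ValueError("expected an NCHW batch")
    for op in policy.ops:
        attr, fn = _OP_TABLE[op]
        amount = getattr(policy, attr)
        if amount <= 0:
            continue
        if op in _INTENSITY_OPS and intensity_channels is not None:
            n_ch = x.shape[1]
            idx = range(n_ch)[intensity_channels]
            lo, hi = idx[0], idx[-1] + 1
            parts = []
            if lo > 0:
                parts.append(x[:, 0:lo])
            parts.append(fn(x[:, lo:hi], amount, rng))
            if hi < n_ch:
                parts.append(x[:, hi:n_ch])
            x = parts[0] if len(parts) == 1 else concat(parts, axis=1)
        else:
            x = fn(x, amount, rng)
    return x
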