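"""Mask Generation Stage: a DCGAN-style pair mapping Gaussian noise to
tumor-contour masks.

The generator projects a latent vector to a low-resolution seed grid and
doubles the spatial side once per transposed-convolution block (kernel 4,
stride 2, batch norm + ReLU), ending in a stride-1 tanh output layer.  The
discriminator stacks spectrally normalized stride-2 convolutions
(LeakyReLU, dropout) and collapses the final grid to one sigmoid realism
score per sample.  Adversarial losses are the original minimax forms; the
generator's non-saturating surrogate is selectable for training.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import diffaug
from .nn import (
    BatchNorm2d,
    Conv2d,
    ConvTranspose2d,
    Dense,
    Dropout,
    LeakyReLU,
    Module,
    ReLU,
    Tanh,
    Tensor,
    as_tensor,
)

__all__ = [
    "MgsConfig",
    "Generator1",
    "Discriminator1",
    "g1_generate",
    "binarize_mask",
    "d1_score",
    "mgs_g_loss",
    "mgs_d_loss",
    "mgs_losses_with_dam",
]


@dataclasses.dataclass(frozen=True)
class MgsConfig:
    """Desk-scale defaults; ``paper_scale`` reproduces the printed
    256x256 width plan (seed 8x8x512, five doublings)."""

    noise_dim: int = 64
    image_size: int = 64
    g1_channels: tuple[int, ...] = (64, 32, 16, 8)  # one up-block per entry
    d1_channels: tuple[int, ...] = (16, 32, 64)  # stride-2 blocks before the collapse
    dropout_rate: float = 0.3
    leaky_slope: float = 0.2
    sn_power_iterations: int = 1
    binarize_threshold: float = 0.0  # on the tanh scale
    out_kernel: int = 5  # stride-1 output smoothing kernel (odd)
    out_bias_init: float = 0.0  # optional background bias of the tanh output

    def __post_init__(self):
        n_up = len(self.g1_channels)
        if self.image_size % (1 << n_up) != 0 or self.image_size >> n_up < 1:
            raise ValueError("image_size must equal seed_size * 2**len(g1_channels)")
        if list(self.g1_channels) != sorted(self.g1_channels, reverse=True):
            raise ValueError("g1_channels must be decreasing")
        if self.image_size >> len(self.d1_channels) < 2:
            raise ValueError("too many d1 blocks for this image size")

    @property
    def seed_size(self) -> int:
        return self.image_size >> len(self.g1_channels)

    @classmethod
    def paper_scale(cls) -> "MgsConfig":
        return cls(
            image_size=256,
            g1_channels=(512, 256, 128, 64, 32),
            d1_channels=(32, 64, 128, 256, 512),
        )


class Generator1(Module):
    def __init__(self, config: MgsConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        ch = config.g1_channels
        self.project = Dense(config.noise_dim, ch[0] * config.seed_size**2, rng)
        blocks: list[Module] = []
        prev = ch[0]
        for width in ch:
            blocks.extend(
                [ConvTranspose2d(prev, width, 4, rng, stride=2, padding=1), BatchNorm2d(width), ReLU()]
            )
            prev = width
        k_out = config.out_kernel
        out_conv = Conv2d(prev, 1, k_out, rng, stride=1, padding=k_out // 2)
        # start from "all background": biasing the tanh output negative makes
        # early samples near-empty so training grows a single lesion rather
        # than thresholding mid-gray noise into scattered blobs
        out_conv.bias.data[:] = config.out_bias_init
        blocks.extend([out_conv, Tanh()])
        self.blocks = blocks

    def forward(self, z: Tensor) -> Tensor:
        z = as_tensor(z)
        if z.ndim != 2 or z.shape[1] != self.config.noise_dim:
            raise ValueError(f"expected latent batch of dimension {self.config.noise_dim}")
        c0, s0 = self.config.g1_channels[0], self.config.seed_size
        x = self.project(z).reshape(z.shape[0], c0, s0, s0)
        for block in self.blocks:
            x = block(x)
        return x


class Discriminator1(Module):
    def __init__(self, config: MgsConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        blocks: list[Module] = []
        prev = 1
        size = config.image_size
        for width in config.d1_channels:
            blocks.extend(
                [
                    Conv2d(
                        prev, width, 4, rng, stride=2, padding=1,
                        spectral_norm=True, power_iterations=config.sn_power_iterations,
                    ),
                    LeakyReLU(config.leaky_slope),
                    Dropout(config.dropout_rate, rng),
                ]
            )
            prev = width
            size //= 2
        # final valid convolution collapses the remaining grid to one logit
        blocks.append(
            Conv2d(
                prev, 1, size, rng, stride=1, padding=0,
                spectral_norm=True, power_iterations=config.sn_power_iterations,
            )
        )
        self.blocks = blocks

    def forward(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        if x.data.shape[-2:] != (self.config.image_size,) * 2:
            raise ValueError(f"expected {self.config.image_size}px inputs, got {x.data.shape}")
        for block in self.blocks:
            x = block(x)
        n = x.shape[0]
        # clip keeps float32 sigmoid saturation out of the log losses
        return x.reshape(n).sigmoid().clip(1e-7, 1.0 - 1e-7)

    def sn_convs(self) -> list[Conv2d]:
        return [b for b in self.blocks if isinstance(b, Conv2d) and b.spectral_norm]


def g1_generate(g1: Generator1, z: Tensor | np.ndarray) -> Tensor:
    """Raw mask batch in [-1, 1] (N, 1, S, S)."""
    return g1(as_tensor(z))


def binarize_mask(raw: np.ndarray | Tensor, threshold: float = 0.0) -> np.ndarray:
    """Tanh-scale mask -> {0, 1}: lesion where raw > threshold."""
    data = raw.data if isinstance(raw, Tensor) else np.asarray(raw)
    return (data > threshold).astype(np.uint8)


def d1_score(d1: Discriminator1, masks: Tensor | np.ndarray) -> Tensor:
    """Per-sample realism probability in (0, 1)."""
    return d1(as_tensor(masks))


def _check_scores(scores: Tensor) -> Tensor:
    data = scores.data
    if np.any(data <= 0.0) or np.any(data >= 1.0) or not np.all(np.isfinite(data)):
        raise ValueError("scores must lie strictly inside (0, 1)")
    return scores


def mgs_g_loss(fake_scores: Tensor | np.ndarray, saturating: bool = True) -> Tensor:
    """Generator objective: mean log(1 - D(fake)), minimized.

    With ``saturating=False`` returns the non-saturating surrogate
    -mean log D(fake) (same fixed points, stronger early gradients).
    """
    s = _check_scores(as_tensor(fake_scores))
    if saturating:
        return (1.0 - s).log().mean()
    return -(s.log().mean())


def mgs_d_loss(real_scores: Tensor | np.ndarray, fake_scores: Tensor | np.ndarray) -> Tensor:
    """Negated discriminator objective (minimize):
    -mean log D(real) - mean log(1 - D(fake))."""
    r = _check_scores(as_tensor(real_scores))
    f = _check_scores(as_tensor(fake_scores))
    return -(r.log().mean()) - (1.0 - f).log().mean()


def mgs_losses_with_dam(
    g1: Generator1,
    d1: Discriminator1,
    real_masks: Tensor | np.ndarray,
    z: Tensor | np.ndarray,
    policy: diffaug.AugPolicy,
    rng: np.random.Generator,
    saturating: bool = True,
) -> tuple[Tensor, Tensor]:
    """Adversarial losses with every discriminator input augmented.

    With the identity policy this reduces exactly to the plain losses.  The
    generator loss and discriminator loss are computed on one generated
    batch (detached for the discriminator side).
    """
    fake = g1_generate(g1, z)
    fake_scores = d1(diffaug.apply(policy, fake, rng))
    g_loss = mgs_g_loss(fake_scores, saturating=saturating)
    real_scores = d1(diffaug.apply(policy, as_tensor(real_masks), rng))
    fake_scores_d = d1(diffaug.apply(policy, fake.detach(), rng))
    d_loss = mgs_d_loss(real_scores, fake_scores_d)
    return g_loss, d_loss
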