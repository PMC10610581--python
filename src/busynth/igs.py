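"""Image Generation Stage: translates a tumor-contour mask into a textured
ultrasound image.

The generator is an encoder-decoder: a 1x1 channel adapter, stride-2
convolution blocks (3x3, instance norm, ReLU), a stack of residual blocks
(two stride-1 convolutions each), mirrored stride-2 transposed-convolution
blocks and a 1x1 tanh output adapter.  The discriminator is a patch
discriminator over the channel-concatenated (mask, image) pair: spectrally
normalized stride-2 4x4 convolutions ending in a stride-1 sigmoid score
grid, one probability per image patch.  Its per-block activations double as
the feature extractor for the feature-matching loss, which pulls generated
pairs toward real pairs in the discriminator's own representation at every
scale.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import diffaug
from .nn import (
    Conv2d,
    ConvTranspose2d,
    Dropout,
    InstanceNorm2d,
    LeakyReLU,
    Module,
    ReLU,
    Tanh,
    Tensor,
    as_tensor,
    concat,
)

__all__ = [
    "IgsConfig",
    "PatchScoreMap",
    "Generator2",
    "Discriminator2",
    "g2_translate",
    "d2_patch_scores",
    "igs_g_adv_loss",
    "igs_d_loss",
    "feature_matching_loss",
    "igs_total_g_loss",
    "igs_losses_with_dam",
]


@dataclasses.dataclass(frozen=True)
class IgsConfig:
    """Desk-scale defaults; ``paper_scale`` gives the printed 256x256 plan
    (encoder widths 64..512, 5 residual blocks, 16x16 patch map)."""

    image_size: int = 64
    n_residual_blocks: int = 5
    g2_widths: tuple[int, ...] = (12, 24, 32, 48)  # one stride-2 encoder block per entry
    d2_widths: tuple[int, ...] = (12, 24, 32, 48)  # one stride-2 block per entry
    lambda_fm: float = 10.0
    dropout_rate: float = 0.3
    leaky_slope: float = 0.2
    sn_power_iterations: int = 1

    def __post_init__(self):
        if self.lambda_fm < 0:
            raise ValueError("lambda_fm must be >= 0")
        if self.image_size >> len(self.g2_widths) < 1:
            raise ValueError("too many encoder blocks for this image size")

    @property
    def bottleneck_size(self) -> int:
        return self.image_size >> len(self.g2_widths)

    @property
    def patch_map_size(self) -> int:
        return self.image_size >> len(self.d2_widths)

    @classmethod
    def paper_scale(cls) -> "IgsConfig":
        return cls(image_size=256, g2_widths=(64, 128, 256, 512), d2_widths=(64, 128, 256, 512))


@dataclasses.dataclass
class PatchScoreMap:
    """Patch realism probabilities plus the per-layer features behind them."""

    scores: Tensor  # (N, P, P) in (0, 1)
    features: list[Tensor]  # one activation tensor per tapped layer

    @property
    def n_layers(self) -> int:
        return len(self.features)


class _ResidualBlock(Module):
    def __init__(self, width: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv2d(width, width, 3, rng, stride=1, padding=1)
        self.norm1 = InstanceNorm2d(width)
        self.relu = ReLU()
        self.conv2 = Conv2d(width, width, 3, rng, stride=1, padding=1)
        self.norm2 = InstanceNorm2d(width)

    def forward(self, x: Tensor) -> Tensor:
        h = self.relu(self.norm1(self.conv1(x)))
        h = self.norm2(self.conv2(h))
        return x + h


class Generator2(Module):
    def __init__(self, config: IgsConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        w = config.g2_widths
        self.head = Conv2d(1, w[0], 1, rng)
        enc: list[Module] = []
        prev = w[0]
        for width in w:
            enc.extend([Conv2d(prev, width, 3, rng, stride=2, padding=1), InstanceNorm2d(width), ReLU()])
            prev = width
        self.encoder = enc
        self.res_blocks = [_ResidualBlock(prev, rng) for _ in range(config.n_residual_blocks)]
        dec: list[Module] = []
        for width in reversed(w):
            dec.extend(
                [
                    ConvTranspose2d(prev, width, 3, rng, stride=2, padding=1, output_padding=1),
                    InstanceNorm2d(width),
                    ReLU(),
                ]
            )
            prev = width
        self.decoder = dec
        self.tail = Conv2d(prev, 1, 1, rng)
        self.out_act = Tanh()

    def forward(self, mask: Tensor) -> Tensor:
        x = self.head(as_tensor(mask))
        for block in self.encoder:
            x = block(x)
        for block in self.res_blocks:
            x = block(x)
        for block in self.decoder:
            x = block(x)
        return self.out_act(self.tail(x))


class Discriminator2(Module):
    """Patch discriminator over concatenated (mask, image) pairs."""

    def __init__(self, config: IgsConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        self.blocks: list[list[Module]] = []
        prev = 2
        for width in config.d2_widths:
            self.blocks.append(
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
        self.score_conv = Conv2d(
            prev, 1, 3, rng, stride=1, padding=1,
            spectral_norm=True, power_iterations=config.sn_power_iterations,
        )

    def children(self):
        for i, block in enumerate(self.blocks):
            for j, layer in enumerate(block):
                yield f"blocks.{i}.{j}", layer
        yield "score_conv", self.score_conv

    def forward_features(self, pair: Tensor) -> tuple[Tensor, list[Tensor]]:
        x = as_tensor(pair)
        if x.shape[1] != 2:
            raise ValueError("expected a 2-channel (mask, image) pair batch")
        feats: list[Tensor] = []
        for block in self.blocks:
            for layer in block:
                x = layer(x)
            feats.append(x)
        logits = self.score_conv(x)
        n, _, p, _ = logits.shape
        scores = logits.reshape(n, p, p).sigmoid().clip(1e-7, 1.0 - 1e-7)
        return scores, feats

    def forward(self, pair: Tensor) -> Tensor:
        return self.forward_features(pair)[0]

    def sn_convs(self) -> list[Conv2d]:
        convs = [block[0] for block in self.blocks]
        convs.append(self.score_conv)
        return convs


def _pair(mask: Tensor | np.ndarray, image: Tensor | np.ndarray) -> Tensor:
    m, im = as_tensor(mask), as_tensor(image)
    if m.shape != im.shape:
        raise ValueError("mask and image batches must share a shape")
    return concat([m, im], axis=1)


def mask_to_model_scale(mask01: np.ndarray) -> np.ndarray:
    """{0,1} mask -> {-1,+1} model scale (background -1, lesion +1)."""
    return mask01.astype(np.float32) * 2.0 - 1.0


def g2_translate(g2: Generator2, masks: Tensor | np.ndarray) -> Tensor:
    """Mask batch (model scale) -> image batch in [-1, 1]."""
    return g2(as_tensor(masks))


def d2_patch_scores(d2: Discriminator2, masks, images) -> PatchScoreMap:
    scores, feats = d2.forward_features(_pair(masks, images))
    return PatchScoreMap(scores=scores, features=feats)


def _check_scores(scores: Tensor) -> Tensor:
    data = scores.data
    if np.any(data <= 0.0) or np.any(data >= 1.0) or not np.all(np.isfinite(data)):
        raise ValueError("patch scores must lie strictly inside (0, 1)")
    return scores


def igs_g_adv_loss(fake_scores: Tensor | np.ndarray, saturating: bool = True) -> Tensor:
    """Mean log(1 - D(fake)) over all patches and samples (or the
    non-saturating -mean log D(fake))."""
    s = _check_scores(as_tensor(fake_scores))
    if saturating:
        return (1.0 - s).log().mean()
    return -(s.log().mean())


def igs_d_loss(real_scores: Tensor | np.ndarray, fake_scores: Tensor | np.ndarray) -> Tensor:
    """Negated patch-discriminator objective, averaged over patches."""
    r = _check_scores(as_tensor(real_scores))
    f = _check_scores(as_tensor(fake_scores))
    return -(r.log().mean()) - (1.0 - f).log().mean()


def feature_matching_loss(real_features: list[Tensor], fake_features: list[Tensor]) -> Tensor:
    """sum_i (1/N_i) * L1(real_i - fake_i), averaged over the batch.

    N_i counts the per-sample elements of layer i, so constant-offset
    features give exactly M*c.
    """
    if len(real_features) != len(fake_features):
        raise ValueError("feature stacks differ in layer count")
    total = None
    for fr, ff in zip(real_features, fake_features):
        fr, ff = as_tensor(fr), as_tensor(ff)
        if fr.shape != ff.shape:
            raise ValueError("feature shapes differ within a layer")
        n_batch = fr.shape[0]
        n_i = fr.data.size // n_batch
        term = (fr - ff).abs().sum() * (1.0 / (n_i * n_batch))
        total = term if total is None else total + term
    if total is None:
        raise ValueError("feature stacks are empty")
    return total


def igs_total_g_loss(adv: Tensor | float, fm: Tensor | float, lambda_fm: float = 10.0) -> Tensor:
    """Combined generator objective adv + lambda * FML."""
    if lambda_fm < 0:
        raise ValueError("lambda_fm must be >= 0")
    return as_tensor(adv) + lambda_fm * as_tensor(fm)


def igs_losses_with_dam(
    g2: Generator2,
    d2: Discriminator2,
    real_masks: Tensor | np.ndarray,
    real_images: Tensor | np.ndarray,
    policy: diffaug.AugPolicy,
    rng: np.random.Generator,
    saturating: bool = True,
) -> tuple[Tensor, Tensor]:
    """Adversarial losses with the concatenated pair augmented as one unit.

    Spatial ops move mask and image together (pair coherence); intensity ops
    touch the image channel only.  The feature-matching loss is *not*
    computed here — it uses clean, un-augmented pairs.
    """
    fake_images = g2_translate(g2, real_masks)
    img_ch = slice(1, 2)
    fake_pair = diffaug.apply(policy, _pair(real_masks, fake_images), rng, intensity_channels=img_ch)
    g_adv = igs_g_adv_loss(d2(fake_pair), saturating=saturating)
    real_pair = diffaug.apply(policy, _pair(real_masks, real_images), rng, intensity_channels=img_ch)
    fake_pair_d = diffaug.apply(
        policy, _pair(real_masks, fake_images.detach()), rng, intensity_channels=img_ch
    )
    d_loss = igs_d_loss(d2(real_pair), d2(fake_pair_d))
    return g_adv, d_loss
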