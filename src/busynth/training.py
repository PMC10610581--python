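"""Two-stage, per-class training protocol and the end-to-end sampler.

Benign and malignant models are trained separately; the mask stage trains
first and independently of the image stage, which trains on real
(mask, image) pairs only — generated masks enter the pipeline at sampling
time, when noise -> mask -> image produces internally consistent annotated
pairs.  Updates alternate one discriminator step with one generator step
per batch, both Adam.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from pathlib import Path

import numpy as np

from . import diffaug, igs, mgs
from .io import from_model_scale
from .nn import Adam, as_tensor
from .nn.autograd import no_grad
from .phantom import LabeledPair

__all__ = [
    "TrainConfig",
    "RunRecord",
    "train_mgs",
    "train_igs",
    "save_checkpoint",
    "load_mgs_checkpoint",
    "load_igs_checkpoint",
    "sample_pipeline",
]


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 16
    lr_g: float = 1e-4
    lr_d: float = 4e-4
    adam_betas: tuple[float, float] = (0.5, 0.999)
    epochs: int = 100  # the reference protocol uses 6000 at full scale
    class_label: str = "benign"
    seed: int = 0
    checkpoint_interval: int = 0  # steps; 0 = final only
    max_steps: int | None = None  # hard cap overriding epochs (desk-scale runs)
    saturating_g_loss: bool = False  # non-saturating surrogate by default

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.lr_g <= 0 or self.lr_d <= 0:
            raise ValueError("learning rates must be positive")


def default_mgs_train_config(**overrides) -> TrainConfig:
    """Mask-stage defaults: D learns at 2x the generator rate (the 4x ratio
    used for the image stage lets D1 overpower G1 at small scale)."""
    overrides.setdefault("lr_d", 2e-4)
    return TrainConfig(**overrides)


def default_igs_train_config(**overrides) -> TrainConfig:
    """Image-stage defaults: the published 1e-4 / 4e-4 rates."""
    return TrainConfig(**overrides)


@dataclasses.dataclass
class RunRecord:
    stage: str
    config: TrainConfig
    losses: list[dict]  # per-step {"step", "d_loss", "g_loss"}
    checkpoint_path: str | None = None

    @property
    def n_steps(self) -> int:
        return len(self.losses)

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["step", "d_loss", "g_loss"])
            writer.writeheader()
            writer.writerows(self.losses)


def _batches(n: int, batch_size: int, epochs: int, rng: np.random.Generator, max_steps: int | None):
    steps = 0
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            if len(idx) < batch_size and n >= batch_size:
                idx = np.concatenate([idx, order[: batch_size - len(idx)]])
            yield idx
            steps += 1
            if max_steps is not None and steps >= max_steps:
                return


def train_mgs(
    masks: np.ndarray,
    mgs_config: mgs.MgsConfig,
    train_config: TrainConfig,
    policy: diffaug.AugPolicy | None = None,
    mask_smoothing: float = 1.0,
    ema_decay: float = 0.98,
) -> tuple[mgs.Generator1, mgs.Discriminator1, RunRecord]:
    """Train the mask stage on {0,1} masks of shape (N, S, S).

    ``mask_smoothing`` antialiases the real contour images with a small
    Gaussian before mapping them to the tanh scale: hard {-1,+1} edges are
    outside the generator's reachable set, and letting the discriminator key
    on edge saturation alone destabilizes small-scale runs.  Set 0 to train
    on the raw binary masks.

    ``ema_decay``: the returned generator carries an exponential moving
    average of the generator weights — adversarial updates oscillate and the
    time-averaged iterate samples more cleanly than the last one.  Set 0 to
    return the raw final iterate.
    """
    if len(masks) == 0:
        raise ValueError("empty dataset")
    policy = policy if policy is not None else diffaug.default_policy()
    rng = np.random.default_rng(np.random.SeedSequence([train_config.seed, 1]))
    g1 = mgs.Generator1(mgs_config, rng)
    d1 = mgs.Discriminator1(mgs_config, rng)
    opt_g = Adam(g1.parameters(), train_config.lr_g, train_config.adam_betas)
    opt_d = Adam(d1.parameters(), train_config.lr_d, train_config.adam_betas)
    real01 = np.asarray(masks, dtype=np.float32)
    if mask_smoothing > 0:
        from scipy import ndimage as _ndi

        real01 = np.stack([_ndi.gaussian_filter(m, mask_smoothing) for m in real01])
    real_all = (real01 * 2.0 - 1.0)[:, None]
    g_params = g1.parameters()
    # tail averaging: adversarial training keeps oscillating, so the
    # returned generator averages iterates over roughly the last third of
    # the run (weight averaging across early, still-moving iterates hurts)
    total_steps = train_config.max_steps
    if total_steps is None:
        total_steps = train_config.epochs * max(1, int(np.ceil(len(masks) / train_config.batch_size)))
    ema_start = int(0.65 * total_steps)
    ema = [p.data.copy() for p in g_params] if ema_decay > 0 else None
    losses: list[dict] = []
    for step, idx in enumerate(
        _batches(len(masks), train_config.batch_size, train_config.epochs, rng, train_config.max_steps)
    ):
        real = real_all[idx]
        nb = len(idx)
        # discriminator step (generator run untaped)
        z = rng.standard_normal((nb, mgs_config.noise_dim), dtype=np.float32)
        with no_grad():
            fake = mgs.g1_generate(g1, z).data
        d_real = d1(diffaug.apply(policy, as_tensor(real), rng))
        d_fake = d1(diffaug.apply(policy, as_tensor(fake), rng))
        d_loss = mgs.mgs_d_loss(d_real, d_fake)
        d1.zero_grad()
        d_loss.backward()
        opt_d.step()
        # generator step
        z = rng.standard_normal((nb, mgs_config.noise_dim), dtype=np.float32)
        fake_t = mgs.g1_generate(g1, z)
        g_scores = d1(diffaug.apply(policy, fake_t, rng))
        g_loss = mgs.mgs_g_loss(g_scores, saturating=train_config.saturating_g_loss)
        g1.zero_grad()
        d1.zero_grad()
        g_loss.backward()
        opt_g.step()
        if ema is not None:
            if step < ema_start:
                for e, p in zip(ema, g_params):
                    e[...] = p.data
            else:
                for e, p in zip(ema, g_params):
                    e *= ema_decay
                    e += (1.0 - ema_decay) * p.data
        losses.append({"step": step, "d_loss": float(d_loss.data), "g_loss": float(g_loss.data)})
    if ema is not None:
        for e, p in zip(ema, g_params):
            p.data = e
    return g1, d1, RunRecord(stage="mgs", config=train_config, losses=losses)


def train_igs(
    pairs: list[LabeledPair],
    igs_config: igs.IgsConfig,
    train_config: TrainConfig,
    policy: diffaug.AugPolicy | None = None,
    use_fml: bool = True,
) -> tuple[igs.Generator2, igs.Discriminator2, RunRecord]:
    """Train the image stage on real (mask, image) pairs."""
    if len(pairs) == 0:
        raise ValueError("empty dataset")
    policy = policy if policy is not None else diffaug.default_policy()
    rng = np.random.default_rng(np.random.SeedSequence([train_config.seed, 2]))
    g2 = igs.Generator2(igs_config, rng)
    d2 = igs.Discriminator2(igs_config, rng)
    opt_g = Adam(g2.parameters(), train_config.lr_g, train_config.adam_betas)
    opt_d = Adam(d2.parameters(), train_config.lr_d, train_config.adam_betas)
    masks_all = np.stack([igs.mask_to_model_scale(p.mask) for p in pairs])[:, None]
    imgs_all = np.stack([p.image.astype(np.float32) * 2.0 - 1.0 for p in pairs])[:, None]
    img_ch = slice(1, 2)
    losses: list[dict] = []
    for step, idx in enumerate(
        _batches(len(pairs), train_config.batch_size, train_config.epochs, rng, train_config.max_steps)
    ):
        m, x = masks_all[idx], imgs_all[idx]
        # discriminator step
        with no_grad():
            fake = igs.g2_translate(g2, m).data
        real_pair = diffaug.apply(policy, igs._pair(m, x), rng, intensity_channels=img_ch)
        fake_pair = diffaug.apply(policy, igs._pair(m, fake), rng, intensity_channels=img_ch)
        d_loss = igs.igs_d_loss(d2(real_pair), d2(fake_pair))
        d2.zero_grad()
        d_loss.backward()
        opt_d.step()
        # generator step: adversarial (augmented) + feature matching (clean)
        fake_t = igs.g2_translate(g2, m)
        gen_pair = diffaug.apply(policy, igs._pair(m, fake_t), rng, intensity_channels=img_ch)
        adv = igs.igs_g_adv_loss(d2(gen_pair), saturating=train_config.saturating_g_loss)
        if use_fml and igs_config.lambda_fm > 0:
            with no_grad():
                _, real_feats = d2.forward_features(igs._pair(m, x))
            _, fake_feats = d2.forward_features(igs._pair(m, fake_t))
            fm = igs.feature_matching_loss([f.detach() for f in real_feats], fake_feats)
            total = igs.igs_total_g_loss(adv, fm, igs_config.lambda_fm)
        else:
            total = adv
        g2.zero_grad()
        d2.zero_grad()
        total.backward()
        opt_g.step()
        losses.append({"step": step, "d_loss": float(d_loss.data), "g_loss": float(total.data)})
    return g2, d2, RunRecord(stage="igs", config=train_config, losses=losses)


# ----------------------------------------------------------------- checkpoints
def save_checkpoint(path: str | Path, stage: str, generator, discriminator, config) -> None:
    """Write weights + config to an .npz container."""
    payload = {f"g::{k}": v for k, v in generator.state_dict().items()}
    payload.update({f"d::{k}": v for k, v in discriminator.state_dict().items()})
    meta = {"stage": stage, "config": dataclasses.asdict(config)}
    payload["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **payload)


def _load_checkpoint(path, stage, make_models):
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        if meta["stage"] != stage:
            raise ValueError(f"checkpoint holds stage {meta['stage']!r}, expected {stage!r}")
        cfg_kwargs = meta["config"]
        for key, val in cfg_kwargs.items():
            if isinstance(val, list):
                cfg_kwargs[key] = tuple(val)
        gen, disc, config = make_models(cfg_kwargs)
        gen.load_state_dict({k[3:]: data[k] for k in data.files if k.startswith("g::")})
        disc.load_state_dict({k[3:]: data[k] for k in data.files if k.startswith("d::")})
    return gen, disc, config


def load_mgs_checkpoint(path: str | Path):
    def make(cfg_kwargs):
        config = mgs.MgsConfig(**cfg_kwargs)
        rng = np.random.default_rng(0)
        return mgs.Generator1(config, rng), mgs.Discriminator1(config, rng), config

    return _load_checkpoint(path, "mgs", make)


def load_igs_checkpoint(path: str | Path):
    def make(cfg_kwargs):
        config = igs.IgsConfig(**cfg_kwargs)
        rng = np.random.default_rng(0)
        return igs.Generator2(config, rng), igs.Discriminator2(config, rng), config

    return _load_checkpoint(path, "igs", make)


# -------------------------------------------------------------------- sampling
def sample_pipeline(
    n: int,
    g1: mgs.Generator1,
    g2: igs.Generator2,
    class_label: str,
    seed: int = 0,
    threshold: float = 0.0,
    batch_size: int = 16,
) -> list[LabeledPair]:
    """noise -> mask -> image; each pair is internally consistent."""
    if g1.config.image_size != g2.config.image_size:
        raise ValueError("mask and image stages disagree on image_size")
    g1.eval()
    g2.eval()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    out: list[LabeledPair] = []
    with no_grad():
        while len(out) < n:
            nb = min(batch_size, n - len(out))
            z = rng.standard_normal((nb, g1.config.noise_dim), dtype=np.float32)
            raw = mgs.g1_generate(g1, z)
            masks = mgs.binarize_mask(raw, threshold)
            imgs = igs.g2_translate(g2, masks.astype(np.float32) * 2.0 - 1.0).data
            for i in range(nb):
                out.append(
                    LabeledPair(
                        image=from_model_scale(imgs[i, 0]),
                        mask=masks[i, 0].astype(np.uint8),
                        class_label=class_label,
                    )
                )
    g1.train()
    g2.train()
    return out
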