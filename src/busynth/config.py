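"""Run configuration: one YAML file with nested, schema-validated sections.

Unknown keys are rejected field-by-field so typos surface immediately; the
global seed feeds every random stream in a run.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict

from . import diffaug, igs, mgs, training
from .evalkit import ExperimentConfig

__all__ = ["RunConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PhantomSection(_Strict):
    image_size: int = 64
    n_benign: int = 30
    n_malignant: int = 30
    overrides: dict[str, dict] = {}


class MgsSection(_Strict):
    noise_dim: int = 64
    image_size: int = 64
    g1_channels: list[int] = [64, 32, 16, 8]
    d1_channels: list[int] = [16, 32, 64]
    dropout_rate: float = 0.3
    leaky_slope: float = 0.2
    sn_power_iterations: int = 1
    binarize_threshold: float = 0.0

    def build(self) -> mgs.MgsConfig:
        data = self.model_dump()
        data["g1_channels"] = tuple(data["g1_channels"])
        data["d1_channels"] = tuple(data["d1_channels"])
        return mgs.MgsConfig(**data)


class IgsSection(_Strict):
    image_size: int = 64
    n_residual_blocks: int = 5
    g2_widths: list[int] = [12, 24, 32, 48]
    d2_widths: list[int] = [12, 24, 32, 48]
    lambda_fm: float = 10.0
    dropout_rate: float = 0.3
    leaky_slope: float = 0.2
    sn_power_iterations: int = 1

    def build(self) -> igs.IgsConfig:
        data = self.model_dump()
        data["g2_widths"] = tuple(data["g2_widths"])
        data["d2_widths"] = tuple(data["d2_widths"])
        return igs.IgsConfig(**data)


class TrainingSection(_Strict):
    batch_size: int = 16
    lr_g: float = 1e-4
    lr_d: float = 4e-4
    adam_betas: list[float] = [0.5, 0.999]
    epochs: int = 100
    max_steps: int | None = None
    checkpoint_interval: int = 0
    saturating_g_loss: bool = False

    def build(self, class_label: str, seed: int) -> training.TrainConfig:
        data = self.model_dump()
        data["adam_betas"] = tuple(data["adam_betas"])
        return training.TrainConfig(class_label=class_label, seed=seed, **data)


class DiffaugSection(_Strict):
    ops: list[str] = ["brightness", "translation"]
    brightness_range: float = 0.5
    contrast_range: float = 0.0
    translation_fraction: float = 0.125
    cutout_fraction: float = 0.0

    def build(self) -> diffaug.AugPolicy:
        data = self.model_dump()
        data["ops"] = tuple(data["ops"])
        return diffaug.AugPolicy(**data)


class MetricsSection(_Strict):
    extractor: str = "randconv"
    n_diversity_pairs: int = 100


class EvalkitSection(_Strict):
    task: str = "segmentation"
    epochs: int = 6
    batch_size: int = 16
    lr: float = 2e-3
    online_p: float = 0.3
    synthetic_ratio: float = 1.0
    k_folds: int = 3
    model_width: int = 8
    seg_pos_weight: float = 8.0

    def build(self, seed: int) -> ExperimentConfig:
        return ExperimentConfig(seed=seed, **self.model_dump())


class RunConfig(_Strict):
    seed: int = 0
    phantom: PhantomSection = PhantomSection()
    mgs: MgsSection = MgsSection()
    igs: IgsSection = IgsSection()
    training: TrainingSection = TrainingSection()
    diffaug: DiffaugSection = DiffaugSection()
    metrics: MetricsSection = MetricsSection()
    evalkit: EvalkitSection = EvalkitSection()


def load_config(path: str | Path | None) -> RunConfig:
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig(**raw)
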