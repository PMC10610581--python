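"""Downstream augmentation-evaluation harness.

Implements the protocol used to judge whether synthetic image/mask pairs
help real tasks: a stratified 60/20/20 split, minority-class oversampling,
online augmentation applied with per-op probability 0.3, small from-scratch
classification and segmentation models, and the standard evaluation
formulas (precision, recall, accuracy, F1, Dice).  Conditions compared:
baseline (no augmentation), traditional augmentation (TA), and TA plus
synthetic pairs; the held-out test set is always real and disjoint from
every training input.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import ndimage

from .nn import Adam, Conv2d, ConvTranspose2d, LeakyReLU, Module, ReLU, Sequential, Tensor, as_tensor, concat, he_init
from .nn.autograd import no_grad
from .phantom import CLASSES, MALIGNANT, LabeledPair

__all__ = [
    "ConfusionCounts",
    "SplitPlan",
    "OnlineAugConfig",
    "split_dataset",
    "kfold_indices",
    "oversample_balance",
    "online_augment",
    "confusion",
    "precision",
    "recall",
    "accuracy",
    "f1_score",
    "dice",
    "ExperimentConfig",
    "run_augmentation_experiment",
]


# ------------------------------------------------------------------ formulas
@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(pred: np.ndarray, true: np.ndarray) -> ConfusionCounts:
    pred = np.asarray(pred).astype(bool).ravel()
    true = np.asarray(true).astype(bool).ravel()
    if pred.shape != true.shape:
        raise ValueError("prediction/label length mismatch")
    return ConfusionCounts(
        tp=int(np.sum(pred & true)),
        fp=int(np.sum(pred & ~true)),
        fn=int(np.sum(~pred & true)),
        tn=int(np.sum(~pred & ~true)),
    )


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name}: zero denominator, defined as 0", stacklevel=3)
        return 0.0
    return num / den


def precision(c: ConfusionCounts) -> float:
    return _safe_ratio(c.tp, c.tp + c.fp, "precision")


def recall(c: ConfusionCounts) -> float:
    return _safe_ratio(c.tp, c.tp + c.fn, "recall")


def accuracy(c: ConfusionCounts) -> float:
    return _safe_ratio(c.tp + c.tn, c.total, "accuracy")


def f1_score(c: ConfusionCounts) -> float:
    p, r = precision(c), recall(c)
    if p + r == 0:
        warnings.warn("f1: zero denominator, defined as 0", stacklevel=2)
        return 0.0
    return 2.0 * p * r / (p + r)


def dice(pred_mask: np.ndarray, gt_mask: np.ndarray) -> float:
    """Pixelwise 2TP / (2TP + FP + FN); empty vs empty = 1."""
    pred = np.asarray(pred_mask).astype(bool)
    gt = np.asarray(gt_mask).astype(bool)
    if pred.shape != gt.shape:
        raise ValueError("mask shapes differ")
    tp = np.sum(pred & gt)
    fp = np.sum(pred & ~gt)
    fn = np.sum(~pred & gt)
    if tp + fp + fn == 0:
        return 1.0
    return float(2.0 * tp / (2.0 * tp + fp + fn))


# ------------------------------------------------------------------ splitting
@dataclasses.dataclass(frozen=True)
class SplitPlan:
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    stratified_by_class: bool = True
    seed: int = 0
    k_folds: int = 3

    def __post_init__(self):
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")


def _assign(n: int, fractions, rng) -> list[np.ndarray]:
    order = rng.permutation(n)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    return [order[:n_train], order[n_train : n_train + n_val], order[n_train + n_val :]]


def split_dataset(pairs: list[LabeledPair], plan: SplitPlan) -> tuple[list, list, list]:
    """Disjoint, exhaustive train/val/test split (stratified when flagged)."""
    if not pairs:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(plan.seed)
    idx_groups: list[list[int]] = [[], [], []]
    if plan.stratified_by_class:
        for label in CLASSES:
            cls_idx = np.array([i for i, p in enumerate(pairs) if p.class_label == label], dtype=int)
            if len(cls_idx) == 0:
                continue
            for g, part in enumerate(_assign(len(cls_idx), plan.fractions, rng)):
                idx_groups[g].extend(cls_idx[part].tolist())
    else:
        for g, part in enumerate(_assign(len(pairs), plan.fractions, rng)):
            idx_groups[g].extend(part.tolist())
    return tuple([pairs[i] for i in sorted(g)] for g in idx_groups)  # type: ignore[return-value]


def kfold_indices(labels: list[str], k: int, seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold (train_idx, val_idx) pairs."""
    labels = list(labels)
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for label in sorted(set(labels)):
        cls_idx = [i for i, l in enumerate(labels) if l == label]
        if len(cls_idx) < k:
            raise ValueError(f"class {label!r} has fewer samples than folds")
        cls_idx = rng.permutation(cls_idx)
        for j, i in enumerate(cls_idx):
            folds[j % k].append(int(i))
    out = []
    for j in range(k):
        val = np.array(sorted(folds[j]), dtype=int)
        train = np.array(sorted(i for jj in range(k) if jj != j for i in folds[jj]), dtype=int)
        out.append((train, val))
    return out


def oversample_balance(pairs: list[LabeledPair], seed: int = 0) -> list[LabeledPair]:
    """Duplicate minority-class samples (with replacement) until class
    counts match the majority; majority samples are untouched."""
    counts = {label: sum(1 for p in pairs if p.class_label == label) for label in CLASSES}
    present = {l: c for l, c in counts.items() if c > 0}
    if not present:
        raise ValueError("empty dataset")
    target = max(present.values())
    rng = np.random.default_rng(seed)
    out = list(pairs)
    for label, count in present.items():
        deficit = target - count
        if deficit > 0:
            cls = [p for p in pairs if p.class_label == label]
            picks = rng.integers(0, len(cls), size=deficit)
            out.extend(cls[int(i)] for i in picks)
    return out


# --------------------------------------------------------- online augmentation
@dataclasses.dataclass(frozen=True)
class OnlineAugConfig:
    """Per-op probability p; geometric ops co-transform image and mask
    (mask re-binarized), intensity ops touch the image only."""

    p: float = 0.3
    ops: tuple[str, ...] = ("translation", "hflip", "rotation")
    rotation_degrees: float = 15.0
    shift_fraction: float = 0.10
    blur_sigma_range: tuple[float, float] = (0.5, 1.5)
    gamma_range: tuple[float, float] = (0.8, 1.2)
    noise_sigma: float = 0.02
    scale_range: tuple[float, float] = (0.9, 1.1)

    def __post_init__(self):
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")

    @classmethod
    def classification(cls) -> "OnlineAugConfig":
        return cls(ops=("translation", "hflip", "rotation"))

    @classmethod
    def segmentation(cls) -> "OnlineAugConfig":
        return cls(ops=("rotation", "blur", "translation", "gamma", "scaling", "noise"))


def _rotate(img, mask, angle):
    img2 = ndimage.rotate(img, angle, reshape=False, order=1, mode="nearest")
    mask2 = ndimage.rotate(mask.astype(float), angle, reshape=False, order=0, mode="constant")
    return img2, mask2


def _scale(img, mask, factor):
    h, w = img.shape
    zi = ndimage.zoom(img, factor, order=1)
    zm = ndimage.zoom(mask.astype(float), factor, order=0)

    def fit(arr, fill):
        out = np.full((h, w), fill, dtype=float)
        hh, ww = arr.shape
        if hh >= h:
            y0, x0 = (hh - h) // 2, (ww - w) // 2
            out[:, :] = arr[y0 : y0 + h, x0 : x0 + w]
        else:
            y0, x0 = (h - hh) // 2, (w - ww) // 2
            out[y0 : y0 + hh, x0 : x0 + ww] = arr
        return out

    return fit(zi, float(np.median(zi))), fit(zm, 0.0)


def online_augment(sample: LabeledPair, cfg: OnlineAugConfig, rng: np.random.Generator) -> LabeledPair:
    """Each configured op fires independently with probability cfg.p."""
    img = np.asarray(sample.image, dtype=float).copy()
    mask = np.asarray(sample.mask, dtype=float).copy()
    for op in cfg.ops:
        if rng.random() >= cfg.p:
            continue
        if op == "hflip":
            img, mask = img[:, ::-1], mask[:, ::-1]
        elif op == "rotation":
            angle = rng.uniform(-cfg.rotation_degrees, cfg.rotation_degrees)
            img, mask = _rotate(img, mask, angle)
        elif op == "translation":
            lim = cfg.shift_fraction * img.shape[0]
            dy, dx = rng.uniform(-lim, lim, size=2)
            img = ndimage.shift(img, (dy, dx), order=1, mode="nearest")
            mask = ndimage.shift(mask, (dy, dx), order=0, mode="constant")
        elif op == "blur":
            img = ndimage.gaussian_filter(img, rng.uniform(*cfg.blur_sigma_range))
        elif op == "gamma":
            img = np.clip(img, 0, 1) ** rng.uniform(*cfg.gamma_range)
        elif op == "noise":
            img = img + rng.normal(0.0, cfg.noise_sigma, img.shape)
        elif op == "scaling":
            img, mask = _scale(img, mask, rng.uniform(*cfg.scale_range))
        else:
            raise ValueError(f"unknown augmentation op {op!r}")
    return LabeledPair(
        image=np.clip(img, 0.0, 1.0),
        mask=(mask >= 0.5).astype(np.uint8),
        class_label=sample.class_label,
    )


# ----------------------------------------------------------------- task models
class SmallClassifier(Module):
    """From-scratch CNN: three stride-2 conv blocks, global pooling, linear head."""

    def __init__(self, rng: np.random.Generator, width: int = 8):
        super().__init__()
        self.features = Sequential(
            Conv2d(1, width, 3, rng, stride=2, padding=1),
            LeakyReLU(0.2),
            Conv2d(width, width * 2, 3, rng, stride=2, padding=1),
            LeakyReLU(0.2),
            Conv2d(width * 2, width * 4, 3, rng, stride=2, padding=1),
            LeakyReLU(0.2),
        )
        from .nn import Dense

        self.head = Dense(width * 4, 1, rng)
        he_init(self, rng)

    def forward(self, x: Tensor) -> Tensor:
        h = self.features(x)
        pooled = h.mean(axis=(2, 3))
        return self.head(pooled).reshape(x.shape[0])  # logit: positive = malignant


class SmallUNet(Module):
    """Width-reduced U-Net-style encoder-decoder with skip connections."""

    def __init__(self, rng: np.random.Generator, width: int = 8):
        super().__init__()
        w = width
        self.enc1 = Sequential(Conv2d(1, w, 3, rng, stride=1, padding=1), ReLU())
        self.down1 = Sequential(Conv2d(w, w * 2, 3, rng, stride=2, padding=1), ReLU())
        self.down2 = Sequential(Conv2d(w * 2, w * 4, 3, rng, stride=2, padding=1), ReLU())
        self.up1 = Sequential(
            ConvTranspose2d(w * 4, w * 2, 3, rng, stride=2, padding=1, output_padding=1), ReLU()
        )
        self.fuse1 = Sequential(Conv2d(w * 4, w * 2, 3, rng, stride=1, padding=1), ReLU())
        self.up2 = Sequential(
            ConvTranspose2d(w * 2, w, 3, rng, stride=2, padding=1, output_padding=1), ReLU()
        )
        self.fuse2 = Sequential(Conv2d(w * 2, w, 3, rng, stride=1, padding=1), ReLU())
        self.out = Conv2d(w, 1, 1, rng)
        he_init(self, rng)

    def forward(self, x: Tensor) -> Tensor:
        e1 = self.enc1(x)
        e2 = self.down1(e1)
        e3 = self.down2(e2)
        d1 = self.fuse1(concat([self.up1(e3), e2], axis=1))
        d2 = self.fuse2(concat([self.up2(d1), e1], axis=1))
        return self.out(d2)  # logits; sigmoid applied in the loss / prediction


def _bce_with_logits(logits: Tensor, targets: np.ndarray, pos_weight: float = 1.0) -> Tensor:
    """Numerically stable binary cross-entropy on logits:
    mean( w(t) * (softplus(x) - t*x) ) with w = pos_weight on positives."""
    t = as_tensor(targets.astype(logits.data.dtype))
    x = logits
    # softplus(x) = max(x, 0) + log(1 + exp(-|x|))
    sp = x.relu() + (1.0 + (-(x.abs())).exp()).log()
    per_elem = sp - t * x
    if pos_weight != 1.0:
        w = 1.0 + (pos_weight - 1.0) * targets.astype(logits.data.dtype)
        per_elem = per_elem * as_tensor(w)
    return per_elem.mean()


# ------------------------------------------------------------------ experiment
@dataclasses.dataclass(frozen=True)
class ExperimentConfig:
    task: str = "segmentation"  # or "classification"
    epochs: int = 6
    batch_size: int = 16
    lr: float = 2e-3
    seed: int = 0
    online_p: float = 0.3
    synthetic_ratio: float = 1.0  # synthetic pairs added per real training pair
    k_folds: int = 3
    model_width: int = 8
    seg_pos_weight: float = 8.0  # lesion-pixel weight in the segmentation BCE


def _train_classifier(train: list[LabeledPair], cfg: ExperimentConfig, aug: OnlineAugConfig | None, rng):
    model = SmallClassifier(np.random.default_rng(int(rng.integers(2**31))), cfg.model_width)
    opt = Adam(model.parameters(), cfg.lr, betas=(0.9, 0.999))
    for _ in range(cfg.epochs):
        order = rng.permutation(len(train))
        for start in range(0, len(train), cfg.batch_size):
            batch = [train[i] for i in order[start : start + cfg.batch_size]]
            if aug is not None:
                batch = [online_augment(p, aug, rng) for p in batch]
            x = np.stack([p.image for p in batch])[:, None].astype(np.float32) * 2 - 1
            y = np.array([1.0 if p.class_label == MALIGNANT else 0.0 for p in batch])
            loss = _bce_with_logits(model(as_tensor(x)), y)
            model.zero_grad()
            loss.backward()
            opt.step()
    return model


def _predict_labels(model: SmallClassifier, pairs: list[LabeledPair]) -> np.ndarray:
    x = np.stack([p.image for p in pairs])[:, None].astype(np.float32) * 2 - 1
    with no_grad():
        logits = model(as_tensor(x)).data
    return (logits > 0).astype(int)


def _train_segmenter(train: list[LabeledPair], cfg: ExperimentConfig, aug: OnlineAugConfig | None, rng):
    model = SmallUNet(np.random.default_rng(int(rng.integers(2**31))), cfg.model_width)
    opt = Adam(model.parameters(), cfg.lr, betas=(0.9, 0.999))
    for _ in range(cfg.epochs):
        order = rng.permutation(len(train))
        for start in range(0, len(train), cfg.batch_size):
            batch = [train[i] for i in order[start : start + cfg.batch_size]]
            if aug is not None:
                batch = [online_augment(p, aug, rng) for p in batch]
            x = np.stack([p.image for p in batch])[:, None].astype(np.float32) * 2 - 1
            y = np.stack([p.mask for p in batch])[:, None].astype(np.float32)
            loss = _bce_with_logits(model(as_tensor(x)), y, pos_weight=cfg.seg_pos_weight)
            model.zero_grad()
            loss.backward()
            opt.step()
    return model


def _predict_masks(model: SmallUNet, pairs: list[LabeledPair], batch: int = 32) -> list[np.ndarray]:
    out = []
    for start in range(0, len(pairs), batch):
        chunk = pairs[start : start + batch]
        x = np.stack([p.image for p in chunk])[:, None].astype(np.float32) * 2 - 1
        with no_grad():
            logits = model(as_tensor(x)).data
        out.extend((1.0 / (1.0 + np.exp(-logits[i, 0])) >= 0.5).astype(np.uint8) for i in range(len(chunk)))
    return out


def _check_no_leakage(train: list[LabeledPair], test: list[LabeledPair]) -> None:
    train_ids = {id(p) for p in train}
    if train_ids & {id(p) for p in test}:
        raise RuntimeError("data leakage: test samples appear in training data")


def run_augmentation_experiment(
    real_train: list[LabeledPair],
    real_test: list[LabeledPair],
    synthetic: list[LabeledPair],
    config: ExperimentConfig,
) -> dict:
    """Train one model per condition (baseline / TA / TA+synthetic) and
    evaluate on the held-out real test set.

    Classification reports mean +/- sd over stratified k-fold resamplings of
    the training set; segmentation trains once per condition.  Returns a
    nested report dict keyed by condition.
    """
    _check_no_leakage(real_train, test=real_test)
    _check_no_leakage(synthetic, test=real_test)
    rng_master = np.random.default_rng(config.seed)
    aug_cfg = (
        OnlineAugConfig.classification() if config.task == "classification" else OnlineAugConfig.segmentation()
    )
    aug_cfg = dataclasses.replace(aug_cfg, p=config.online_p)
    n_syn = int(round(config.synthetic_ratio * len(real_train)))
    synthetic_used = synthetic[:n_syn]
    conditions = {
        "baseline": (real_train, None),
        "ta": (real_train, aug_cfg),
        "ta_synthetic": (real_train + synthetic_used, aug_cfg),
    }
    report: dict = {"task": config.task, "conditions": {}}
    for name, (train, aug) in conditions.items():
        # seed from the training-set size, not the condition name: with zero
        # synthetic pairs the TA and TA+synthetic arms are then bit-identical
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, len(train)]))
        if config.task == "classification":
            labels = [p.class_label for p in train]
            fold_metrics: list[dict] = []
            for tr_idx, _ in kfold_indices(labels, config.k_folds, seed=config.seed):
                fold_train = oversample_balance([train[i] for i in tr_idx], seed=config.seed)
                model = _train_classifier(fold_train, config, aug, rng)
                pred = _predict_labels(model, real_test)
                true = np.array([1 if p.class_label == MALIGNANT else 0 for p in real_test])
                c = confusion(pred, true)
                fold_metrics.append(
                    {"precision": precision(c), "recall": recall(c), "accuracy": accuracy(c), "f1": f1_score(c)}
                )
            agg = {
                k: {"mean": float(np.mean([m[k] for m in fold_metrics])),
                    "sd": float(np.std([m[k] for m in fold_metrics]))}
                for k in fold_metrics[0]
            }
            report["conditions"][name] = agg
        elif config.task == "segmentation":
            model = _train_segmenter(train, config, aug, rng)
            preds = _predict_masks(model, real_test)
            per_class: dict = {}
            for label in CLASSES:
                scores = [
                    dice(pred, p.mask) for pred, p in zip(preds, real_test) if p.class_label == label
                ]
                if scores:
                    per_class[label] = float(np.mean(scores))
            all_scores = [dice(pred, p.mask) for pred, p in zip(preds, real_test)]
            report["conditions"][name] = {"dice": float(np.mean(all_scores)), "dice_per_class": per_class}
        else:
            raise ValueError(f"unknown task {config.task!r}")
    return report
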