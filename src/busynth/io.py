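"""Dataset readers/writers and pairing logic for BUSI-style folders.

Layout convention: per-class subdirectories ("benign", "malignant") holding
8-bit grayscale PNGs named "<stem>.png" with partner "<stem>_mask.png".
Masks are stored with lesion=255/background=0 on disk and lesion=1 in
memory (standard segmentation convention).  Images load to [0, 1] floats;
``to_model_scale``/``from_model_scale`` map between [0, 1] storage scale and
the [-1, 1] range the generators work on.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
from PIL import Image

from .phantom import CLASSES, LabeledPair

__all__ = [
    "DatasetManifest",
    "scan_dataset",
    "load_pair",
    "load_dataset",
    "save_pair",
    "save_image",
    "load_image",
    "to_model_scale",
    "from_model_scale",
]

log = logging.getLogger("busynth.io")

MASK_SUFFIX = "_mask"


def to_model_scale(img01: np.ndarray) -> np.ndarray:
    """[0, 1] storage scale -> [-1, 1] model scale."""
    return img01.astype(np.float32) * 2.0 - 1.0


def from_model_scale(img_pm1: np.ndarray) -> np.ndarray:
    """[-1, 1] model scale -> [0, 1] storage scale (clipped)."""
    return np.clip((np.asarray(img_pm1) + 1.0) / 2.0, 0.0, 1.0)


def save_image(arr01: np.ndarray, path: str | Path) -> None:
    """Write a [0, 1] float array as an 8-bit grayscale PNG."""
    data = np.clip(np.asarray(arr01, dtype=float), 0.0, 1.0)
    Image.fromarray(np.round(data * 255).astype(np.uint8), mode="L").save(path)


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG as a [0, 1] float array (converts non-grayscale with a warning)."""
    with Image.open(path) as im:
        if im.mode != "L":
            log.warning("converting %s from mode %s to grayscale", path, im.mode)
            im = im.convert("L")
        return np.asarray(im, dtype=np.float32) / 255.0


def save_pair(pair: LabeledPair, image_path: str | Path, mask_path: str | Path) -> None:
    save_image(pair.image, image_path)
    save_image(pair.mask.astype(float), mask_path)


class DatasetManifest:
    """Immutable listing of (image, mask, class, id) entries under a root."""

    def __init__(self, root: Path, entries: list[dict]):
        self.root = Path(root)
        self.entries = entries
        ids = [e["id"] for e in entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate ids in manifest")
        digest = hashlib.sha256()
        for e in entries:
            digest.update(f'{e["id"]}|{e["class_label"]}|{e["image"]}|{e["mask"]}'.encode())
        self.checksum = digest.hexdigest()

    def __len__(self):
        return len(self.entries)

    def by_class(self, label: str) -> list[dict]:
        return [e for e in self.entries if e["class_label"] == label]


def scan_dataset(root: str | Path) -> DatasetManifest:
    """Pair images with "<stem>_mask" partners inside class subdirectories.

    Unmatched files are skipped with a logged warning; ordering is
    lexicographic so repeated scans of an unchanged folder are identical.
    """
    root = Path(root)
    if not root.exists():
        raise FileNotFoundError(root)
    entries: list[dict] = []
    for label in CLASSES:
        cls_dir = root / label
        if not cls_dir.is_dir():
            continue
        pngs = sorted(cls_dir.glob("*.png"), key=lambda p: p.name.lower())
        stems = {p.stem.lower(): p for p in pngs}
        for p in pngs:
            stem_l = p.stem.lower()
            if stem_l.endswith(MASK_SUFFIX):
                base = stem_l[: -len(MASK_SUFFIX)]
                if base not in stems:
                    log.warning("mask without image, skipped: %s", p)
                continue
            mask = stems.get(stem_l + MASK_SUFFIX)
            if mask is None:
                log.warning("image without mask, skipped: %s", p)
                continue
            entries.append(
                {
                    "id": f"{label}/{p.stem}",
                    "image": str(p),
                    "mask": str(mask),
                    "class_label": label,
                }
            )
    if not entries:
        raise ValueError(f"no image/mask pairs found under {root}")
    return DatasetManifest(root, entries)


def _resize(arr: np.ndarray, size: int, nearest: bool) -> np.ndarray:
    if arr.shape == (size, size):
        return arr
    im = Image.fromarray((np.clip(arr, 0, 1) * 255).astype(np.uint8), mode="L")
    im = im.resize((size, size), Image.NEAREST if nearest else Image.BILINEAR)
    return np.asarray(im, dtype=np.float32) / 255.0


def load_pair(entry: dict, image_size: int | None = None) -> LabeledPair:
    """Load one manifest entry; optionally resize (bilinear image, nearest
    mask, mask re-binarized at 0.5)."""
    img = load_image(entry["image"])
    mask = load_image(entry["mask"])
    if image_size is not None:
        img = _resize(img, image_size, nearest=False)
        mask = _resize(mask, image_size, nearest=True)
    mask_bin = (mask >= 0.5).astype(np.uint8)
    return LabeledPair(image=img, mask=mask_bin, class_label=entry["class_label"])


def load_dataset(root: str | Path, image_size: int | None = None) -> list[LabeledPair]:
    manifest = scan_dataset(root)
    return [load_pair(e, image_size=image_size) for e in manifest.entries]
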