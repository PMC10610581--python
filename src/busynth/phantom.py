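"""Procedural ultrasound-like phantoms: class-conditional lesion masks and
speckled B-mode-style textures.

The generator emulates the statistical structure of annotated breast
ultrasound datasets: benign lesions have smooth, near-elliptical contours
while malignant lesions are irregular and spiculated; lesion interiors are
hypoechoic (darker than surrounding tissue); the background is layered
tissue carrying multiplicative speckle; an optional posterior shadow
attenuates the columns below the lesion.  Masks are star-convex radial
curves

    r(theta) = r0 * (1 + sum_k a_k cos(k*theta + phi_k)),

which guarantees a single simply-connected foreground component and exposes
one roughness knob that mirrors the benign/malignant morphology difference.
All outputs are pure functions of (spec, seed).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import draw

__all__ = [
    "PhantomSpec",
    "LabeledPair",
    "default_spec",
    "generate_mask",
    "base_field",
    "render_image",
    "generate_pair",
    "make_dataset",
]

BENIGN = "benign"
MALIGNANT = "malignant"
CLASSES = (BENIGN, MALIGNANT)


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one phantom class.

    roughness_amplitude is the relative radial perturbation scale (0 = exact
    ellipse); lesion_contrast in (0,1) multiplies the interior intensity
    (lower = darker lesion); speckle_shape is the gamma shape parameter of
    the mean-one multiplicative speckle (None or inf = noise-free);
    psf_sigma is the Gaussian blur of the imaging point-spread function in
    pixels; shadow_strength in [0,1] attenuates columns below the lesion.
    """

    image_size: int = 64
    class_label: str = BENIGN
    area_fraction_range: tuple[float, float] = (0.04, 0.14)
    roughness_amplitude: float = 0.05
    roughness_harmonics: int = 3
    lesion_contrast: float = 0.35
    speckle_shape: float | None = 16.0
    psf_sigma: float = 0.8
    shadow_strength: float = 0.25
    eccentricity_range: tuple[float, float] = (1.2, 1.8)
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.area_fraction_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("area_fraction_range must lie inside (0, 1)")
        if not 0.0 < self.lesion_contrast < 1.0:
            raise ValueError("lesion_contrast must lie in (0, 1)")
        if self.class_label not in CLASSES:
            raise ValueError(f"class_label must be one of {CLASSES}")
        if self.roughness_amplitude < 0 or self.roughness_harmonics < 0:
            raise ValueError("roughness parameters must be non-negative")
        if not 0.0 <= self.shadow_strength <= 1.0:
            raise ValueError("shadow_strength must lie in [0, 1]")


@dataclasses.dataclass
class LabeledPair:
    """One grayscale image + binary lesion mask + class label."""

    image: np.ndarray  # float, [0, 1]
    mask: np.ndarray  # uint8, {0, 1}
    class_label: str

    def __post_init__(self):
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask shapes differ")


def default_spec(class_label: str, image_size: int = 64, seed: int = 0, **overrides) -> PhantomSpec:
    """Default study conditions per class: benign contours are smooth and
    elliptical, malignant contours irregular/spiculated with more harmonics."""
    if class_label == BENIGN:
        base = dict(roughness_amplitude=0.05, roughness_harmonics=3, lesion_contrast=0.35)
    elif class_label == MALIGNANT:
        base = dict(roughness_amplitude=0.25, roughness_harmonics=8, lesion_contrast=0.30)
    else:
        raise ValueError(f"unknown class {class_label!r}")
    base.update(overrides)
    return PhantomSpec(image_size=image_size, class_label=class_label, seed=seed, **base)


_N_THETA = 720
_MAX_TRIES = 30


def _radial_contour(spec: PhantomSpec, rng: np.random.Generator):
    """Sample polygon vertices of one star-convex lesion contour."""
    s = spec.image_size
    lo, hi = spec.area_fraction_range
    # keep the target off the band edges so rasterization error stays inside
    pad = 0.08 * (hi - lo)
    target_frac = rng.uniform(lo + pad, hi - pad)
    theta = np.linspace(0.0, 2 * np.pi, _N_THETA, endpoint=False)
    pert = np.zeros(_N_THETA)
    for k in range(1, spec.roughness_harmonics + 1):
        # ~1/sqrt(k) decay keeps high harmonics visible (spiculation) but bounded
        a_k = spec.roughness_amplitude * rng.normal() / np.sqrt(k)
        phi_k = rng.uniform(0, 2 * np.pi)
        pert += a_k * np.cos((k + 1) * theta + phi_k)
    pert = np.clip(pert, -0.65, 0.65)
    ecc = rng.uniform(*spec.eccentricity_range)
    angle = rng.uniform(0, np.pi)
    # unit-area base ellipse axes with eccentricity ratio ecc
    ax_a, ax_b = np.sqrt(ecc), 1.0 / np.sqrt(ecc)
    r0 = np.sqrt(target_frac * s * s / np.pi)
    ex = ax_a * np.cos(theta)
    ey = ax_b * np.sin(theta)
    radii = r0 * (1.0 + pert)
    xs = radii * (ex * np.cos(angle) - ey * np.sin(angle))
    ys = radii * (ex * np.sin(angle) + ey * np.cos(angle))
    # rescale so the polygon area hits the target exactly (the radial
    # perturbation inflates area by ~sum a_k^2 / 2 otherwise)
    shoelace = 0.5 * abs(np.dot(xs, np.roll(ys, -1)) - np.dot(ys, np.roll(xs, -1)))
    scale = np.sqrt(target_frac * s * s / shoelace)
    xs, ys = xs * scale, ys * scale
    margin = 2.0
    half_w = (xs.max() - xs.min()) / 2
    half_h = (ys.max() - ys.min()) / 2
    cx_lo, cx_hi = half_w + margin, s - half_w - margin
    cy_lo, cy_hi = half_h + margin, s - half_h - margin
    if cx_lo >= cx_hi or cy_lo >= cy_hi:
        return None
    cx = rng.uniform(cx_lo, cx_hi)
    cy = rng.uniform(cy_lo, cy_hi)
    return ys + cy, xs + cx


def generate_mask(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Rasterize one lesion mask; rejection-resamples until the measured
    area fraction lands in ``spec.area_fraction_range``."""
    s = spec.image_size
    lo, hi = spec.area_fraction_range
    for _ in range(_MAX_TRIES):
        contour = _radial_contour(spec, rng)
        if contour is None:
            continue
        rows, cols = contour
        rr, cc = draw.polygon(rows, cols, shape=(s, s))
        mask = np.zeros((s, s), dtype=np.uint8)
        mask[rr, cc] = 1
        frac = mask.mean()
        if lo <= frac <= hi and ndimage.label(mask)[1] == 1:
            return mask
    raise RuntimeError(
        f"could not draw a mask with area fraction in [{lo}, {hi}] after {_MAX_TRIES} tries"
    )


def base_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Deterministic-given-rng layered background tissue field in (0, 1).

    A gentle depth gradient plus smooth band structure, the large-scale
    echotexture the speckle later modulates.
    """
    s = spec.image_size
    rows = np.linspace(0.0, 1.0, s)[:, None]
    depth = 0.62 - 0.18 * rows  # slight attenuation with depth
    n_bands = rng.integers(2, 5)
    bands = np.zeros((s, 1))
    for _ in range(int(n_bands)):
        freq = rng.uniform(1.0, 3.0)
        phase = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(0.02, 0.07)
        bands += amp * np.sin(2 * np.pi * freq * rows + phase)
    lowfreq = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (s, s)), sigma=s / 8.0)
    lowfreq *= 0.08 / (lowfreq.std() + 1e-9)
    field = depth + bands + lowfreq
    return np.clip(field, 0.05, 0.95)


def render_image(mask: np.ndarray, spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Render the speckled grayscale image for ``mask``; values in [0, 1]."""
    s = spec.image_size
    if mask.shape != (s, s):
        raise ValueError(f"mask shape {mask.shape} does not match spec.image_size {s}")
    field = base_field(spec, rng)
    soft = ndimage.gaussian_filter(mask.astype(float), sigma=1.0)
    signal = field * (1.0 - (1.0 - spec.lesion_contrast) * soft)
    shape = spec.speckle_shape
    if shape is not None and np.isfinite(shape):
        speckle = rng.gamma(shape, 1.0 / shape, size=(s, s))  # mean-one multiplicative
    else:
        speckle = 1.0
    img = signal * speckle
    if spec.psf_sigma > 0:
        img = ndimage.gaussian_filter(img, sigma=spec.psf_sigma)
    if spec.shadow_strength > 0 and mask.any():
        cols_hit = mask.any(axis=0)
        bottom = np.where(mask.any(axis=1))[0].max()
        atten = np.ones((s, s))
        depth_below = np.clip(np.arange(s)[:, None] - bottom, 0, None) / max(s - bottom - 1, 1)
        ramp = spec.shadow_strength * np.clip(depth_below * 3.0, 0.0, 1.0)
        atten -= ramp * cols_hit[None, :]
        img = img * atten
    return np.clip(img, 0.0, 1.0)


def generate_pair(spec: PhantomSpec, rng: np.random.Generator) -> LabeledPair:
    mask = generate_mask(spec, rng)
    image = render_image(mask, spec, rng)
    return LabeledPair(image=image, mask=mask, class_label=spec.class_label)


def make_dataset(
    n_benign: int,
    n_malignant: int,
    out_dir: str | Path,
    seed: int = 0,
    image_size: int = 64,
    spec_overrides: dict | None = None,
) -> list[dict]:
    """Write a BUSI-style directory of phantom pairs; returns the manifest.

    Layout: ``<out>/<class>/<class>_<i>.png`` + ``..._mask.png``.  Fully
    reproducible: every pair is generated from a child seed spawned from
    ``seed``.
    """
    from . import io as _io  # local import to avoid a cycle at module load

    if n_benign < 0 or n_malignant < 0:
        raise ValueError("counts must be non-negative")
    out = Path(out_dir)
    overrides = spec_overrides or {}
    manifest: list[dict] = []
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_benign + n_malignant)
    jobs = [(BENIGN, i) for i in range(n_benign)] + [(MALIGNANT, i) for i in range(n_malignant)]
    for child, (label, i) in zip(children, jobs):
        spec = default_spec(label, image_size=image_size, seed=seed, **overrides.get(label, {}))
        rng = np.random.default_rng(child)
        pair = generate_pair(spec, rng)
        cls_dir = out / label
        cls_dir.mkdir(parents=True, exist_ok=True)
        stem = f"{label}_{i:04d}"
        img_path = cls_dir / f"{stem}.png"
        mask_path = cls_dir / f"{stem}_mask.png"
        _io.save_pair(pair, img_path, mask_path)
        manifest.append(
            {
                "id": stem,
                "image": str(img_path),
                "mask": str(mask_path),
                "class_label": label,
            }
        )
    if manifest:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
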