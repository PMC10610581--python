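"""Generative-model evaluation: FID, KID and multi-scale SSIM.

FID is the Frechet (Wasserstein-2) distance between Gaussian fits to two
embedding sets:

    FID = ||mu_a - mu_b||^2 + Tr(S_a + S_b - 2 (S_a S_b)^{1/2}).

KID is the unbiased squared maximum mean discrepancy under a polynomial
kernel; being unbiased it may come out slightly negative.  MS-SSIM follows
the standard pyramid construction: contrast/structure terms at every scale,
the luminance term at the coarsest scale only.  Embeddings come from a
pluggable extractor registry whose built-ins (downsampled pixels; a
fixed-seed untrained convolutional embedder) need no downloads; reported
results depend on the extractor, so the extractor id travels with every
FeatureSet.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import linalg, signal

from .nn import Conv2d, LeakyReLU, Module, Sequential, as_tensor, he_init
from .nn.autograd import no_grad

__all__ = [
    "FeatureSet",
    "FeatureMoments",
    "MsSsimConfig",
    "KernelConfig",
    "register_extractor",
    "embed",
    "moments",
    "fid",
    "kid",
    "ssim",
    "ms_ssim",
    "internal_diversity",
    "max_scales_for",
    "CANONICAL_WEIGHTS",
]


# ------------------------------------------------------------------ embeddings
@dataclasses.dataclass
class FeatureSet:
    vectors: np.ndarray  # (n, d)
    extractor_id: str

    def __post_init__(self):
        self.vectors = np.atleast_2d(np.asarray(self.vectors, dtype=np.float64))
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("non-finite feature values")

    def __len__(self):
        return len(self.vectors)


@dataclasses.dataclass
class FeatureMoments:
    mu: np.ndarray
    sigma: np.ndarray


def moments(features: FeatureSet | np.ndarray) -> FeatureMoments:
    v = features.vectors if isinstance(features, FeatureSet) else np.asarray(features, dtype=np.float64)
    if len(v) < 2:
        raise ValueError("moment estimation needs at least 2 vectors")
    return FeatureMoments(mu=v.mean(axis=0), sigma=np.cov(v, rowvar=False).reshape(v.shape[1], v.shape[1]))


def _pixel_extractor(images: np.ndarray, side: int = 8) -> np.ndarray:
    """Local-mean downsample to side x side, flattened."""
    n, h, w = images.shape
    fh, fw = h // side, w // side
    if fh < 1 or fw < 1:
        raise ValueError(f"images smaller than {side}x{side}")
    crop = images[:, : fh * side, : fw * side]
    pooled = crop.reshape(n, side, fh, side, fw).mean(axis=(2, 4))
    return pooled.reshape(n, side * side)


class _RandomConvEmbedder(Module):
    """Untrained conv net with weights fixed by seed; a cheap, deterministic
    stand-in for a pretrained embedding network.

    Weights use He-scaled init — the variance-preserving choice; with tiny
    (GAN-style 0.02) init the activations collapse toward zero after three
    layers and every embedding degenerates to the same point.
    """

    def __init__(self, seed: int = 7, width: int = 16, out_dim: int = 32):
        super().__init__()
        rng = np.random.default_rng(seed)
        layers = [
            Conv2d(1, width, 3, rng, stride=2, padding=1),
            LeakyReLU(0.2),
            Conv2d(width, width * 2, 3, rng, stride=2, padding=1),
            LeakyReLU(0.2),
            Conv2d(width * 2, out_dim, 3, rng, stride=2, padding=1),
        ]
        self.net = he_init(Sequential(*layers), rng)
        self.eval()

    def embed(self, images: np.ndarray) -> np.ndarray:
        x = as_tensor(images[:, None].astype(np.float32))
        with no_grad():
            feats = self.net(x).data
        # mean and dispersion per channel: pooled means alone cancel the
        # signed activations of a random net
        mu = feats.mean(axis=(2, 3))
        sd = feats.std(axis=(2, 3))
        return np.concatenate([mu, sd], axis=1).astype(np.float64)


_EXTRACTORS: dict[str, object] = {}


def register_extractor(name: str, fn) -> None:
    _EXTRACTORS[name] = fn


register_extractor("pixels", _pixel_extractor)
_conv_embedder_cache: dict[int, _RandomConvEmbedder] = {}


def _conv_extractor(images: np.ndarray, seed: int = 7) -> np.ndarray:
    if seed not in _conv_embedder_cache:
        _conv_embedder_cache[seed] = _RandomConvEmbedder(seed=seed)
    return _conv_embedder_cache[seed].embed(images)


register_extractor("randconv", _conv_extractor)


def embed(images: np.ndarray | list, extractor: str = "randconv", **kwargs) -> FeatureSet:
    """Images (n, H, W) in [0, 1] -> FeatureSet via a registered extractor."""
    if extractor not in _EXTRACTORS:
        raise KeyError(f"unknown extractor {extractor!r}; registered: {sorted(_EXTRACTORS)}")
    images = np.stack([np.asarray(im, dtype=np.float64) for im in images])
    return FeatureSet(vectors=_EXTRACTORS[extractor](images, **kwargs), extractor_id=extractor)


# ------------------------------------------------------------------------- FID
def _sqrtm_psd(mat: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    """Symmetric PSD square root by eigendecomposition, clipping small
    negative eigenvalues that arise numerically."""
    sym = (mat + mat.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    vals = np.clip(vals, 0.0, None)
    return (vecs * np.sqrt(vals + eps * 0.0)) @ vecs.T


def fid(a: FeatureSet | FeatureMoments, b: FeatureSet | FeatureMoments) -> float:
    """Frechet distance between Gaussian fits to two feature sets."""
    ma = a if isinstance(a, FeatureMoments) else moments(a)
    mb = b if isinstance(b, FeatureMoments) else moments(b)
    if ma.mu.shape != mb.mu.shape:
        raise ValueError("feature dimensions differ")
    diff = ma.mu - mb.mu
    sa_half = _sqrtm_psd(ma.sigma)
    inner = _sqrtm_psd(sa_half @ mb.sigma @ sa_half)
    value = float(diff @ diff + np.trace(ma.sigma) + np.trace(mb.sigma) - 2.0 * np.trace(inner))
    return max(value, 0.0)


# ------------------------------------------------------------------------- KID
@dataclasses.dataclass(frozen=True)
class KernelConfig:
    """Polynomial kernel k(x, y) = (scale * <x, y> + offset)^degree; the
    conventional KID kernel is degree 3, scale 1/d, offset 1."""

    degree: int = 3
    scale: float | None = None  # None -> 1/dim
    offset: float = 1.0


def _kernel_matrix(x: np.ndarray, y: np.ndarray, cfg: KernelConfig) -> np.ndarray:
    scale = cfg.scale if cfg.scale is not None else 1.0 / x.shape[1]
    return (scale * (x @ y.T) + cfg.offset) ** cfg.degree


def kid(a: FeatureSet, b: FeatureSet, kcfg: KernelConfig | None = None) -> float:
    """Unbiased MMD^2 estimate between two embedding sets (may be < 0)."""
    kcfg = kcfg or KernelConfig()
    va, vb = a.vectors, b.vectors
    m, n = len(va), len(vb)
    if m < 2 or n < 2:
        raise ValueError("KID needs at least 2 vectors per set")
    if va.shape[1] != vb.shape[1]:
        raise ValueError("feature dimensions differ")
    kaa = _kernel_matrix(va, va, kcfg)
    kbb = _kernel_matrix(vb, vb, kcfg)
    kab = _kernel_matrix(va, vb, kcfg)
    term_a = (kaa.sum() - np.trace(kaa)) / (m * (m - 1))
    term_b = (kbb.sum() - np.trace(kbb)) / (n * (n - 1))
    term_ab = 2.0 * kab.mean()
    return float(term_a + term_b - term_ab)


# --------------------------------------------------------------------- MS-SSIM
CANONICAL_WEIGHTS = (0.0448, 0.2856, 0.3001, 0.2363, 0.1333)


@dataclasses.dataclass(frozen=True)
class MsSsimConfig:
    """Scale weights act as the exponents alpha (luminance, coarsest scale
    only), beta and gamma (contrast and structure, all scales); the
    conventional setting ties beta_j = gamma_j = w_j."""

    scales: int = 5
    weights: tuple[float, ...] | None = None  # None -> canonical, renormalized
    window: int = 11
    sigma: float = 1.5
    k1: float = 0.01
    k2: float = 0.03
    data_range: float = 1.0

    def scale_weights(self) -> np.ndarray:
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if len(w) != self.scales or np.any(w <= 0):
                raise ValueError("need one positive weight per scale")
            return w
        if self.scales > len(CANONICAL_WEIGHTS):
            raise ValueError(f"no canonical weights beyond {len(CANONICAL_WEIGHTS)} scales")
        w = np.asarray(CANONICAL_WEIGHTS[: self.scales], dtype=float)
        return w / w.sum()


def max_scales_for(shape: tuple[int, int], window: int = 11) -> int:
    """Largest scale count the image supports (min side >= window * 2^(M-1))."""
    m = 1
    while min(shape) >= window * (1 << m):
        m += 1
    return m


def _gaussian_window(size: int, sigma: float) -> np.ndarray:
    g = signal.windows.gaussian(size, sigma)
    g /= g.sum()
    return g


def _local_stats(a: np.ndarray, b: np.ndarray, win: np.ndarray):
    def filt(img):
        return signal.convolve2d(
            signal.convolve2d(img, win[:, None], mode="valid"), win[None, :], mode="valid"
        )

    mu_a, mu_b = filt(a), filt(b)
    var_a = filt(a * a) - mu_a**2
    var_b = filt(b * b) - mu_b**2
    cov = filt(a * b) - mu_a * mu_b
    return mu_a, mu_b, np.maximum(var_a, 0), np.maximum(var_b, 0), cov


def _lcs_maps(a: np.ndarray, b: np.ndarray, cfg: MsSsimConfig):
    c1 = (cfg.k1 * cfg.data_range) ** 2
    c2 = (cfg.k2 * cfg.data_range) ** 2
    c3 = c2 / 2.0
    win = _gaussian_window(cfg.window, cfg.sigma)
    mu_a, mu_b, var_a, var_b, cov = _local_stats(a, b, win)
    lum = (2 * mu_a * mu_b + c1) / (mu_a**2 + mu_b**2 + c1)
    sd_a, sd_b = np.sqrt(var_a), np.sqrt(var_b)
    con = (2 * sd_a * sd_b + c2) / (var_a + var_b + c2)
    struct = (cov + c3) / (sd_a * sd_b + c3)
    return lum, con, struct


def ssim(a: np.ndarray, b: np.ndarray, cfg: MsSsimConfig | None = None) -> float:
    """Plain single-scale SSIM (Gaussian-weighted local statistics)."""
    cfg = cfg or MsSsimConfig(scales=1)
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("image shapes differ")
    lum, con, struct = _lcs_maps(a, b, cfg)
    return float(np.mean(lum * con * struct))


def _downsample2(img: np.ndarray) -> np.ndarray:
    h, w = img.shape
    crop = img[: h - h % 2, : w - w % 2]
    return crop.reshape(h // 2, 2, w // 2, 2).mean(axis=(1, 3))


def ms_ssim(a: np.ndarray, b: np.ndarray, cfg: MsSsimConfig | None = None) -> float:
    """Multi-scale SSIM with dyadic downsampling between scales."""
    cfg = cfg or MsSsimConfig()
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("image shapes differ")
    supported = max_scales_for(a.shape, cfg.window)
    if cfg.scales > supported:
        raise ValueError(
            f"image {a.shape} supports at most M={supported} scales with window "
            f"{cfg.window}; reduce MsSsimConfig.scales to {supported}"
        )
    weights = cfg.scale_weights()
    value = 1.0
    for level in range(cfg.scales):
        lum, con, struct = _lcs_maps(a, b, cfg)
        cs = np.clip(con, 0, None) * np.clip(struct, 0, None)
        if level == cfg.scales - 1:
            # luminance enters at the coarsest scale only
            value *= np.clip(np.mean(lum * cs), 0, None) ** weights[level]
        else:
            value *= np.clip(np.mean(cs), 0, None) ** weights[level]
            a, b = _downsample2(a), _downsample2(b)
    return float(value)


def internal_diversity(
    images: np.ndarray | list,
    n_pairs: int = 100,
    seed: int = 0,
    cfg: MsSsimConfig | None = None,
) -> float:
    """Mean pairwise MS-SSIM over sampled distinct pairs (lower = more
    diverse generated sets)."""
    images = [np.asarray(im, dtype=np.float64) for im in images]
    n = len(images)
    if n < 2:
        raise ValueError("need at least 2 images")
    if cfg is None:
        m = min(max_scales_for(images[0].shape), len(CANONICAL_WEIGHTS))
        cfg = MsSsimConfig(scales=m)
    all_pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    rng = np.random.default_rng(seed)
    if len(all_pairs) > n_pairs:
        chosen = rng.choice(len(all_pairs), size=n_pairs, replace=False)
        pairs = [all_pairs[int(c)] for c in chosen]
    else:
        pairs = all_pairs
    return float(np.mean([ms_ssim(images[i], images[j], cfg) for i, j in pairs]))
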