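"""Pseudo-color rendering, per-image feature extraction and PCA reduction.

Lifetime maps are rendered through a warm-to-cool colormap (orange = short
lifetime / low bound fraction, blue = long / high), encoded into a
fixed-length descriptor with a convolutional backend, and reduced with PCA
before clustering.  The default backend is a fixed-seed random
convolutional filter bank with the same output geometry as the final
pooled convolutional layer of AlexNet (256 x 6 x 6 = 9216 features per
three-channel image), so no pre-trained weights are ever required; an
AlexNet backend is available when torch/torchvision are installed.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

__all__ = ["ColormapSpec", "TM_COLORMAP", "A2_COLORMAP", "PseudocolorImage",
           "FeatureVector", "PCAModel", "render_pseudocolor",
           "stack_modalities", "extract_features", "fit_pca", "transform_pca",
           "tsne_embed", "N_FEATURES_PER_MODALITY"]

N_FEATURES_PER_MODALITY = 9216          # 256 filters x 36 pooled values
_PATCH = 8
_STRIDE = 4
_SIDE = 48
_N_QUANTILES = 36
_N_FILTERS = 256


@dataclass(frozen=True)
class ColormapSpec:
    """Ordered color anchors over a value range (warm at min, cool at max)."""

    value_range: tuple
    stops: tuple = (
        (1.00, 0.50, 0.00),   # orange
        (1.00, 1.00, 0.00),   # yellow
        (0.00, 0.80, 0.00),   # green
        (0.00, 0.90, 0.90),   # cyan
        (0.00, 0.20, 1.00),   # blue
    )

    def __post_init__(self) -> None:
        lo, hi = self.value_range
        if not lo < hi:
            raise ValueError("value_range must satisfy min < max")
        if len(self.stops) < 2:
            raise ValueError("need at least two color stops")


#: Default display ranges (package constants, overridable per call).
TM_COLORMAP = ColormapSpec(value_range=(400.0, 1400.0))
A2_COLORMAP = ColormapSpec(value_range=(0.0, 100.0))


@dataclass
class PseudocolorImage:
    """RGB (3-channel) or tm & a2 stacked (6-channel) image in [0, 1]."""

    pixels: np.ndarray            # (ny, nx, channels)
    modality: str                 # "tm" | "a2" | "tm&a2"

    def __post_init__(self) -> None:
        if self.pixels.ndim != 3 or self.pixels.shape[2] not in (3, 6):
            raise ValueError("pixels must be (ny, nx, 3) or (ny, nx, 6)")

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[2]


@dataclass
class FeatureVector:
    values: np.ndarray
    backend: str
    modality: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if not np.isfinite(self.values).all():
            raise ValueError("feature values must be finite")


@dataclass
class PCAModel:
    """Mean + orthonormal components retaining a target variance fraction."""

    mean: np.ndarray
    components: np.ndarray        # (k, d), orthonormal rows
    explained_variance_ratio: np.ndarray
    preserved_fraction: float

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


def render_pseudocolor(values: np.ndarray, mask, cmap: ColormapSpec,
                       modality: str = "tm") -> PseudocolorImage:
    """Map scalar values through the colormap; off-mask pixels are black."""
    values = np.asarray(values, dtype=np.float64)
    m = np.asarray(getattr(mask, "mask", mask), dtype=bool)
    if m.shape != values.shape:
        raise ValueError("mask and values must share a shape")
    if not np.isfinite(values[m]).all():
        raise ValueError("masked values must be finite")
    lo, hi = cmap.value_range
    t = np.clip((values - lo) / (hi - lo), 0.0, 1.0)
    pos = np.linspace(0.0, 1.0, len(cmap.stops))
    stops = np.asarray(cmap.stops, dtype=np.float64)
    rgb = np.stack([np.interp(t, pos, stops[:, c]) for c in range(3)], axis=-1)
    rgb[~m] = 0.0
    return PseudocolorImage(pixels=rgb, modality=modality)


def stack_modalities(tm_image: PseudocolorImage,
                     a2_image: PseudocolorImage) -> PseudocolorImage:
    """Six-channel tm & a2 stack of one field of view."""
    if tm_image.pixels.shape != a2_image.pixels.shape:
        raise ValueError("modalities must share image shape")
    return PseudocolorImage(
        pixels=np.concatenate([tm_image.pixels, a2_image.pixels], axis=2),
        modality="tm&a2")


from functools import lru_cache


@lru_cache(maxsize=8)
def _bank_filters(seed: int) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    d = _PATCH * _PATCH * 3
    W = rng.standard_normal((_N_FILTERS, d)) / np.sqrt(d)
    b = rng.standard_normal(_N_FILTERS) * 0.05
    return W, b


def _bank_features(rgb: np.ndarray, seed: int) -> np.ndarray:
    """Random conv filter bank with quantile pooling.

    The image is cropped to the bounding box of its non-black (cell)
    region and resized to 48 x 48; 256 fixed random 8 x 8 x 3 filters are
    evaluated with ReLU on overlapping patches (stride 4), and each
    filter's response distribution over the image is summarised by 36
    evenly spaced quantiles.  Pooling over patch *distributions* rather
    than patch *positions* makes the descriptor insensitive to where on
    the slide the cells happen to lie, which is nuisance variation.  The
    2-normalised result has the same 256 x 36 = 9216 geometry as the
    final pooled convolutional activation of AlexNet.
    """
    nonblack = rgb.any(axis=2)
    if nonblack.any():
        ys, xs = np.where(nonblack)
        rgb = rgb[ys.min():ys.max() + 1, xs.min():xs.max() + 1]
    small = resize(rgb, (_SIDE, _SIDE, 3), order=1, mode="reflect",
                   anti_aliasing=True, preserve_range=True)
    W, b = _bank_filters(seed)
    pos = range(0, _SIDE - _PATCH + 1, _STRIDE)
    resp = np.empty((_N_FILTERS, len(pos) ** 2))
    k = 0
    for gy in pos:
        for gx in pos:
            patch = small[gy:gy + _PATCH, gx:gx + _PATCH, :].ravel()
            resp[:, k] = np.maximum(W @ patch + b, 0.0)  # ReLU
            k += 1
    pooled = np.quantile(resp, np.linspace(0.0, 1.0, _N_QUANTILES), axis=1).T
    v = pooled.ravel()
    norm = np.linalg.norm(v)
    return v / norm if norm > 0 else v


def _alexnet_features(rgb: np.ndarray) -> np.ndarray:
    try:
        import torch
        from torchvision import models, transforms
    except ImportError as exc:  # pragma: no cover - optional backend
        raise ImportError(
            "the cnn_alexnet backend needs torch and torchvision; install "
            "the 'cnn' extra or use backend='deterministic_bank'") from exc
    net = models.alexnet(weights=models.AlexNet_Weights.IMAGENET1K_V1)
    net.eval()
    prep = transforms.Compose([
        transforms.ToTensor(),
        transforms.Resize((224, 224), antialias=True),
        transforms.Normalize(mean=[0.485, 0.456, 0.406],
                             std=[0.229, 0.224, 0.225]),
    ])
    with torch.no_grad():
        x = prep((rgb * 255).astype(np.uint8)).unsqueeze(0)
        feats = net.avgpool(net.features(x))
    return feats.numpy().ravel()


def extract_features(image: PseudocolorImage,
                     backend: str = "deterministic_bank",
                     seed: int = 0) -> FeatureVector:
    """Fixed-length descriptor; 6-channel input is encoded per modality
    and concatenated (9216 features per 3-channel image)."""
    if backend not in ("deterministic_bank", "cnn_alexnet"):
        raise ValueError(f"unknown backend {backend!r}")
    fn = (_alexnet_features if backend == "cnn_alexnet"
          else lambda rgb: _bank_features(rgb, seed))
    px = image.pixels
    if image.n_channels == 3:
        vals = fn(px)
    else:
        vals = np.concatenate([fn(px[:, :, :3]), fn(px[:, :, 3:])])
    return FeatureVector(values=vals, backend=backend, modality=image.modality)


def fit_pca(features: np.ndarray, preserved_fraction: float = 0.30) -> PCAModel:
    """PCA retaining the minimal leading set reaching the variance target."""
    if not 0.0 < preserved_fraction <= 1.0:
        raise ValueError("preserved_fraction must lie in (0, 1]")
    X = np.asarray(features, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >= 2 training vectors")
    from sklearn.decomposition import PCA
    pca = PCA(svd_solver="full")
    pca.fit(X)
    evr = pca.explained_variance_ratio_
    cum = np.cumsum(evr)
    nonzero = pca.explained_variance_ > 1e-12
    if preserved_fraction >= 1.0:
        k = int(nonzero.sum())
    else:
        k = int(np.searchsorted(cum, preserved_fraction - 1e-12) + 1)
        k = min(k, len(evr))
    return PCAModel(mean=pca.mean_.copy(),
                    components=pca.components_[:k].copy(),
                    explained_variance_ratio=evr[:k].copy(),
                    preserved_fraction=preserved_fraction)


def transform_pca(model: PCAModel, features: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(features, dtype=np.float64))
    if X.shape[1] != model.mean.shape[0]:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match the model "
            f"({model.mean.shape[0]})")
    return (X - model.mean) @ model.components.T


def tsne_embed(reduced: np.ndarray, perplexity: float = 30.0,
               seed: int = 0) -> np.ndarray:
    """2-D t-SNE embedding for visualisation only."""
    X = np.asarray(reduced, dtype=np.float64)
    if X.shape[0] < 3 * perplexity:
        raise ValueError(
            f"need at least {int(3 * perplexity)} points for perplexity "
            f"{perplexity}")
    from sklearn.manifold import TSNE
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=seed,
                init="pca")
    return tsne.fit_transform(X)
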