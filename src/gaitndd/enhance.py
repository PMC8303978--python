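"""PCA feature enhancement of spectrogram images.

An image is projected onto the leading principal components of a training
image population and reconstructed from them, suppressing within-class
pixel variation while keeping the dominant (between-class) structure.
Images are reduced to a single luminance channel before the
decomposition (a colormapped raster is rank-deficient in hue) and
re-expanded to 3 channels afterwards; per-channel PCA is available via
``channel_mode="per_channel"``.

The decomposition is fit on training-fold images only by default; a
``fit_population="all"`` mode (fit on the full dataset before
cross-validation) exists for comparison but leaks test information and is
not recommended.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from .images import SpectrogramImage


@dataclass
class PCAModel:
    """Frozen principal-component basis of an image population."""

    mean: np.ndarray  # (D,)
    components: np.ndarray  # (k, D), orthonormal rows
    explained_variance_ratio: np.ndarray  # (k,)
    k: int

    def reconstruct(self, flat: np.ndarray) -> np.ndarray:
        """Project centered vectors on the basis and reconstruct."""
        centered = flat - self.mean
        if self.k == 0:
            return np.broadcast_to(self.mean, flat.shape).copy()
        coords = centered @ self.components.T
        return coords @ self.components + self.mean


def _to_luminance(images: np.ndarray) -> np.ndarray:
    """(n, H, W, 3) -> (n, H*W) mean-channel luminance."""
    return images.mean(axis=3).reshape(images.shape[0], -1)


def fit_pca(flat: np.ndarray, retain: float | int = 0.95) -> PCAModel:
    """Fit a PCA basis on flattened training vectors (n x D).

    ``retain`` is either a variance fraction in (0, 1] (the smallest
    component count reaching it is kept) or an explicit component count.
    """
    flat = np.asarray(flat, dtype=float)
    if flat.ndim != 2 or flat.shape[0] < 2:
        raise ValueError("need an n x D matrix with n >= 2")
    n, D = flat.shape
    mean = flat.mean(axis=0)
    total_var = ((flat - mean) ** 2).sum() / (n - 1)
    scale = float(np.abs(flat).max()) ** 2 + 1e-30
    if total_var <= 1e-12 * scale:
        # identical images: zero covariance, no components to keep
        return PCAModel(
            mean=mean,
            components=np.empty((0, D)),
            explained_variance_ratio=np.empty(0),
            k=0,
        )
    max_k = min(n - 1, D)
    if isinstance(retain, (int, np.integer)) and not isinstance(retain, bool):
        k = int(min(retain, max_k))
        pca = PCA(n_components=max_k if k > 0 else 1).fit(flat)
        evr = pca.explained_variance_ratio_[:k]
        comps = pca.components_[:k]
    else:
        retain = float(retain)
        if not 0 < retain <= 1:
            raise ValueError("retained variance fraction must be in (0, 1]")
        pca = PCA(n_components=max_k).fit(flat)
        if retain >= 1.0:
            k = max_k
        else:
            k = int(np.searchsorted(np.cumsum(pca.explained_variance_ratio_), retain) + 1)
            k = min(k, max_k)
        evr = pca.explained_variance_ratio_[:k]
        comps = pca.components_[:k]
    return PCAModel(mean=mean, components=comps, explained_variance_ratio=evr, k=k)


def enhance(image: SpectrogramImage | np.ndarray, model: PCAModel) -> SpectrogramImage | np.ndarray:
    """Reconstruct one image from the model's leading components.

    Accepts and returns either a SpectrogramImage or an (H, W, 3) array;
    output is clipped to [0, 1] and keeps the input shape.
    """
    arr = image.pixels if isinstance(image, SpectrogramImage) else np.asarray(image)
    out = _enhance_batch(arr[None], model)[0]
    if isinstance(image, SpectrogramImage):
        return SpectrogramImage(
            pixels=out, band=image.band, provenance={**image.provenance, "pca": True}
        )
    return out


def _enhance_batch(images: np.ndarray, model: PCAModel) -> np.ndarray:
    n, H, W, C = images.shape
    flat = _to_luminance(images)
    if flat.shape[1] != model.mean.size:
        raise ValueError(
            f"image dimension {flat.shape[1]} does not match model ({model.mean.size})"
        )
    recon = model.reconstruct(flat)
    recon = np.clip(recon, 0.0, 1.0).reshape(n, H, W, 1)
    return np.repeat(recon, C, axis=3)


class PCAEnhancer(BaseEstimator, TransformerMixin):
    """Sklearn transformer: PCA reconstruction of spectrogram images.

    Parameters
    ----------
    retain : float or int
        Variance fraction in (0, 1] or explicit component count.
    channel_mode : {"luminance", "per_channel"}
        Whether to decompose a single luminance channel (default) or each
        RGB channel independently.

    Fitted attributes
    -----------------
    model_ : PCAModel (luminance mode) or list of PCAModel (per channel).
    """

    def __init__(self, retain: float | int = 0.95, channel_mode: str = "luminance"):
        self.retain = retain
        self.channel_mode = channel_mode

    def fit(self, X: np.ndarray, y=None) -> "PCAEnhancer":
        X = self._validate(X)
        if self.channel_mode == "luminance":
            self.model_ = fit_pca(_to_luminance(X), self.retain)
        elif self.channel_mode == "per_channel":
            self.model_ = [
                fit_pca(X[..., c].reshape(X.shape[0], -1), self.retain)
                for c in range(X.shape[3])
            ]
        else:
            raise ValueError(f"unknown channel_mode {self.channel_mode!r}")
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = self._validate(X)
        if self.channel_mode == "luminance":
            return _enhance_batch(X, self.model_)
        out = np.empty_like(X)
        for c, model in enumerate(self.model_):
            flat = X[..., c].reshape(X.shape[0], -1)
            out[..., c] = np.clip(model.reconstruct(flat), 0, 1).reshape(X.shape[:3])
        return out

    @staticmethod
    def _validate(X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 4 or X.shape[3] != 3:
            raise ValueError("expected an (n, H, W, 3) image array")
        return X
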