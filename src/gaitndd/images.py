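"""Rendering spectrograms into fixed-size 3-channel rasters for the CNN.

The rendering rule is deterministic: crop the spectrogram to a frequency
band, take log magnitude with a relative display floor, min-max normalize
per image (a constant image maps to mid-scale), push through a frozen
monotone 256-entry colormap lookup table, and resample to the CNN input
side (227 x 227 x 3, values in [0, 1]).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from skimage.transform import resize

from .tfr import BAND_FULL, BAND_HIGH, BAND_LOW, TFRSpectrogram

#: CNN input side in pixels.
IMAGE_SIDE = 227
#: Relative log-magnitude display floor.
LOG_FLOOR = 1e-6

BANDS = {"low": BAND_LOW, "high": BAND_HIGH, "full": BAND_FULL}

_lut_cache: np.ndarray | None = None


def colormap_lut() -> np.ndarray:
    """The frozen 256 x 3 monotone colormap lookup table (RGB in [0, 1])."""
    global _lut_cache
    if _lut_cache is None:
        with resources.files("gaitndd._data").joinpath(
            "colormap_lut_v1.csv"
        ).open() as fh:
            _lut_cache = np.loadtxt(fh, delimiter=",")
        assert _lut_cache.shape == (256, 3)
    return _lut_cache


@dataclass
class SpectrogramImage:
    """A fixed-size RGB raster of one spectrogram band."""

    pixels: np.ndarray  # (H, W, 3) in [0, 1]
    band: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be H x W x 3")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("pixel values must lie in [0, 1]")


def render_image(
    tfr: TFRSpectrogram, band: str = "full", size: int = IMAGE_SIDE
) -> SpectrogramImage:
    """Render one spectrogram band as a ``size x size x 3`` raster."""
    if band not in BANDS:
        raise ValueError(f"unknown band {band!r}; expected one of {sorted(BANDS)}")
    fmin, fmax = BANDS[band]
    sub = tfr.band_slice(fmin, fmax)
    mag = sub.mag
    peak = mag.max()
    if peak > 0:
        logm = np.log10(np.maximum(mag, LOG_FLOOR * peak))
    else:
        logm = np.zeros_like(mag)
    lo, hi = logm.min(), logm.max()
    if hi - lo > 0:
        norm = (logm - lo) / (hi - lo)
    else:
        # degenerate constant-magnitude image: mid-scale by rule
        norm = np.full_like(logm, 0.5)
    # low frequencies at the bottom of the raster
    norm = norm[::-1]
    scaled = resize(
        norm, (size, size), order=1, mode="edge", anti_aliasing=norm.shape[0] > size
    )
    idx = np.clip((scaled * 255).round().astype(int), 0, 255)
    pixels = colormap_lut()[idx]
    return SpectrogramImage(
        pixels=np.clip(pixels, 0.0, 1.0),
        band=band,
        provenance={"method": tfr.method, **tfr.meta.get("provenance", {})},
    )
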