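"""Spectral summaries of cohorts: ridge statistics per phenotype.

Used to verify that generated cohorts carry the spectral signatures the
phenotype configurations encode (healthy cadence band, slowed ALS gait,
fluctuating Huntington cadence).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .io import segment_windows
from .simulate import default_phenotype, generate_record
from .tfr import cwt, default_freq_grid, ridge_frequency

#: Expected dominant-ridge band per phenotype, Hz.  HD has no fixed band
#: (its signature is ridge variance); PD's band spans both the stride
#: subharmonic (~0.9 Hz, from left/right asymmetry) and the step rate.
RIDGE_BANDS = {"HC": (1.6, 2.1), "ALS": (1.0, 1.5), "PD": (0.8, 2.1)}


def window_ridges(
    group: str,
    n_subjects: int = 4,
    window_s: float = 10.0,
    duration_s: float = 300.0,
    fs: float = 150.0,
    seed: int = 0,
) -> np.ndarray:
    """Per-window CWT ridge frequencies for fresh records of one phenotype.

    Windows are mean-removed before the transform (the constant load
    offset otherwise leaks into the lowest octaves).
    """
    freqs = default_freq_grid(fmax=min(50.0, fs / 2))
    ridges = []
    for i in range(n_subjects):
        cfg = replace(default_phenotype(group), seed=seed * 1000 + i)
        rec = generate_record(cfg, duration_s=duration_s, fs=fs)
        for win in segment_windows(rec, "CF", window_s):
            x = win.samples - win.samples.mean()
            ridges.append(ridge_frequency(cwt(x, fs, freqs)))
    return np.asarray(ridges)


def ridge_in_band_fraction(ridges: np.ndarray, band: tuple[float, float]) -> float:
    """Fraction of ridge frequencies inside the closed band."""
    ridges = np.asarray(ridges)
    return float(((ridges >= band[0]) & (ridges <= band[1])).mean())
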