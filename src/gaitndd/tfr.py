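"""Time-frequency feature transformations: Morlet CWT, STFT, and WSST.

The continuous wavelet transform is computed as the scale-family of
correlations

    X(s, tau) = s^{-1/2} * integral x(t) psi*((t - tau)/s) dt

with the zero-mean (admissible) Morlet mother wavelet

    psi(t) = (exp(-i f t) - exp(-f^2 / 2)) * exp(-t^2 / 2),

where ``f`` is the dimensionless reference (center) frequency, default 6.
The correction term exp(-f^2/2) makes the wavelet's Fourier transform
vanish exactly at zero frequency.  A target frequency F in Hz maps to the
scale s = f / (2 pi F).

The wavelet synchrosqueezed transform (WSST) computes the phase transform

    omega(s, u) = d/du W(s, u) / (2 pi i W(s, u))

with the translation derivative evaluated analytically through the
derivative-of-wavelet kernel, then reassigns each coefficient's magnitude
to the output frequency bin nearest omega(s, u), sharpening ridges.

All transforms here use zero-padded (finite-support) edge handling; the
per-frequency cone-of-influence half-width in samples is recorded in
``meta["coi_samples"]`` so callers can exclude edge columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.signal import fftconvolve

#: Dimensionless Morlet reference (center) frequency.
DEFAULT_MORLET_F = 6.0
#: Half-width of the truncated wavelet support in units of the Gaussian
#: envelope's argument (exp(-8^2/2) ~ 1e-14 of the peak).
_SUPPORT = 8.0
#: Display/analysis bands, Hz.
BAND_LOW = (0.1, 5.0)
BAND_HIGH = (5.0, 50.0)
BAND_FULL = (0.1, 50.0)


@dataclass
class TFRSpectrogram:
    """A time x frequency magnitude matrix with axis vectors."""

    method: str  # "CWT", "STFT", or "WSST"
    freqs_hz: np.ndarray
    times_s: np.ndarray
    mag: np.ndarray  # shape (n_freqs, n_times), non-negative
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.mag = np.asarray(self.mag, dtype=float)
        if self.mag.shape != (self.freqs_hz.size, self.times_s.size):
            raise ValueError(
                f"mag shape {self.mag.shape} does not match axes "
                f"({self.freqs_hz.size}, {self.times_s.size})"
            )
        if not np.isfinite(self.mag).all():
            raise ValueError("magnitudes must be finite")
        if (self.mag < 0).any():
            raise ValueError("magnitudes must be non-negative")
        if self.freqs_hz.size > 1 and not (np.diff(self.freqs_hz) > 0).all():
            raise ValueError("freqs_hz must be strictly increasing")

    def band_slice(self, fmin: float, fmax: float) -> "TFRSpectrogram":
        """Restrict to frequencies in [fmin, fmax] (inclusive)."""
        mask = (self.freqs_hz >= fmin) & (self.freqs_hz <= fmax)
        if not mask.any():
            raise ValueError(
                f"band [{fmin}, {fmax}] Hz does not intersect the frequency axis"
            )
        return TFRSpectrogram(
            method=self.method,
            freqs_hz=self.freqs_hz[mask],
            times_s=self.times_s,
            mag=self.mag[mask],
            meta=dict(self.meta),
        )


def default_freq_grid(
    fmin: float = BAND_FULL[0], fmax: float = BAND_FULL[1], voices: int = 12
) -> np.ndarray:
    """Geometric frequency grid with ``voices`` points per octave."""
    n = int(np.floor(voices * np.log2(fmax / fmin))) + 1
    grid = fmin * 2.0 ** (np.arange(n) / voices)
    if grid[-1] < fmax * (1 - 1e-12):
        grid = np.append(grid, fmax)
    return grid


def morlet(t: np.ndarray | float, f: float = DEFAULT_MORLET_F) -> np.ndarray:
    """Zero-mean complex Morlet wavelet sampled at time offsets ``t``."""
    t = np.asarray(t, dtype=float)
    return (np.exp(-1j * f * t) - np.exp(-0.5 * f**2)) * np.exp(-0.5 * t**2)


def morlet_derivative(t: np.ndarray | float, f: float = DEFAULT_MORLET_F) -> np.ndarray:
    """d psi / d t of the zero-mean Morlet wavelet."""
    t = np.asarray(t, dtype=float)
    env = np.exp(-0.5 * t**2)
    osc = np.exp(-1j * f * t)
    corr = np.exp(-0.5 * f**2)
    return (-1j * f * osc) * env + (osc - corr) * (-t) * env


def freq_to_scale(freq_hz: np.ndarray | float, f_ref: float = DEFAULT_MORLET_F) -> np.ndarray:
    """Scale at which the Morlet wavelet responds to ``freq_hz``: s = f / (2 pi F)."""
    return f_ref / (2.0 * np.pi * np.asarray(freq_hz, dtype=float))


def _cwt_kernel(
    scale: float, fs: float, f_ref: float, kernel_fn: Callable
) -> np.ndarray:
    """Sampled, conjugated, time-reversed wavelet kernel for correlation.

    Returns g with g[m + M] = conj(psi(-m dt / s)) for m = -M..M, so that
    fftconvolve(x, g, 'same') evaluates sum_j x[j] conj(psi((j - n) dt / s)).
    """
    dt = 1.0 / fs
    m_half = int(np.ceil(_SUPPORT * scale / dt))
    m = np.arange(-m_half, m_half + 1)
    return np.conj(kernel_fn(-m * dt / scale, f_ref))


def cwt(
    x: np.ndarray,
    fs: float,
    freqs_hz: np.ndarray | Sequence[float] | None = None,
    f_ref: float = DEFAULT_MORLET_F,
    _kernel_fn: Callable = morlet,
) -> TFRSpectrogram:
    """Continuous wavelet transform magnitudes on a target frequency grid.

    Implemented by FFT-based linear convolution per scale; numerically
    identical (to roundoff) to the direct correlation sum with zero-padded
    edges.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    freqs = (
        default_freq_grid() if freqs_hz is None else np.asarray(freqs_hz, dtype=float)
    )
    if (freqs <= 0).any() or (freqs > fs / 2 + 1e-12).any():
        raise ValueError("frequencies must lie in (0, fs/2]")
    W = cwt_complex(x, fs, freqs, f_ref=f_ref, kernel_fn=_kernel_fn)
    dt = 1.0 / fs
    scales = freq_to_scale(freqs, f_ref)
    coi = np.minimum(np.ceil(_SUPPORT * scales / dt).astype(int), x.size)
    return TFRSpectrogram(
        method="CWT",
        freqs_hz=freqs,
        times_s=np.arange(x.size) * dt,
        mag=np.abs(W),
        meta={"fs": fs, "f_ref": f_ref, "coi_samples": coi},
    )


def cwt_complex(
    x: np.ndarray,
    fs: float,
    freqs_hz: np.ndarray,
    f_ref: float = DEFAULT_MORLET_F,
    kernel_fn: Callable = morlet,
) -> np.ndarray:
    """Complex CWT coefficients, shape (n_freqs, n_samples)."""
    x = np.asarray(x, dtype=float)
    dt = 1.0 / fs
    scales = freq_to_scale(freqs_hz, f_ref)
    out = np.empty((scales.size, x.size), dtype=complex)
    for i, s in enumerate(scales):
        g = _cwt_kernel(s, fs, f_ref, kernel_fn)
        out[i] = fftconvolve(x, g, mode="same") * dt / np.sqrt(s)
    return out


def _resolve_window(window_fn, L: int) -> np.ndarray:
    if window_fn is None or window_fn == "hann":
        return np.hanning(L)
    if window_fn in ("rect", "rectangular", "boxcar"):
        return np.ones(L)
    if callable(window_fn):
        return np.asarray(window_fn(L), dtype=float)
    return np.asarray(window_fn, dtype=float)


def stft(
    x: np.ndarray,
    fs: float,
    win_len: int | None = None,
    hop: int | None = None,
    window_fn="hann",
) -> TFRSpectrogram:
    """Short-time Fourier transform magnitudes.

    Successive length-``win_len`` segments (default 2 s of samples) are
    tapered and transformed with the DFT; default hop is 25% of the
    segment (75% overlap).  The frequency axis is k * fs / L for
    k = 0 .. L // 2.
    """
    x = np.asarray(x, dtype=float)
    L = int(2 * fs) if win_len is None else int(win_len)
    if L > x.size:
        raise ValueError(f"win_len {L} exceeds signal length {x.size}")
    hop = max(1, L // 4) if hop is None else int(hop)
    if not 0 < hop <= L:
        raise ValueError("hop must satisfy 0 < hop <= win_len")
    g = _resolve_window(window_fn, L)
    if g.size != L:
        raise ValueError("window length must equal win_len")
    starts = np.arange(0, x.size - L + 1, hop)
    frames = x[starts[:, None] + np.arange(L)] * g
    spec = np.fft.rfft(frames, axis=1).T  # (L//2 + 1, n_frames)
    freqs = np.arange(L // 2 + 1) * fs / L
    times = (starts + (L - 1) / 2) / fs
    return TFRSpectrogram(
        method="STFT",
        freqs_hz=freqs,
        times_s=times,
        mag=np.abs(spec),
        meta={"fs": fs, "win_len": L, "hop": hop},
    )


def wsst(
    x: np.ndarray,
    fs: float,
    freqs_hz: np.ndarray | Sequence[float] | None = None,
    f_ref: float = DEFAULT_MORLET_F,
    gamma_rel: float = 1e-8,
) -> TFRSpectrogram:
    """Wavelet synchrosqueezed transform.

    Computes the module's own CWT, evaluates the phase transform
    omega = dW/du / (2 pi i W) wherever |W| exceeds
    ``gamma_rel * max|W|``, and reassigns each cell's magnitude to the
    output bin whose frequency is nearest omega (log-spaced nearest for
    the geometric default grid).  Cells below the threshold, or whose
    instantaneous frequency falls outside the grid span, are discarded.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    freqs = (
        default_freq_grid() if freqs_hz is None else np.asarray(freqs_hz, dtype=float)
    )
    if (freqs <= 0).any() or (freqs > fs / 2 + 1e-12).any():
        raise ValueError("frequencies must lie in (0, fs/2]")
    W = cwt_complex(x, fs, freqs, f_ref=f_ref, kernel_fn=morlet)
    scales = freq_to_scale(freqs, f_ref)
    dW = cwt_complex(x, fs, freqs, f_ref=f_ref, kernel_fn=morlet_derivative)
    # d/du psi*((t-u)/s) = -(1/s) psi*'((t-u)/s): scale the derivative kernel
    dW = dW * (-1.0 / scales)[:, None]
    absW = np.abs(W)
    gamma = gamma_rel * absW.max() if absW.max() > 0 else np.inf
    valid = absW > gamma
    omega = np.full_like(absW, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = dW[valid] / (2j * np.pi * W[valid])
        # the e^{-ift} wavelet passband sits at negative frequency, so for
        # real signals the instantaneous frequency is the negated phase
        # derivative
        omega[valid] = -np.real(ratio)
    out = np.zeros_like(absW)
    # nearest output bin in log-frequency (grid is geometric)
    logf = np.log(freqs)
    edges = (logf[:-1] + logf[1:]) / 2.0
    fmin_edge = freqs[0] * np.exp(-(logf[1] - logf[0]) / 2) if freqs.size > 1 else 0.0
    fmax_edge = freqs[-1] * np.exp((logf[-1] - logf[-2]) / 2) if freqs.size > 1 else np.inf
    rows, cols = np.nonzero(valid)
    om = omega[rows, cols]
    ok = np.isfinite(om) & (om >= fmin_edge) & (om <= fmax_edge)
    rows, cols, om = rows[ok], cols[ok], om[ok]
    bins = np.searchsorted(edges, np.log(np.maximum(om, 1e-300)))
    np.add.at(out, (bins, cols), absW[rows, cols])
    dt = 1.0 / fs
    coi = np.minimum(np.ceil(_SUPPORT * scales / dt).astype(int), x.size)
    discarded = float(absW.sum() - absW[rows, cols].sum())
    return TFRSpectrogram(
        method="WSST",
        freqs_hz=freqs,
        times_s=np.arange(x.size) * dt,
        mag=out,
        meta={
            "fs": fs,
            "f_ref": f_ref,
            "gamma": float(gamma),
            "coi_samples": coi,
            "cwt_mass": float(absW.sum()),
            "discarded_mass": discarded,
        },
    )


def ridge_frequency(tfr: TFRSpectrogram, exclude_coi: bool = False) -> float:
    """Median over time columns of the per-column argmax frequency, Hz.

    With ``exclude_coi`` the edge columns inside the widest
    cone-of-influence are dropped first (when recorded in meta).
    """
    mag = tfr.mag
    if exclude_coi and "coi_samples" in tfr.meta:
        w = int(np.max(tfr.meta["coi_samples"]))
        if 2 * w < mag.shape[1]:
            mag = mag[:, w : mag.shape[1] - w]
    idx = np.argmax(mag, axis=0)
    return float(np.median(tfr.freqs_hz[idx]))


def spectral_concentration(tfr: TFRSpectrogram, half_width_bins: int = 1) -> float:
    """Share of total magnitude mass within +/- ``half_width_bins`` of the
    globally dominant frequency bin."""
    per_freq = tfr.mag.sum(axis=1)
    total = per_freq.sum()
    if total == 0:
        return 0.0
    k = int(np.argmax(per_freq))
    lo, hi = max(0, k - half_width_bins), min(per_freq.size, k + half_width_bins + 1)
    return float(per_freq[lo:hi].sum() / total)
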