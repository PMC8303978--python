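"""Time-frequency transforms against direct-summation oracles, plus the
synchrosqueezing sharpening and ridge-tracking properties."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.signal import chirp

from gaitndd.images import render_image
from gaitndd.tfr import (
    TFRSpectrogram,
    cwt,
    default_freq_grid,
    freq_to_scale,
    morlet,
    morlet_derivative,
    ridge_frequency,
    spectral_concentration,
    stft,
    wsst,
)

FS = 100.0


def direct_cwt_mag(x, fs, freqs):
    """Direct quadrature of the scale-correlation integral (the slow oracle)."""
    dt = 1.0 / fs
    n = x.size
    out = np.empty((len(freqs), n))
    for i, f in enumerate(freqs):
        s = float(freq_to_scale(f))
        for m in range(n):
            t = (np.arange(n) - m) * dt
            out[i, m] = np.abs((dt / np.sqrt(s)) * np.sum(x * np.conj(morlet(t / s))))
    return out


def direct_stft_mag(x, L, hop, window):
    """Per-segment windowed DFT by explicit summation."""
    starts = range(0, x.size - L + 1, hop)
    k = np.arange(L // 2 + 1)
    out = []
    for m in starts:
        seg = x[m : m + L] * window
        out.append(
            [np.abs(np.sum(seg * np.exp(-2j * np.pi * kk * np.arange(L) / L))) for kk in k]
        )
    return np.array(out).T


class TestMorlet:
    def test_value_at_zero(self):
        for f in (2.0, 6.0):
            assert morlet(0.0, f) == pytest.approx(1 - np.exp(-(f**2) / 2))

    def test_gaussian_decay(self):
        peak = np.abs(morlet(0.0, 6.0))
        assert np.abs(morlet(10.0, 6.0)) < 1e-20 * peak

    def test_zero_mean_by_quadrature(self):
        re = quad(lambda t: morlet(t, 6.0).real, -8, 8, limit=200)[0]
        im = quad(lambda t: morlet(t, 6.0).imag, -8, 8, limit=200)[0]
        assert abs(complex(re, im)) < 1e-6

    def test_derivative_matches_central_difference(self):
        t = np.linspace(-3, 3, 31)
        h = 1e-6
        numeric = (morlet(t + h, 6.0) - morlet(t - h, 6.0)) / (2 * h)
        np.testing.assert_allclose(morlet_derivative(t, 6.0), numeric, atol=1e-6)


class TestCWT:
    def test_zero_signal(self):
        out = cwt(np.zeros(64), FS, [1.0, 5.0, 10.0])
        assert np.all(out.mag == 0)

    def test_linearity(self, rng):
        x = rng.standard_normal(128)
        a = cwt(x, FS, [2.0, 8.0]).mag
        b = cwt(3.0 * x, FS, [2.0, 8.0]).mag
        np.testing.assert_allclose(b, 3.0 * a, rtol=1e-10)

    def test_tone_peak_frequency_vs_direct_oracle(self):
        t = np.arange(0, 2, 1 / FS)
        x = np.sin(2 * np.pi * 2.0 * t)
        freqs = np.geomspace(0.5, 10, 40)
        fast = cwt(x, FS, freqs)
        peak = freqs[np.argmax(fast.mag.mean(axis=1))]
        assert 1.8 <= peak <= 2.2
        oracle = direct_cwt_mag(x, FS, freqs[::8])
        sub = fast.mag[::8]
        assert np.linalg.norm(sub - oracle) / np.linalg.norm(oracle) < 1e-6

    def test_fast_matches_direct_on_noise(self, rng):
        x = rng.standard_normal(200)
        freqs = np.geomspace(1, 40, 12)
        fast = cwt(x, FS, freqs).mag
        oracle = direct_cwt_mag(x, FS, freqs)
        assert np.linalg.norm(fast - oracle) / np.linalg.norm(oracle) < 1e-6

    def test_time_covariance_under_circular_shift(self):
        t = np.arange(0, 8, 1 / FS)
        x = np.sin(2 * np.pi * 5 * t) * np.exp(-((t - 4) ** 2))
        freqs = np.geomspace(2, 10, 10)
        delta = 40
        a = cwt(x, FS, freqs).mag
        b = cwt(np.roll(x, delta), FS, freqs).mag
        interior = slice(200, 600)
        shifted = slice(200 + delta, 600 + delta)
        err = np.linalg.norm(b[:, shifted] - a[:, interior]) / np.linalg.norm(a[:, interior])
        assert err < 1e-3

    def test_frequency_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError):
            cwt(np.ones(64), FS, [60.0])


class TestSTFT:
    def test_constant_signal_rectangular_window(self):
        c, L = 2.5, 50
        out = stft(np.full(200, c), FS, win_len=L, hop=L, window_fn="rect")
        np.testing.assert_allclose(out.mag[0], c * L, rtol=1e-12)
        assert out.mag[1:].max() < 1e-9

    def test_tone_bin_vs_direct_dft_oracle(self):
        t = np.arange(0, 4, 1 / FS)
        x = np.sin(2 * np.pi * 5 * t)
        L, hop = 100, 50
        out = stft(x, FS, win_len=L, hop=hop, window_fn="rect")
        assert np.all(np.argmax(out.mag, axis=0) == 5)
        oracle = direct_stft_mag(x, L, hop, np.ones(L))
        assert np.linalg.norm(out.mag - oracle) / np.linalg.norm(oracle) < 1e-6

    def test_parseval_rectangular(self, rng):
        x = rng.standard_normal(128)
        L = 64
        out = stft(x, FS, win_len=L, hop=L, window_fn="rect")
        spec = np.fft.fft(x[:L])
        # rfft halves the spectrum; reconstruct full-bin energy
        full = np.concatenate([out.mag[:, 0], out.mag[1 : L // 2, 0][::-1]])
        assert np.sum(full**2) == pytest.approx(L * np.sum(x[:L] ** 2), rel=1e-9)
        assert np.sum(np.abs(spec) ** 2) == pytest.approx(L * np.sum(x[:L] ** 2), rel=1e-9)

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(ValueError):
            stft(np.ones(10), FS, win_len=20)


class TestWSST:
    GRID = default_freq_grid(0.5, 10, 12)

    def test_zero_signal(self):
        out = wsst(np.zeros(64), FS, [1.0, 2.0])
        assert np.all(out.mag == 0)

    def test_sharpens_pure_tone_over_cwt(self):
        fs = 50.0
        t = np.arange(0, 20, 1 / fs)
        x = np.sin(2 * np.pi * 3 * t)
        conc_c = spectral_concentration(cwt(x, fs, self.GRID))
        conc_w = spectral_concentration(wsst(x, fs, self.GRID))
        assert conc_w > conc_c

    def test_two_tone_ridges_carry_most_energy(self):
        fs = 50.0
        t = np.arange(0, 20, 1 / fs)
        x = np.sin(2 * np.pi * 1.0 * t) + np.sin(2 * np.pi * 4.0 * t)
        out = wsst(x, fs, self.GRID)
        per_freq = out.mag.sum(axis=1)
        top2 = np.sort(np.argsort(per_freq)[-2:])
        np.testing.assert_allclose(self.GRID[top2], [1.0, 4.0], rtol=0.03)
        assert per_freq[top2].sum() / per_freq.sum() >= 0.8

    def test_mass_conservation_within_discarded(self):
        fs = 50.0
        t = np.arange(0, 10, 1 / fs)
        x = np.sin(2 * np.pi * 2 * t) + 0.3 * np.sin(2 * np.pi * 6 * t)
        out = wsst(x, fs, self.GRID)
        total = out.mag.sum()
        assert total <= out.meta["cwt_mass"] + 1e-9
        assert total + out.meta["discarded_mass"] == pytest.approx(
            out.meta["cwt_mass"], rel=1e-9
        )

    def test_chirp_ridge_tracks_instantaneous_frequency(self):
        fs = 50.0
        t = np.arange(0, 20, 1 / fs)
        x = chirp(t, f0=2, f1=4, t1=20)
        out = wsst(x, fs, self.GRID)
        inst = 2 + (4 - 2) * t / 20
        est = self.GRID[np.argmax(out.mag, axis=0)]
        central = slice(int(0.1 * t.size), int(0.9 * t.size))
        # within one bin on the 12-voice geometric grid
        assert np.all(np.abs(np.log2(est[central] / inst[central])) <= 1 / 12 + 1e-9)


class TestRenderImage:
    def _tone_tfr(self):
        t = np.arange(0, 5, 1 / FS)
        x = np.sin(2 * np.pi * 2 * t)
        return cwt(x, FS, default_freq_grid(0.5, 40, 8))

    def test_output_shape_and_range(self):
        img = render_image(self._tone_tfr(), band="full")
        assert img.pixels.shape == (227, 227, 3)
        assert img.pixels.min() >= 0.0 and img.pixels.max() <= 1.0

    def test_constant_magnitude_maps_to_uniform_midscale(self):
        tfr = TFRSpectrogram("CWT", [1.0, 2.0, 4.0], np.arange(5.0), np.ones((3, 5)))
        img = render_image(tfr, band="low", size=32)
        assert np.unique(img.pixels.reshape(-1, 3), axis=0).shape[0] == 1

    def test_deterministic(self):
        a = render_image(self._tone_tfr())
        b = render_image(self._tone_tfr())
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_empty_band_rejected(self):
        tfr = TFRSpectrogram("CWT", [20.0, 30.0], np.arange(4.0), np.ones((2, 4)))
        with pytest.raises(ValueError):
            render_image(tfr, band="low")

    def test_colormap_monotone_index(self):
        from gaitndd.images import colormap_lut

        lut = colormap_lut()
        assert lut.shape == (256, 3)
        # luminance proxy strictly related to index ordering at the ends
        lum = lut.mean(axis=1)
        assert lum[0] < lum[-1]


class TestContainer:
    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            TFRSpectrogram("CWT", [1.0, 2.0], np.arange(3.0), np.ones((3, 3)))

    def test_negative_magnitude_rejected(self):
        with pytest.raises(ValueError):
            TFRSpectrogram("CWT", [1.0], np.arange(2.0), -np.ones((1, 2)))

    def test_band_slice(self):
        tfr = TFRSpectrogram("CWT", [1.0, 5.0, 20.0], np.arange(2.0), np.ones((3, 2)))
        assert tfr.band_slice(0.1, 5.0).freqs_hz.tolist() == [1.0, 5.0]
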