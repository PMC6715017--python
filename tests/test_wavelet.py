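"""Morlet transform and band reconstruction against FFT and direct-sum oracles."""

import numpy as np
import pandas as pd
import pytest

from searchrhythms import ScaleGrid, cwt_morlet, dominant_period, reconstruct_band, wavelet_power
from searchrhythms.wavelet import FOURIER_FACTOR, OMEGA0, WaveletError, periods_to_scales, scales_to_periods

from conftest import fft_bandpass


def _series(values, start="2016-01-01"):
    return pd.Series(np.asarray(values, dtype=float), index=pd.date_range(start, periods=len(values)))


def _cosine(period, n=365, amplitude=10.0, level=50.0):
    t = np.arange(n)
    return amplitude * np.cos(2 * np.pi * t / period) + level


class TestTransform:
    def test_periodogram_peak_matches_dominant_period(self):
        x = _cosine(7.0)
        dec = cwt_morlet(_series(x))
        # independent oracle: FFT periodogram peak on the same series
        spec = np.abs(np.fft.rfft(x - x.mean())) ** 2
        freq = np.fft.rfftfreq(len(x))
        fft_peak = 1.0 / freq[np.argmax(spec)]
        step = 2 ** (1 / dec.grid.voices_per_octave)
        assert dominant_period(dec) == pytest.approx(fft_peak, rel=step - 1)

    @pytest.mark.parametrize("period", [3.5, 7.0])
    def test_dominant_period_recovers_cosine(self, period):
        dec = cwt_morlet(_series(_cosine(period)))
        step = 2 ** (1 / dec.grid.voices_per_octave)
        assert dominant_period(dec) == pytest.approx(period, rel=step - 1)

    def test_constant_series_has_null_coefficients(self):
        dec = cwt_morlet(_series(np.full(365, 42.0)))
        assert np.abs(dec.coefficients).max() < 1e-9
        avg, full = wavelet_power(dec)
        assert avg.max() <= 1e-18

    def test_linearity(self):
        x = _cosine(7.0) + _cosine(20.0, level=0.0)
        d1 = cwt_morlet(_series(x))
        d2 = cwt_morlet(_series(2 * x))
        np.testing.assert_allclose(d2.coefficients, 2 * d1.coefficients, rtol=1e-9, atol=1e-9)

    def test_shift_equivariance_away_from_edges(self):
        n, k = 365, 7
        t = np.arange(n)
        f = lambda t: 10 * np.cos(2 * np.pi * t / 7) + 5 * np.cos(2 * np.pi * t / 11 + 1.0) + 50
        grid = ScaleGrid(min_period=2, max_period=16, voices_per_octave=10)
        d1 = cwt_morlet(_series(f(t)), grid)
        d2 = cwt_morlet(_series(f(t - k)), grid)
        # columns far enough from both edges that edge effects are < 1e-6 relative
        margin = int(np.ceil(5.5 * periods_to_scales(np.array([16.0]))[0])) + k
        cols = slice(margin, n - margin)
        scale = np.abs(d1.coefficients).max()
        np.testing.assert_allclose(
            d2.coefficients[:, cols],
            d1.coefficients[:, cols.start - k : cols.stop - k],
            atol=1e-6 * scale,
        )

    def test_direct_convolution_oracle(self):
        """FFT coefficients match a brute-force time-domain convolution."""
        x = _cosine(7.0, n=256) + _cosine(30.0, n=256, level=0.0)
        dec = cwt_morlet(_series(x), ScaleGrid(min_period=4, max_period=32, voices_per_octave=8))
        xc = x - x.mean()
        n = len(x)
        for si in [0, len(dec.periods) // 2, len(dec.periods) - 1]:
            s = dec.scales[si]
            for ti in [n // 2, n // 2 + 17]:
                eta = (np.arange(n) - ti) / s
                psi = (1.0 / np.sqrt(s)) * np.pi**-0.25 * np.exp(1j * OMEGA0 * eta) * np.exp(-0.5 * eta**2)
                direct = np.sum(xc * np.conj(psi))
                assert dec.coefficients[si, ti] == pytest.approx(direct, rel=1e-6)

    def test_power_has_two_maxima_for_two_tone_mixture(self):
        n = 730
        x = _cosine(7.0, n=n) + _cosine(180.0, n=n, level=0.0)
        grid = ScaleGrid(min_period=2, max_period=256, voices_per_octave=10)
        dec = cwt_morlet(_series(x), grid)
        avg, _ = wavelet_power(dec)
        lows = avg[dec.periods < 20]
        highs = avg[dec.periods >= 20]
        low_peak = dec.periods[dec.periods < 20][np.argmax(lows)]
        high_peak = dec.periods[dec.periods >= 20][np.argmax(highs)]
        assert low_peak == pytest.approx(7.0, rel=0.1)
        assert high_peak == pytest.approx(180.0, rel=0.1)

    def test_white_noise_has_no_stable_dominant_period(self):
        wins = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            dec = cwt_morlet(_series(np.abs(50 + 5 * rng.normal(size=365))))
            avg, _ = wavelet_power(dec)
            wins.append(int(np.argmax(avg)))
        worst = max(sum(1 for w in wins if abs(w - i) <= 1) for i in set(wins))
        assert worst <= 5

    def test_series_too_short_for_grid(self):
        with pytest.raises(WaveletError, match="too short"):
            cwt_morlet(_series(np.full(40, 50.0)), ScaleGrid(min_period=2, max_period=32))


class TestReconstruction:
    def test_full_band_round_trip(self):
        n = 365
        x = _cosine(7.0, n=n) + _cosine(30.0, n=n, level=0.0)
        dec = cwt_morlet(_series(x), ScaleGrid(min_period=2, max_period=64, voices_per_octave=20))
        rec = reconstruct_band(dec, 2, None)
        mask = dec.coi >= 64
        r = np.corrcoef(rec.values[mask], x[mask])[0, 1]
        assert r >= 0.99

    def test_weekly_band_isolates_short_component(self):
        n = 365
        t = np.arange(n)
        short = 10 * np.cos(2 * np.pi * t / 7)
        x = short + 10 * np.cos(2 * np.pi * t / 180) + 50
        dec = cwt_morlet(_series(x))
        rec = reconstruct_band(dec, 2, 14)
        mask = dec.coi >= 14
        r = np.corrcoef(rec.values[mask], (short + x.mean())[mask])[0, 1]
        assert r >= 0.95
        # independent oracle: hard FFT band-pass with the same cutoffs
        oracle = fft_bandpass(x, 2, 14)
        assert np.corrcoef(rec.values[mask], oracle[mask])[0, 1] >= 0.95

    def test_constant_series_reconstructs_to_mean(self):
        dec = cwt_morlet(_series(np.full(365, 37.0)))
        rec = reconstruct_band(dec, 2, 14)
        np.testing.assert_allclose(rec.values, 37.0, atol=1e-9)

    def test_band_additivity(self):
        x = _cosine(7.0) + _cosine(25.0, level=0.0) + 3 * np.sin(np.arange(365) / 11.0)
        dec = cwt_morlet(_series(x))
        low = reconstruct_band(dec, 2, 14)
        high = reconstruct_band(dec, 14, None)
        full = reconstruct_band(dec, 2, None)
        resid = (low.values + high.values - dec.series_mean) - full.values
        assert np.abs(resid).max() <= 1e-6 * x.std()

    def test_empty_band_rejected(self):
        dec = cwt_morlet(_series(_cosine(7.0)))
        with pytest.raises(WaveletError):
            reconstruct_band(dec, 40, 50)
        with pytest.raises(WaveletError):
            reconstruct_band(dec, 14, 14)

    def test_period_scale_bijection(self):
        periods = cwt_morlet(_series(_cosine(7.0))).periods
        np.testing.assert_allclose(scales_to_periods(periods_to_scales(periods)), periods, rtol=1e-12)

    def test_fourier_factor_value(self):
        assert FOURIER_FACTOR == pytest.approx(1.0330, abs=5e-5)
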