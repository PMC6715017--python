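import numpy as np
import pandas as pd
import pytest

from searchrhythms import SeriesSpec, generate_daily_series


@pytest.fixture
def dates_364():
    return pd.date_range("2016-01-04", periods=364, freq="D")  # starts a Monday


@pytest.fixture
def noisy_series():
    """Default synthetic series: planted Sunday uplift, seasonality, noise."""
    return generate_daily_series(SeriesSpec(), seed=7)


@pytest.fixture
def flat_uplift_series(dates_364):
    """Noise-free series: Sundays 110, every other day 100."""
    values = np.where(dates_364.dayofweek == 6, 110.0, 100.0)
    return pd.Series(values, index=dates_364)


def fft_bandpass(values, min_period, max_period):
    """Hard FFT band-pass keeping frequencies with period in [min, max), plus the mean."""
    x = np.asarray(values, dtype=float)
    mean = x.mean()
    spec = np.fft.rfft(x - mean)
    freq = np.fft.rfftfreq(len(x), d=1.0)
    keep = np.zeros_like(freq, dtype=bool)
    with np.errstate(divide="ignore"):
        period = np.where(freq > 0, 1.0 / np.where(freq > 0, freq, 1.0), np.inf)
    keep = (period >= min_period) & (period < max_period)
    spec[~keep] = 0.0
    return np.fft.irfft(spec, n=len(x)) + mean
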