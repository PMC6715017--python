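"""Synthetic Google-Trends-like data with planted effects.

Every downstream estimator in this package (weekly uplift ratio, seasonal
contrast, geographic regression) is exercised against series and state tables
generated here, where the true effect sizes are known.  The daily generator
plants a multiplicative Sunday uplift, an annual cosine peaking in winter, a
slow linear trend, and multiplicative log-AR(1) noise, then normalizes to the
integer 0-100 dialect that Trends exports use.  The geographic generator
plants standardized regression slopes of a state search index on latitude and
percent sunshine.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .series import ensure_daily_series

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25


class SpecValidationError(ValueError):
    """Raised when a generator spec has an invalid field; names the field."""


def _require(condition: bool, fieldname: str, message: str) -> None:
    if not condition:
        raise SpecValidationError(f"{fieldname}: {message}")


@dataclass(frozen=True)
class SeriesSpec:
    """Recipe for a synthetic daily search-volume series.

    Defaults emulate the weekly/seasonal structure of "sundowning" search
    interest in the United States: a +10.9% Sunday uplift, an annual cosine
    peaking in mid-January sized so winter runs roughly 2.7x summer, a mild
    upward trend, and moderate autocorrelated noise.  ``start_date``
    2016-01-04 is a Monday and ``n_days`` 364 gives exactly 52 weeks.
    """

    start_date: str = "2016-01-04"
    n_days: int = 364
    baseline: float = 50.0
    sunday_uplift: float = 0.109
    seasonal_amplitude: float = 0.455
    seasonal_peak_doy: int = 15
    trend_per_year: float = 0.02
    noise_sd: float = 0.05
    noise_ar1: float = 0.3

    def __post_init__(self) -> None:
        try:
            pd.Timestamp(self.start_date)
        except (TypeError, ValueError) as exc:
            raise SpecValidationError(f"start_date: not a parseable date ({exc})") from exc
        _require(self.n_days >= 28, "n_days", "must be at least 28")
        _require(self.baseline > 0, "baseline", "must be positive")
        _require(self.seasonal_amplitude >= 0, "seasonal_amplitude", "must be non-negative")
        _require(self.seasonal_amplitude < 1, "seasonal_amplitude", "must be below 1 to keep the latent series positive")
        _require(self.sunday_uplift > -1, "sunday_uplift", "must exceed -1")
        _require(1 <= self.seasonal_peak_doy <= 366, "seasonal_peak_doy", "must be a day of year in [1, 366]")
        _require(self.noise_sd >= 0, "noise_sd", "must be non-negative")
        _require(abs(self.noise_ar1) < 1, "noise_ar1", "must lie strictly inside (-1, 1)")

    @classmethod
    def from_dict(cls, config: Mapping) -> "SeriesSpec":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(config) - known
        if unknown:
            raise SpecValidationError(f"{sorted(unknown)[0]}: unknown SeriesSpec field")
        return cls(**config)


@dataclass(frozen=True)
class GeoSpec:
    """Recipe for a synthetic state-level table with planted slopes.

    ``beta_latitude`` and ``beta_percent_sun`` are standardized partial slopes
    of the state search index on latitude and percent sunshine.  When
    ``noise_sd_standardized`` is None the residual SD is derived so the
    standardized index has unit variance, which makes the planted slopes
    directly comparable to fitted standardized coefficients; a combination of
    slopes and predictor correlation whose systematic variance already exceeds
    1 is then rejected as infeasible.
    """

    n_states: int = 50
    latitude_range: Tuple[float, float] = (27.0, 48.0)
    beta_latitude: float = 0.648
    beta_percent_sun: float = -0.429
    lat_sun_correlation: float = 0.0
    noise_sd_standardized: Optional[float] = None

    def __post_init__(self) -> None:
        _require(self.n_states >= 3, "n_states", "must be at least 3")
        lo, hi = self.latitude_range
        _require(-90 < lo < hi < 90, "latitude_range", "must be an increasing pair inside (-90, 90)")
        _require(abs(self.lat_sun_correlation) < 1, "lat_sun_correlation", "must lie strictly inside (-1, 1)")
        if self.noise_sd_standardized is not None:
            _require(self.noise_sd_standardized >= 0, "noise_sd_standardized", "must be non-negative")

    @property
    def systematic_variance(self) -> float:
        bl, bs, rho = self.beta_latitude, self.beta_percent_sun, self.lat_sun_correlation
        return bl * bl + bs * bs + 2.0 * rho * bl * bs

    def residual_sd(self) -> float:
        """Residual SD of the standardized index implied by the spec."""
        if self.noise_sd_standardized is not None:
            return self.noise_sd_standardized
        resid_var = 1.0 - self.systematic_variance
        if resid_var < 0:
            raise SpecValidationError(
                "noise_sd_standardized: implied residual variance is negative "
                f"({resid_var:.4f}); reduce the planted slopes or their correlation"
            )
        return float(np.sqrt(resid_var))

    @classmethod
    def from_dict(cls, config: Mapping) -> "GeoSpec":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(config) - known
        if unknown:
            raise SpecValidationError(f"{sorted(unknown)[0]}: unknown GeoSpec field")
        config = dict(config)
        if "latitude_range" in config:
            config["latitude_range"] = tuple(config["latitude_range"])
        return cls(**config)


@dataclass(frozen=True)
class GeoDataset:
    """State-level records plus the generator parameters that produced them."""

    records: pd.DataFrame  # columns: state, search_index, latitude, percent_sun
    planted: Optional[GeoSpec] = None

    def __post_init__(self) -> None:
        validate_geo_frame(self.records)

    def __len__(self) -> int:
        return len(self.records)


def validate_geo_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Check a state table against the geographic record contract."""
    required = ["state", "search_index", "latitude", "percent_sun"]
    for column in required:
        if column not in frame.columns:
            raise SpecValidationError(f"{column}: column missing from geographic table")
    if len(frame) < 3:
        raise SpecValidationError("records: at least 3 states required")
    if frame["state"].duplicated().any():
        dup = frame.loc[frame["state"].duplicated(), "state"].iloc[0]
        raise SpecValidationError(f"state: duplicate label {dup!r}")
    if ((frame["search_index"] < 0) | (frame["search_index"] > 100)).any():
        raise SpecValidationError("search_index: values must lie in [0, 100]")
    if ((frame["latitude"] <= -90) | (frame["latitude"] >= 90)).any():
        raise SpecValidationError("latitude: values must lie strictly inside (-90, 90)")
    if ((frame["percent_sun"] < 0) | (frame["percent_sun"] > 100)).any():
        raise SpecValidationError("percent_sun: values must lie in [0, 100]")
    return frame


def normalize_trends(values: Sequence[float]) -> np.ndarray:
    """Rescale non-negative values to the integer 0-100 Trends dialect.

    Each value maps to ``round(100 * v / max(v))`` so the maximum maps to
    exactly 100.  Rounding follows numpy's round-half-even convention.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot normalize an empty sequence")
    if np.any(arr < 0):
        raise ValueError("normalize_trends requires non-negative values")
    peak = arr.max()
    if peak <= 0:
        raise ValueError("normalize_trends is undefined for an all-zero sequence")
    return np.rint(100.0 * arr / peak).astype(int)


def _ar1_lognoise(n: int, sd: float, phi: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary Gaussian AR(1) path, returned on the log scale."""
    if sd == 0:
        return np.zeros(n)
    e = np.empty(n)
    e[0] = rng.normal(0.0, sd / np.sqrt(1.0 - phi * phi))
    innovations = rng.normal(0.0, sd, size=n - 1)
    for t in range(1, n):
        e[t] = phi * e[t - 1] + innovations[t - 1]
    return e


def latent_daily_values(spec: SeriesSpec, rng: np.random.Generator) -> Tuple[pd.DatetimeIndex, np.ndarray]:
    """Pre-normalization latent series: baseline x trend x season x Sunday x noise."""
    dates = pd.date_range(spec.start_date, periods=spec.n_days, freq="D")
    t = np.arange(spec.n_days)
    trend = 1.0 + spec.trend_per_year * t / 365.0
    phase = 2.0 * np.pi * (dates.dayofyear.values - spec.seasonal_peak_doy) / DAYS_PER_YEAR
    season = 1.0 + spec.seasonal_amplitude * np.cos(phase)
    sunday = 1.0 + spec.sunday_uplift * (dates.dayofweek.values == 6)
    noise = np.exp(_ar1_lognoise(spec.n_days, spec.noise_sd, spec.noise_ar1, rng))
    return dates, spec.baseline * trend * season * sunday * noise


def generate_daily_series(spec: SeriesSpec, seed: int) -> pd.Series:
    """Generate a normalized (integer 0-100) daily series with planted effects.

    Deterministic given ``(spec, seed)``.  The day of week is derived from the
    calendar date, so an arbitrary ``start_date`` behaves like a real export.
    """
    rng = np.random.default_rng(seed)
    dates, latent = latent_daily_values(spec, rng)
    values = normalize_trends(latent)
    return ensure_daily_series(pd.Series(values.astype(float), index=dates, name="search_volume"))


def generate_geo_dataset(spec: GeoSpec, seed: int) -> GeoDataset:
    """Generate a state table with planted standardized slopes.

    Latitude is uniform over ``latitude_range``; percent sunshine is built with
    the requested correlation to latitude; the standardized index is the
    planted linear combination plus Gaussian noise, then mapped affinely onto
    a 0-100 search index (values outside the range are clipped, which is rare
    at the default scale).  Deterministic given ``(spec, seed)``.
    """
    sd = spec.residual_sd()  # raises on infeasible slope/correlation combos
    rng = np.random.default_rng(seed)
    n = spec.n_states
    latitude = rng.uniform(*spec.latitude_range, size=n)
    z_lat = _zscore(latitude)
    w = rng.normal(size=n)
    w = w - z_lat * (w @ z_lat) / (z_lat @ z_lat)  # orthogonal to latitude in-sample
    w = _zscore(w)
    rho = spec.lat_sun_correlation
    z_sun = rho * z_lat + np.sqrt(1.0 - rho * rho) * w
    percent_sun = np.clip(60.0 + 10.0 * z_sun, 0.0, 100.0)
    noise = sd * rng.normal(size=n)
    index_std = spec.beta_latitude * z_lat + spec.beta_percent_sun * z_sun + noise
    search_index = np.clip(50.0 + 15.0 * index_std, 0.0, 100.0)
    frame = pd.DataFrame(
        {
            "state": [f"S{i:03d}" for i in range(n)],
            "search_index": search_index,
            "latitude": latitude,
            "percent_sun": percent_sun,
        }
    )
    return GeoDataset(records=frame, planted=spec)


def _zscore(values: np.ndarray) -> np.ndarray:
    sd = values.std(ddof=1)
    if sd == 0:
        raise SpecValidationError("latitude_range: degenerate draw with zero variance")
    return (values - values.mean()) / sd
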