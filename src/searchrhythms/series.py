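"""Validation helpers for daily search-volume series.

The canonical in-memory container throughout the package is a
:class:`pandas.Series` of floats indexed by a gap-free daily
:class:`pandas.DatetimeIndex`.  Normalized search-volume values live on the
0-100 scale, but the helpers only enforce non-negativity so that intermediate
(pre-normalization) series can reuse them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

MIN_SERIES_LENGTH = 28


class SeriesValidationError(ValueError):
    """Raised when a series violates the daily-series contract."""


def ensure_daily_series(series: pd.Series, min_length: int = MIN_SERIES_LENGTH) -> pd.Series:
    """Validate and return a date-contiguous daily series.

    Parameters
    ----------
    series
        Values indexed by calendar dates. Accepts any index convertible to a
        ``DatetimeIndex``.
    min_length
        Minimum number of observations required.

    Returns
    -------
    pandas.Series
        Float-valued copy with a normalized ``DatetimeIndex`` at daily
        frequency.

    Raises
    ------
    SeriesValidationError
        If the index is not strictly increasing at one-day spacing, the series
        is too short, or any value is negative or non-finite.
    """
    if not isinstance(series, pd.Series):
        raise SeriesValidationError("expected a pandas Series of daily values")
    try:
        idx = pd.DatetimeIndex(series.index)
    except (TypeError, ValueError) as exc:
        raise SeriesValidationError(f"index is not convertible to dates: {exc}") from exc
    if len(series) < min_length:
        raise SeriesValidationError(
            f"series has {len(series)} observations; at least {min_length} required"
        )
    gaps = np.diff(idx.values).astype("timedelta64[D]").astype(int)
    if len(gaps) and not np.all(gaps == 1):
        bad = int(np.flatnonzero(gaps != 1)[0])
        raise SeriesValidationError(
            f"dates must be contiguous at 1-day spacing; gap of {gaps[bad]} days "
            f"after {idx[bad].date()}"
        )
    values = np.asarray(series.values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise SeriesValidationError("series contains non-finite values")
    if np.any(values < 0):
        raise SeriesValidationError("series contains negative values")
    return pd.Series(values, index=idx.normalize(), name=series.name)


def daily_series(dates, values, name: str | None = None) -> pd.Series:
    """Build a validated daily series from separate date and value sequences."""
    return ensure_daily_series(pd.Series(np.asarray(values, dtype=float), index=pd.DatetimeIndex(dates), name=name))
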