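"""Winter (DJF) versus summer (JJA) seasonal contrast with a paired t-test.

Search interest in sundowning peaks in winter.  The contrast compares, per
calendar year, the mean normalized search volume over December/January/
February with the mean over June/July/August, then pairs the yearly means in
a t-test.  By default December of year Y is grouped with January and
February of the same calendar year Y (the literal month-list reading); the
meteorologically contiguous grouping (December of Y-1 with Jan/Feb of Y) is
available behind ``grouping="contiguous"``.  The test runs on the raw
normalized series, not a wavelet reconstruction, and tolerates daily, weekly
or monthly cadence since only month-window means are needed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

WINTER_MONTHS = (12, 1, 2)
SUMMER_MONTHS = (6, 7, 8)


class SeasonalError(ValueError):
    """Raised for series without usable season windows or degenerate tests."""


@dataclass(frozen=True)
class SeasonalContrast:
    """Across-year summary of the paired winter-summer comparison."""

    winter_overall: float
    winter_sd: float
    summer_overall: float
    summer_sd: float
    mean_difference: float
    t_statistic: float
    df: int
    p_value: float
    n_years: int


def seasonal_means(series: pd.Series, grouping: str = "calendar") -> pd.DataFrame:
    """Per-year winter and summer means of a date-indexed series.

    Returns a frame with columns ``year, winter_mean, summer_mean,
    n_winter_days, n_summer_days``; years missing either season window are
    dropped with a log message.

    Parameters
    ----------
    series
        Date-indexed values; any cadence (daily/weekly/monthly) works.
    grouping
        ``"calendar"`` assigns December of year Y to year Y's winter;
        ``"contiguous"`` assigns it to year Y+1's winter.
    """
    if grouping not in ("calendar", "contiguous"):
        raise SeasonalError(f"unknown season grouping {grouping!r}")
    idx = pd.DatetimeIndex(series.index)
    values = np.asarray(series.values, dtype=float)
    month = idx.month.values
    year = idx.year.values.copy()
    if grouping == "contiguous":
        year[month == 12] += 1

    rows = []
    for y in np.unique(year):
        in_year = year == y
        winter = values[in_year & np.isin(month, WINTER_MONTHS)]
        summer = values[in_year & np.isin(month, SUMMER_MONTHS)]
        if winter.size == 0 or summer.size == 0:
            logger.info("year %d dropped: winter n=%d, summer n=%d", y, winter.size, summer.size)
            continue
        rows.append(
            {
                "year": int(y),
                "winter_mean": float(winter.mean()),
                "summer_mean": float(summer.mean()),
                "n_winter_days": int(winter.size),
                "n_summer_days": int(summer.size),
            }
        )
    if not rows:
        raise SeasonalError("no year has observations in both the DJF and JJA windows")
    return pd.DataFrame(rows)


def paired_seasonal_test(means: pd.DataFrame) -> SeasonalContrast:
    """Paired t-test of yearly winter means against yearly summer means.

    t = mean(d) / (sd(d) / sqrt(n)) with d = winter - summer per year,
    two-sided p from the t distribution with n-1 degrees of freedom.
    """
    winter = np.asarray(means["winter_mean"], dtype=float)
    summer = np.asarray(means["summer_mean"], dtype=float)
    n = len(winter)
    if n < 2:
        raise SeasonalError(f"paired test needs at least 2 yearly pairs, got {n}")
    d = winter - summer
    sd_d = d.std(ddof=1)
    if sd_d == 0:
        raise SeasonalError(
            "degenerate paired test: all yearly winter-summer differences are identical"
        )
    t = d.mean() / (sd_d / np.sqrt(n))
    df = n - 1
    p = 2.0 * stats.t.sf(abs(t), df)
    return SeasonalContrast(
        winter_overall=float(winter.mean()),
        winter_sd=float(winter.std(ddof=1)),
        summer_overall=float(summer.mean()),
        summer_sd=float(summer.std(ddof=1)),
        mean_difference=float(d.mean()),
        t_statistic=float(t),
        df=df,
        p_value=float(p),
        n_years=n,
    )


class SeasonalContrastModel:
    """Winter/summer contrast model over a multi-year series.

    Examples
    --------
    >>> results = SeasonalContrastModel(series).fit()
    >>> results.contrast.p_value
    """

    def __init__(self, series: pd.Series, grouping: str = "calendar"):
        self.series = series
        self.grouping = grouping

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, date_col: str = "date", value_col: str = "value", **kwargs
    ) -> "SeasonalContrastModel":
        series = pd.Series(
            np.asarray(frame[value_col], dtype=float), index=pd.DatetimeIndex(frame[date_col])
        )
        return cls(series, **kwargs)

    def fit(self) -> "SeasonalResults":
        means = seasonal_means(self.series, grouping=self.grouping)
        return SeasonalResults(self, means, paired_seasonal_test(means))


@dataclass(frozen=True)
class SeasonalResults:
    model: SeasonalContrastModel
    yearly_means: pd.DataFrame
    contrast: SeasonalContrast

    def summary(self) -> str:
        c = self.contrast
        return "\n".join(
            [
                f"Seasonal contrast over {c.n_years} years ({self.model.grouping} winter grouping)",
                f"winter (DJF) mean {c.winter_overall:.1f} (SD {c.winter_sd:.1f}); "
                f"summer (JJA) mean {c.summer_overall:.1f} (SD {c.summer_sd:.1f})",
                f"paired t({c.df}) = {c.t_statistic:.2f}, two-sided p = {c.p_value:.3g}",
            ]
        )

    def to_dict(self) -> dict:
        c = self.contrast
        return {
            "grouping": self.model.grouping,
            "winter_overall": c.winter_overall,
            "winter_sd": c.winter_sd,
            "summer_overall": c.summer_overall,
            "summer_sd": c.summer_sd,
            "mean_difference": c.mean_difference,
            "t_statistic": c.t_statistic,
            "df": c.df,
            "p_value": c.p_value,
            "n_years": c.n_years,
        }
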