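"""Day-of-week percent effects with bootstrap confidence intervals.

The weekly signature of search interest is summarized as the percent
difference of each day from Monday, computed from an OLS fit of the (band
reconstructed) series on a day-of-week factor with Monday as the reference
level: percent(day) = 100 * beta_day / beta_intercept.  Uncertainty comes
from a nonparametric case bootstrap, resampling daily observations with
replacement stratified by weekday so every replicate design stays fittable;
95% percentile intervals and the bootstrap SD of each ratio are reported.
A pooled Sunday-versus-rest contrast uses the same machinery with a single
Sunday indicator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import wavelet
from .series import ensure_daily_series

WEEKDAY_NAMES = ["Monday", "Tuesday", "Wednesday", "Thursday", "Friday", "Saturday", "Sunday"]
EFFECT_DAYS = WEEKDAY_NAMES[1:]  # Monday is the reference level


class DayOfWeekError(ValueError):
    """Raised for unfittable designs or undefined ratios."""


@dataclass(frozen=True)
class DowModelFit:
    """OLS fit of value on intercept (Monday) + six weekday indicators."""

    beta_intercept: float
    beta_day: Dict[str, float]
    residuals: np.ndarray
    n_obs: int

    def fitted(self, weekday_index: np.ndarray) -> np.ndarray:
        betas = np.array([0.0] + [self.beta_day[d] for d in EFFECT_DAYS])
        return self.beta_intercept + betas[weekday_index]


@dataclass(frozen=True)
class DayOfWeekEffects:
    """Percent differences versus Monday with bootstrap CIs and SDs."""

    percent_by_day: Dict[str, float]
    ci_by_day: Dict[str, Tuple[float, float]]
    sd_by_day: Dict[str, float]
    significant_days: frozenset
    n_boot: int
    seed: int
    ci_level: float = 0.95

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "day": d,
                "percent": self.percent_by_day[d],
                "ci_low": self.ci_by_day[d][0],
                "ci_high": self.ci_by_day[d][1],
                "sd": self.sd_by_day[d],
                "significant": d in self.significant_days,
            }
            for d in EFFECT_DAYS
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class SundayContrast:
    """Sunday versus pooled non-Sunday percent difference."""

    percent: float
    ci: Tuple[float, float]
    sd: float
    n_boot: int
    seed: int
    ci_level: float = 0.95

    @property
    def significant(self) -> bool:
        return not (self.ci[0] <= 0.0 <= self.ci[1])


def _weekday_groups(series: pd.Series) -> List[np.ndarray]:
    """Values per weekday, Monday..Sunday; errors if any weekday is absent."""
    idx = pd.DatetimeIndex(series.index)
    values = np.asarray(series.values, dtype=float)
    groups = []
    for w, name in enumerate(WEEKDAY_NAMES):
        g = values[idx.dayofweek == w]
        if g.size == 0:
            raise DayOfWeekError(f"weekday {name} is absent from the series")
        groups.append(g)
    return groups


def fit_dow_model(series: pd.Series) -> DowModelFit:
    """Least-squares fit of the day-of-week factor model (Monday reference).

    The design is saturated, so the coefficients equal the difference of each
    weekday's mean from the Monday mean; the fit is nevertheless solved as an
    actual least-squares problem so residuals come from the projection.
    """
    series = ensure_daily_series(series)
    _weekday_groups(series)  # validates presence of every weekday
    idx = pd.DatetimeIndex(series.index)
    y = np.asarray(series.values, dtype=float)
    wd = idx.dayofweek.values
    design = np.ones((len(y), 7))
    for j in range(1, 7):
        design[:, j] = (wd == j).astype(float)
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    residuals = y - design @ coef
    return DowModelFit(
        beta_intercept=float(coef[0]),
        beta_day={name: float(coef[j]) for j, name in enumerate(WEEKDAY_NAMES) if j > 0},
        residuals=residuals,
        n_obs=len(y),
    )


def dow_percent_effects(fit: DowModelFit) -> Dict[str, float]:
    """percent(day) = 100 * beta_day / beta_intercept (Monday level)."""
    if fit.beta_intercept == 0:
        raise DayOfWeekError("Monday level is zero; ratio undefined")
    return {d: 100.0 * b / fit.beta_intercept for d, b in fit.beta_day.items()}


def _bootstrap_weekday_means(
    groups: List[np.ndarray], n_boot: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_boot, 7) matrix of weekday means under stratified case resampling."""
    means = np.empty((n_boot, 7))
    for w, g in enumerate(groups):
        idx = rng.integers(0, g.size, size=(n_boot, g.size))
        means[:, w] = g[idx].mean(axis=1)
    return means


def _percentile_ci(samples: np.ndarray, level: float) -> Tuple[float, float]:
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(samples, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def bootstrap_effects(
    series: pd.Series, n_boot: int = 5000, seed: Optional[int] = None, ci_level: float = 0.95
) -> DayOfWeekEffects:
    """Percentile-bootstrap CIs and SDs for the six percent-vs-Monday ratios.

    Case bootstrap stratified by weekday; for the saturated factor design the
    refitted coefficients are exactly the resampled weekday-mean differences,
    so each replicate ratio is computed directly from resampled group means.
    Deterministic given ``seed``.
    """
    if n_boot < 1:
        raise DayOfWeekError("n_boot must be at least 1")
    if seed is None:
        raise DayOfWeekError("a seed is required for the bootstrap (no hidden global RNG)")
    series = ensure_daily_series(series)
    groups = _weekday_groups(series)
    point = dow_percent_effects(fit_dow_model(series))

    rng = np.random.default_rng(seed)
    means = _bootstrap_weekday_means(groups, n_boot, rng)
    monday = means[:, 0]
    if np.any(monday == 0):
        raise DayOfWeekError("a bootstrap replicate produced a zero Monday level; ratio undefined")
    percents = 100.0 * (means[:, 1:] - monday[:, None]) / monday[:, None]

    ci_by_day, sd_by_day, significant = {}, {}, set()
    for j, day in enumerate(EFFECT_DAYS):
        ci = _percentile_ci(percents[:, j], ci_level)
        ci_by_day[day] = ci
        sd_by_day[day] = float(percents[:, j].std(ddof=1)) if n_boot > 1 else 0.0
        if not (ci[0] <= 0.0 <= ci[1]):
            significant.add(day)
    return DayOfWeekEffects(
        percent_by_day=point,
        ci_by_day=ci_by_day,
        sd_by_day=sd_by_day,
        significant_days=frozenset(significant),
        n_boot=n_boot,
        seed=seed,
        ci_level=ci_level,
    )


def sunday_contrast(
    series: pd.Series, n_boot: int = 5000, seed: Optional[int] = None, ci_level: float = 0.95
) -> SundayContrast:
    """Sunday versus all non-Sunday days: 100 * beta_Sunday / beta_intercept.

    The model is refit with a single Sunday indicator, so the intercept is the
    pooled non-Sunday mean.  The bootstrap resamples within weekday strata
    (identical scheme to :func:`bootstrap_effects`) and pools the non-Sunday
    strata with their observed weights.
    """
    if n_boot < 1:
        raise DayOfWeekError("n_boot must be at least 1")
    if seed is None:
        raise DayOfWeekError("a seed is required for the bootstrap (no hidden global RNG)")
    series = ensure_daily_series(series)
    groups = _weekday_groups(series)
    sizes = np.array([g.size for g in groups], dtype=float)

    def contrast(weekday_means: np.ndarray) -> np.ndarray:
        non_sunday = (weekday_means[..., :6] * sizes[:6]).sum(axis=-1) / sizes[:6].sum()
        return 100.0 * (weekday_means[..., 6] - non_sunday) / non_sunday

    observed = np.array([g.mean() for g in groups])
    point = float(contrast(observed))

    rng = np.random.default_rng(seed)
    means = _bootstrap_weekday_means(groups, n_boot, rng)
    samples = contrast(means)
    ci = _percentile_ci(samples, ci_level)
    return SundayContrast(
        percent=point,
        ci=ci,
        sd=float(samples.std(ddof=1)) if n_boot > 1 else 0.0,
        n_boot=n_boot,
        seed=seed,
        ci_level=ci_level,
    )


class DayOfWeekModel:
    """Weekly-effect model for a daily search-volume series.

    By default the series is band-pass filtered first (wavelet reconstruction
    keeping periods below ``band[1]`` days, mean added back) so that trend and
    seasonality do not confound the weekday comparison; pass
    ``reconstruct=False`` to model the raw series.

    Examples
    --------
    >>> model = DayOfWeekModel(series)
    >>> results = model.fit(n_boot=5000, seed=42)
    >>> print(results.summary())
    """

    def __init__(
        self,
        series: pd.Series,
        reconstruct: bool = True,
        band: Tuple[float, float] = (2.0, 14.0),
        grid: Optional[wavelet.ScaleGrid] = None,
    ):
        self.raw_series = ensure_daily_series(series)
        self.band = band
        self.reconstruct = reconstruct
        if reconstruct:
            self.decomposition = wavelet.cwt_morlet(self.raw_series, grid)
            self.series = wavelet.reconstruct_band(self.decomposition, band[0], band[1])
        else:
            self.decomposition = None
            self.series = self.raw_series

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, date_col: str = "date", value_col: str = "value", **kwargs
    ) -> "DayOfWeekModel":
        series = pd.Series(
            np.asarray(frame[value_col], dtype=float), index=pd.DatetimeIndex(frame[date_col])
        )
        return cls(series, **kwargs)

    def fit(self, n_boot: int = 5000, seed: Optional[int] = None, ci_level: float = 0.95) -> "DayOfWeekResults":
        model_fit = fit_dow_model(self.series)
        effects = bootstrap_effects(self.series, n_boot=n_boot, seed=seed, ci_level=ci_level)
        sunday = sunday_contrast(self.series, n_boot=n_boot, seed=seed, ci_level=ci_level)
        return DayOfWeekResults(self, model_fit, effects, sunday)


@dataclass(frozen=True)
class DayOfWeekResults:
    """Fitted weekly effects: per-day ratios, bootstrap CIs, Sunday contrast."""

    model: DayOfWeekModel
    model_fit: DowModelFit
    effects: DayOfWeekEffects
    sunday: SundayContrast

    def summary(self) -> str:
        lines = [
            "Day-of-week percent effects vs Monday"
            + (" (band-reconstructed series)" if self.model.reconstruct else " (raw series)"),
            f"n_obs = {self.model_fit.n_obs}, n_boot = {self.effects.n_boot}, "
            f"CI level = {self.effects.ci_level:.0%}",
            f"{'day':<10}{'percent':>9}{'ci_low':>9}{'ci_high':>9}{'sd':>7}  sig",
        ]
        for d in EFFECT_DAYS:
            lo, hi = self.effects.ci_by_day[d]
            sig = "*" if d in self.effects.significant_days else ""
            lines.append(
                f"{d:<10}{self.effects.percent_by_day[d]:>9.2f}{lo:>9.2f}{hi:>9.2f}"
                f"{self.effects.sd_by_day[d]:>7.2f}  {sig}"
            )
        lo, hi = self.sunday.ci
        lines.append(
            f"Sunday vs rest: {self.sunday.percent:+.2f}% "
            f"[{lo:.2f}, {hi:.2f}] (SD {self.sunday.sd:.2f})"
        )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "reconstructed": self.model.reconstruct,
            "band": list(self.model.band),
            "effects": {
                d: {
                    "percent": self.effects.percent_by_day[d],
                    "ci": list(self.effects.ci_by_day[d]),
                    "sd": self.effects.sd_by_day[d],
                    "significant": d in self.effects.significant_days,
                }
                for d in EFFECT_DAYS
            },
            "sunday_vs_rest": {
                "percent": self.sunday.percent,
                "ci": list(self.sunday.ci),
                "sd": self.sunday.sd,
                "significant": self.sunday.significant,
            },
            "n_boot": self.effects.n_boot,
            "seed": self.effects.seed,
        }
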