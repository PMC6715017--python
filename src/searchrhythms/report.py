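"""Full-pipeline report: weekly, seasonal, and geographic analyses together.

``run_full_analysis`` wires the stages end to end: read the daily export,
band-pass it through the wavelet reconstruction, estimate day-of-week
effects with the bootstrap, compute the winter/summer paired contrast on the
raw series, and fit both geographic regressions.  Any stage failure is
re-raised with the stage name attached.  Every stochastic step is seeded
from the config, so reports are reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Union

import yaml

from . import __version__
from .dayofweek import DayOfWeekModel, DayOfWeekResults
from .geo import GeoAssociationModel, GeoResults
from .io import TrendsParseError, read_geo_csv, read_trends_csv
from .seasonal import SeasonalContrastModel, SeasonalResults
from .wavelet import ScaleGrid

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised before any computation when the config is invalid."""


class StageError(RuntimeError):
    """Wraps a stage failure; the message names the failed stage."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass(frozen=True)
class AnalysisConfig:
    """Pipeline settings; validated up front."""

    seed: int = 0
    n_boot: int = 5000
    band_min: float = 2.0
    band_max: float = 14.0
    grid_max_period: float = 32.0
    voices_per_octave: int = 20
    skew_threshold: float = 1.0
    season_grouping: str = "calendar"
    reconstruct: bool = True
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ConfigError("n_boot must be at least 1")
        if not 0 < self.ci_level < 1:
            raise ConfigError("ci_level must lie in (0, 1)")
        if not 2.0 <= self.band_min < self.band_max:
            raise ConfigError("require 2 <= band_min < band_max")
        if self.season_grouping not in ("calendar", "contiguous"):
            raise ConfigError(f"unknown season_grouping {self.season_grouping!r}")

    @classmethod
    def from_dict(cls, config: Mapping) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(config) - known
        if unknown:
            raise ConfigError(f"unknown config field {sorted(unknown)[0]!r}")
        return cls(**config)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "AnalysisConfig":
        with open(path, "r", encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
        if not isinstance(payload, Mapping):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(payload)

    def sha256(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        ).hexdigest()


@dataclass(frozen=True)
class AnalysisReport:
    """Assembled results of the three analyses with provenance."""

    weekly: DayOfWeekResults
    seasonal: SeasonalResults
    geo: GeoResults
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "weekly": self.weekly.to_dict(),
            "seasonal": self.seasonal.to_dict(),
            "geo": self.geo.to_dict(),
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    def summary(self) -> str:
        return "\n\n".join(
            [self.weekly.summary(), self.seasonal.summary(), self.geo.summary()]
        )


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            start = time.perf_counter()
            try:
                result = fn(*args, **kwargs)
            except (ConfigError, StageError):
                raise
            except Exception as exc:
                raise StageError(name, exc) from exc
            logger.info("stage %s finished in %.2f s", name, time.perf_counter() - start)
            return result

        return inner

    return wrap


def run_full_analysis(
    daily_path: Union[str, Path],
    geo_path: Union[str, Path],
    config: Optional[AnalysisConfig] = None,
) -> AnalysisReport:
    """Read inputs, run all three analyses, and assemble a report.

    The daily export must have daily cadence for the weekly stage; the
    seasonal stage accepts any cadence.
    """
    config = config or AnalysisConfig()

    @_stage("read_daily")
    def _read_daily():
        return read_trends_csv(daily_path)

    @_stage("read_geo")
    def _read_geo():
        return read_geo_csv(geo_path)

    export = _read_daily()
    geo_data = _read_geo()

    @_stage("weekly")
    def _weekly():
        if not export.is_daily:
            raise TrendsParseError(
                f"{daily_path}: daily cadence required for the weekly analysis, "
                f"got {export.cadence}"
            )
        grid = ScaleGrid(
            min_period=config.band_min,
            max_period=config.grid_max_period,
            voices_per_octave=config.voices_per_octave,
        )
        model = DayOfWeekModel(
            export.series,
            reconstruct=config.reconstruct,
            band=(config.band_min, config.band_max),
            grid=grid,
        )
        return model.fit(n_boot=config.n_boot, seed=config.seed, ci_level=config.ci_level)

    @_stage("seasonal")
    def _seasonal():
        return SeasonalContrastModel(export.series, grouping=config.season_grouping).fit()

    @_stage("geo")
    def _geo():
        return GeoAssociationModel(geo_data, skew_threshold=config.skew_threshold).fit()

    weekly = _weekly()
    seasonal = _seasonal()
    geo = _geo()

    provenance = {
        "daily_input": str(daily_path),
        "geo_input": str(geo_path),
        "config": dataclasses.asdict(config),
        "config_sha256": config.sha256(),
        "seed": config.seed,
        "software_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    return AnalysisReport(weekly=weekly, seasonal=seasonal, geo=geo, provenance=provenance)


def write_report(report: AnalysisReport, out_dir: Union[str, Path]) -> Path:
    """Write the JSON report and per-stage CSVs; returns the JSON path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    json_path = out_dir / "report.json"
    json_path.write_text(report.to_json() + "\n", encoding="utf-8")
    report.weekly.effects.to_frame().to_csv(out_dir / "weekly_effects.csv", index=False)
    report.seasonal.yearly_means.assign(
        difference=lambda d: d["winter_mean"] - d["summer_mean"]
    ).to_csv(out_dir / "seasonal_means.csv", index=False)
    import pandas as pd

    pd.DataFrame(report.geo.to_dict()["associations"]).to_csv(
        out_dir / "geo_associations.csv", index=False
    )
    return json_path
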