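"""Readers and writers for the Google Trends CSV export dialect and state tables.

A Trends export starts with optional metadata lines (e.g. ``Category:
Health`` followed by a blank line), then a header whose first column names
the cadence (``Day``, ``Week`` or ``Month``) and whose second column names
the query and region, then ISO-dated rows.  Values are integers except for
the literal token ``<1``, which is read as 0.5 and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import List, Union

import numpy as np
import pandas as pd

from .simulate import GeoDataset, SpecValidationError, validate_geo_frame

logger = logging.getLogger(__name__)

_CADENCE_LABELS = {"day": "daily", "week": "weekly", "month": "monthly"}


class TrendsParseError(ValueError):
    """Raised with file and line context when an export cannot be parsed."""


@dataclass(frozen=True)
class TrendsExport:
    """Parsed Trends export: preamble, inferred cadence, and the series."""

    metadata_lines: List[str]
    cadence: str  # daily | weekly | monthly
    series: pd.Series

    @property
    def is_daily(self) -> bool:
        return self.cadence == "daily"


def _infer_cadence(idx: pd.DatetimeIndex, path: str) -> str:
    gaps = np.diff(idx.values).astype("timedelta64[D]").astype(int)
    if len(gaps) == 0:
        return "daily"
    if np.any(gaps <= 0):
        bad = int(np.flatnonzero(gaps <= 0)[0])
        raise TrendsParseError(
            f"{path}: dates are not strictly increasing around {idx[bad].date()}"
        )
    if np.all(gaps == 1):
        return "daily"
    if np.all(gaps == 7):
        return "weekly"
    if np.all((gaps >= 28) & (gaps <= 31)):
        return "monthly"
    raise TrendsParseError(
        f"{path}: inconsistent date spacing (gaps of {sorted(set(gaps.tolist()))} days); "
        "expected uniform daily, weekly, or monthly cadence"
    )


def read_trends_csv(path: Union[str, Path]) -> TrendsExport:
    """Parse a Trends-dialect CSV into a :class:`TrendsExport`.

    Lines before the ``Day,<query>`` / ``Week,<query>`` / ``Month,<query>``
    header are kept verbatim as metadata.  ``<1`` cells map to 0.5.
    """
    path = Path(path)
    if not path.exists():
        raise TrendsParseError(f"{path}: file does not exist")
    lines = path.read_text(encoding="utf-8").splitlines()

    header_idx = None
    for i, line in enumerate(lines):
        first = line.split(",")[0].strip().lower()
        if first in _CADENCE_LABELS:
            header_idx = i
            break
    if header_idx is None:
        raise TrendsParseError(
            f"{path}: no header row found (expected a first column labelled Day, Week, or Month)"
        )
    metadata = lines[:header_idx]

    dates, values = [], []
    for lineno, line in enumerate(lines[header_idx + 1 :], start=header_idx + 2):
        if not line.strip():
            continue
        cells = line.split(",")
        if len(cells) != 2:
            raise TrendsParseError(f"{path}:{lineno}: expected 2 columns, got {len(cells)}")
        try:
            date = pd.Timestamp(cells[0].strip())
        except ValueError as exc:
            raise TrendsParseError(f"{path}:{lineno}: unparseable date {cells[0]!r}") from exc
        raw = cells[1].strip()
        if raw == "<1":
            logger.info("%s:%d: value '<1' read as 0.5", path, lineno)
            value = 0.5
        else:
            try:
                value = float(raw)
            except ValueError as exc:
                raise TrendsParseError(f"{path}:{lineno}: unparseable value {raw!r}") from exc
        dates.append(date)
        values.append(value)
    if not dates:
        raise TrendsParseError(f"{path}: no data rows after the header")

    idx = pd.DatetimeIndex(dates)
    cadence = _infer_cadence(idx, str(path))
    series = pd.Series(np.asarray(values, dtype=float), index=idx, name="search_volume")
    return TrendsExport(metadata_lines=metadata, cadence=cadence, series=series)


def write_trends_csv(
    path: Union[str, Path],
    series: pd.Series,
    query: str = "sundowning",
    region: str = "United States",
    category: str = "Health",
) -> None:
    """Write a series in the Trends export dialect (daily header).

    Integer-valued series round-trip losslessly through
    :func:`read_trends_csv`.
    """
    idx = pd.DatetimeIndex(series.index)
    lines = [f"Category: {category}", "", f"Day,{query}: ({region})"]
    for date, value in zip(idx, series.values):
        v = float(value)
        cell = str(int(v)) if v == int(v) else repr(v)
        lines.append(f"{date.date().isoformat()},{cell}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_geo_csv(path: Union[str, Path]) -> GeoDataset:
    """Read a state table CSV with columns state, search_index, latitude, percent_sun."""
    path = Path(path)
    if not path.exists():
        raise TrendsParseError(f"{path}: file does not exist")
    try:
        frame = pd.read_csv(path)
    except Exception as exc:
        raise TrendsParseError(f"{path}: cannot parse CSV ({exc})") from exc
    try:
        validate_geo_frame(frame)
    except SpecValidationError as exc:
        raise TrendsParseError(f"{path}: {exc}") from exc
    return GeoDataset(records=frame[["state", "search_index", "latitude", "percent_sun"]])


def write_geo_csv(path: Union[str, Path], dataset: GeoDataset) -> None:
    dataset.records.to_csv(path, index=False)
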