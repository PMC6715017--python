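"""State-level associations of search volume with latitude and sunshine.

Each predictor (state-center latitude in degrees north; percent of daylight
hours with sunshine) is screened for skew with the adjusted Fisher-Pearson
coefficient and log10-transformed when |skewness| exceeds a configurable
threshold, substituting a reproducible numeric rule for visual density-plot
inspection.  Response and predictor are then z-scored and a simple linear
regression fitted, reporting the standardized slope (equal to the Pearson
correlation), its standard error, the two-sided t-based p-value and R^2.
The two predictors are fit as two separate simple regressions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .simulate import GeoDataset, validate_geo_frame

DEFAULT_SKEW_THRESHOLD = 1.0
PREDICTOR_COLUMNS = {"Latitude": "latitude", "PercentSun": "percent_sun"}


class GeoError(ValueError):
    """Raised for invalid geographic tables or unfittable regressions."""


@dataclass(frozen=True)
class SkewReport:
    variable: str
    skewness: float
    transformed: bool
    threshold: float


@dataclass(frozen=True)
class GeoAssociation:
    """Standardized simple-regression summary for one predictor."""

    predictor: str
    r_squared: float
    beta_standardized: float
    beta_se: float
    p_value: float
    pearson_r: float
    n: int
    skew: SkewReport


def assess_skew(
    values: Sequence[float], threshold: float = DEFAULT_SKEW_THRESHOLD, variable: str = "x"
) -> SkewReport:
    """Adjusted Fisher-Pearson sample skewness and the transform decision.

    Raises when the decision is to transform but a value is non-positive,
    since log10 would be undefined; add an offset upstream in that case.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 3:
        raise GeoError(f"{variable}: skewness needs at least 3 values, got {arr.size}")
    # a constant sample has undefined skewness; treat it as symmetric and let
    # the regression's zero-variance check raise the informative error
    skewness = 0.0 if np.ptp(arr) == 0 else float(stats.skew(arr, bias=False))
    transformed = abs(skewness) > threshold
    if transformed and np.any(arr <= 0):
        raise GeoError(
            f"{variable}: log10 transform triggered (|skew| {abs(skewness):.2f} > "
            f"{threshold}) but values include non-positives; add an offset first"
        )
    return SkewReport(variable=variable, skewness=skewness, transformed=transformed, threshold=threshold)


def _as_frame(data: Union[GeoDataset, pd.DataFrame]) -> pd.DataFrame:
    frame = data.records if isinstance(data, GeoDataset) else data
    return validate_geo_frame(frame)


def fit_simple_association(
    data: Union[GeoDataset, pd.DataFrame],
    predictor: str,
    skew_threshold: float = DEFAULT_SKEW_THRESHOLD,
) -> GeoAssociation:
    """Simple standardized regression of search index on one predictor.

    Parameters
    ----------
    data
        State table (or :class:`GeoDataset`) with columns ``state,
        search_index, latitude, percent_sun``.
    predictor
        ``"Latitude"`` or ``"PercentSun"``.
    skew_threshold
        |skewness| above which the predictor is log10-transformed before
        z-scoring; ``inf`` disables the transform.
    """
    frame = _as_frame(data)
    if predictor not in PREDICTOR_COLUMNS:
        raise GeoError(f"unknown predictor {predictor!r}; expected one of {sorted(PREDICTOR_COLUMNS)}")
    x = np.asarray(frame[PREDICTOR_COLUMNS[predictor]], dtype=float)
    y = np.asarray(frame["search_index"], dtype=float)

    skew = assess_skew(x, threshold=skew_threshold, variable=predictor)
    if skew.transformed:
        x = np.log10(x)
    if x.std(ddof=1) == 0:
        raise GeoError(f"{predictor}: zero predictor variance; slope undefined")
    if y.std(ddof=1) == 0:
        raise GeoError("search_index: zero response variance; slope undefined")

    zx = (x - x.mean()) / x.std(ddof=1)
    zy = (y - y.mean()) / y.std(ddof=1)
    ols = sm.OLS(zy, sm.add_constant(zx)).fit()
    slope = float(ols.params[1])
    pearson_r = float(np.corrcoef(x, y)[0, 1])
    return GeoAssociation(
        predictor=predictor,
        r_squared=float(ols.rsquared),
        beta_standardized=slope,
        beta_se=float(ols.bse[1]),
        p_value=float(ols.pvalues[1]),
        pearson_r=pearson_r,
        n=len(frame),
        skew=skew,
    )


class GeoAssociationModel:
    """Two separate simple regressions of a state search index on Latitude
    and PercentSun.

    Examples
    --------
    >>> results = GeoAssociationModel(geo_dataset).fit()
    >>> print(results.summary())
    """

    def __init__(
        self,
        data: Union[GeoDataset, pd.DataFrame],
        skew_threshold: float = DEFAULT_SKEW_THRESHOLD,
    ):
        self.frame = _as_frame(data)
        self.skew_threshold = skew_threshold

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kwargs) -> "GeoAssociationModel":
        return cls(frame, **kwargs)

    def fit(self, predictors: Sequence[str] = ("Latitude", "PercentSun")) -> "GeoResults":
        associations = [
            fit_simple_association(self.frame, p, skew_threshold=self.skew_threshold)
            for p in predictors
        ]
        return GeoResults(self, associations)


@dataclass(frozen=True)
class GeoResults:
    model: GeoAssociationModel
    associations: List[GeoAssociation]

    def summary(self) -> str:
        lines = [
            f"State-level simple regressions (n = {len(self.model.frame)} states)",
            f"{'predictor':<12}{'beta':>8}{'se':>8}{'R2':>7}{'p':>12}  log10",
        ]
        for a in self.associations:
            lines.append(
                f"{a.predictor:<12}{a.beta_standardized:>8.3f}{a.beta_se:>8.3f}"
                f"{a.r_squared:>7.3f}{a.p_value:>12.3g}  {'yes' if a.skew.transformed else 'no'}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "n_states": len(self.model.frame),
            "associations": [
                {
                    "predictor": a.predictor,
                    "beta_standardized": a.beta_standardized,
                    "beta_se": a.beta_se,
                    "r_squared": a.r_squared,
                    "p_value": a.p_value,
                    "pearson_r": a.pearson_r,
                    "skewness": a.skew.skewness,
                    "log10_transformed": a.skew.transformed,
                }
                for a in self.associations
            ],
        }

    def residual_table(self, predictor: str) -> pd.DataFrame:
        """Per-state residuals of one standardized fit, for Q-Q inspection."""
        a = next((x for x in self.associations if x.predictor == predictor), None)
        if a is None:
            raise GeoError(f"predictor {predictor!r} was not fitted")
        frame = self.model.frame
        x = np.asarray(frame[PREDICTOR_COLUMNS[predictor]], dtype=float)
        if a.skew.transformed:
            x = np.log10(x)
        y = np.asarray(frame["search_index"], dtype=float)
        zx = (x - x.mean()) / x.std(ddof=1)
        zy = (y - y.mean()) / y.std(ddof=1)
        resid = zy - a.beta_standardized * zx
        return pd.DataFrame({"state": frame["state"].values, "residual": resid})
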