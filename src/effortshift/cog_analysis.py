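"""Latitudinal centre of gravity (COG) of fishing effort.

The COG of a year's effort is the effort-weighted mean latitude of the
fishing activity,

    COG = sum_i(latitude_i * effort_i) / sum_i(effort_i),

computed separately north and south of the equator to detect poleward (or
equatorward) shifts in each hemisphere.  Annual series are fitted with an
OLS trend and correlated (Pearson) against the regional SSTA series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CorrelationResult, TrendFit, fit_trend
from .errors import InsufficientDataError

log = logging.getLogger(__name__)

HEMISPHERES = ("north", "south")


@dataclass
class COGSeries:
    """Annual latitudinal centre of gravity for one hemisphere."""

    hemisphere: str
    years: np.ndarray
    cog_lat: np.ndarray  # degrees latitude; NaN where no effort that year
    n_sets: np.ndarray  # records contributing per year

    def to_series(self) -> pd.Series:
        return pd.Series(self.cog_lat, index=self.years, name=f"cog_{self.hemisphere}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.years,
                "hemisphere": self.hemisphere,
                "cog_lat": self.cog_lat,
                "n_sets": self.n_sets,
            }
        )


def _hemisphere_mask(lat: np.ndarray, hemisphere: str) -> np.ndarray:
    # strictly north/south of the equator; centre latitude 0 (impossible on
    # the default half-integer grid) would belong to neither hemisphere
    if hemisphere == "north":
        return lat > 0
    if hemisphere == "south":
        return lat < 0
    raise ValueError(f"hemisphere must be 'north' or 'south', got {hemisphere!r}")


def compute_cog(records: pd.DataFrame, hemisphere: str, year: int | None = None) -> float:
    """Effort-weighted mean latitude of one hemisphere's records.

    Pools all quarters of the year (or of the whole table when ``year`` is
    None).  Returns NaN when the stratum has zero total effort.
    """
    df = records
    if year is not None:
        df = df[df["year"] == year]
    lat = df["lat"].to_numpy(dtype=float)
    eff = df["effort_hours"].to_numpy(dtype=float)
    keep = _hemisphere_mask(lat, hemisphere)
    lat, eff = lat[keep], eff[keep]
    total = eff.sum()
    if total <= 0:
        log.warning("compute_cog: zero effort in %s stratum (year=%s)", hemisphere, year)
        return float("nan")
    return float(np.sum(lat * eff) / total)


def cog_series(records: pd.DataFrame, hemisphere: str) -> COGSeries:
    """Annual COG series over all years present in the records."""
    years = np.sort(records["year"].unique())
    cogs = np.empty(len(years))
    n_sets = np.zeros(len(years), dtype=int)
    for i, y in enumerate(years):
        sub = records[records["year"] == y]
        cogs[i] = compute_cog(sub, hemisphere)
        n_sets[i] = int(_hemisphere_mask(sub["lat"].to_numpy(dtype=float), hemisphere).sum())
    return COGSeries(hemisphere, years, cogs, n_sets)


def cog_trend(series: COGSeries) -> TrendFit:
    """OLS trend of annual COG in degrees latitude per year.

    A negative slope on the southern series means a southward shift.
    """
    return fit_trend(series.to_series())


def correlate(series_a: pd.Series, series_b: pd.Series) -> CorrelationResult:
    """Pearson correlation of two series after pairwise deletion of missing."""
    a, b = series_a.align(series_b, join="inner")
    paired = pd.DataFrame({"a": a, "b": b}).dropna()
    if len(paired) < 3:
        raise InsufficientDataError(
            f"correlation needs >= 3 complete pairs, got {len(paired)}"
        )
    x = paired["a"].to_numpy(dtype=float)
    y = paired["b"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InsufficientDataError("correlation undefined: a series has zero variance")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p_value=float(res.pvalue), n=len(paired))


def annual_mean(series: pd.Series) -> pd.Series:
    """Annual mean of a quarterly series (used to pair SSTA with annual COG)."""
    if not isinstance(series.index, pd.PeriodIndex):
        raise ValueError("annual_mean expects a quarterly PeriodIndex series")
    out = series.groupby(series.index.year).mean()
    out.name = series.name
    return out
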