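"""Core data containers for quarterly gridded effort / SST-anomaly analysis.

The study works on two regular lat/lon grids: monthly purse-seine effort
records reported at 1x1 degree cell centres, and sea-surface-temperature
anomalies (SSTA) on a 5x5 degree grid.  Both are aggregated to a gap-free
quarterly time axis; missing cell-quarters are carried as NaN, never as
zero, so that downstream anomaly and DINEOF steps see true data gaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InsufficientDataError

log = logging.getLogger(__name__)

__all__ = [
    "RegionBox",
    "STUDY_REGION",
    "QuarterCube",
    "EffortCube",
    "SSTACube",
    "AnomalyMatrix",
    "TrendFit",
    "CorrelationResult",
    "quarter_of_month",
    "quarter_range",
    "cell_centres",
    "parent_centre",
]


@dataclass(frozen=True)
class RegionBox:
    """Closed lat/lon study box; membership tests use cell centres in degrees."""

    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float

    def __post_init__(self) -> None:
        if not (self.lat_min < self.lat_max):
            raise ValueError("lat_min must be < lat_max")
        if not (self.lon_min < self.lon_max):
            raise ValueError("lon_min must be < lon_max")

    def contains(self, lat, lon):
        """Vectorised closed-interval membership for cell centres."""
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        return (
            (lat >= self.lat_min)
            & (lat <= self.lat_max)
            & (lon >= self.lon_min)
            & (lon <= self.lon_max)
        )


#: Eastern Atlantic tropical-tuna purse-seine study area (29N, 30S, 19E, 35W).
STUDY_REGION = RegionBox(lat_min=-30.0, lat_max=29.0, lon_min=-35.0, lon_max=19.0)


def quarter_of_month(month: int) -> int:
    """Calendar quarter of a month: 1 = Jan-Mar ... 4 = Oct-Dec."""
    month = int(month)
    if not 1 <= month <= 12:
        raise ValueError(f"month out of range: {month}")
    return (month + 2) // 3


def quarter_range(year_start: int, year_end: int) -> pd.PeriodIndex:
    """Gap-free quarterly index from Q1 of ``year_start`` to Q4 of ``year_end``."""
    return pd.period_range(f"{year_start}Q1", f"{year_end}Q4", freq="Q")


def cell_centres(lo: float, hi: float, cell_deg: float) -> np.ndarray:
    """Cell-centre coordinates of the regular grid covering the closed [lo, hi].

    1-degree cells sit on half-integers; 5-degree cells on the standard
    2.5 + 5k lattice (the Kaplan grid).  Only centres inside the closed
    interval are returned.
    """
    if cell_deg == 1:
        first = np.floor(lo) + 0.5
        centres = np.arange(first, hi + 0.5, 1.0)
    elif cell_deg == 5:
        first = np.floor(lo / 5.0) * 5.0 + 2.5
        centres = np.arange(first, hi + 2.5, 5.0)
    else:
        raise ValueError("cell_deg must be 1 or 5")
    return centres[(centres >= lo) & (centres <= hi)]


def parent_centre(coord, cell_deg: float = 5.0):
    """Centre of the ``cell_deg`` cell containing the given centre coordinate."""
    coord = np.asarray(coord, dtype=float)
    return np.floor(coord / cell_deg) * cell_deg + cell_deg / 2.0


@dataclass
class QuarterCube:
    """Quarterly values on a regular lat/lon grid; NaN marks missing cells."""

    values: np.ndarray  # (time, lat, lon)
    time_index: pd.PeriodIndex
    lats: np.ndarray
    lons: np.ndarray
    cell_size: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.lats = np.asarray(self.lats, dtype=float)
        self.lons = np.asarray(self.lons, dtype=float)
        if self.values.shape != (len(self.time_index), len(self.lats), len(self.lons)):
            raise ValueError("cube shape inconsistent with its axes")
        if len(self.time_index) > 1:
            steps = np.diff(self.time_index.asi8)
            if not np.all(steps == 1):
                raise ValueError("time index must be gap-free quarters")

    @property
    def mask(self) -> np.ndarray:
        """Boolean array marking missing (no-record) cell-quarters."""
        return np.isnan(self.values)

    @property
    def n_quarters(self) -> int:
        return len(self.time_index)

    def to_xarray(self, name: str = "value"):
        import xarray as xr

        return xr.DataArray(
            self.values,
            coords={
                "time": self.time_index.to_timestamp(),
                "lat": self.lats,
                "lon": self.lons,
            },
            dims=("time", "lat", "lon"),
            name=name,
            attrs={"cell_size_deg": self.cell_size},
        )

    def to_netcdf(self, path, name: str = "value") -> None:
        # scipy engine -> NetCDF3 classic, no compiled NetCDF4 dependency
        self.to_xarray(name).to_dataset().to_netcdf(path, engine="scipy")


@dataclass
class EffortCube(QuarterCube):
    """Fishing hours summed per cell-quarter; NaN where no record exists."""


@dataclass
class SSTACube(QuarterCube):
    """Quarterly-mean SST anomaly (degC, relative to the product baseline)."""


@dataclass
class AnomalyMatrix:
    """Deseasonalised anomalies as a time x space matrix.

    ``climatology`` holds the per-cell, per-quarter-of-year means that were
    subtracted; adding it back reproduces the observed cube at observed
    entries.  Columns are grid cells identified by their (lat, lon) centre.
    """

    values: np.ndarray  # (time, space); NaN marks missing
    time_index: pd.PeriodIndex
    space_index: list  # [(lat, lon), ...]
    climatology: np.ndarray  # (4, space): quarter-of-year means

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.climatology = np.asarray(self.climatology, dtype=float)
        if self.values.shape[1] != len(self.space_index):
            raise ValueError("column count must equal length of space_index")
        if self.values.shape[0] != len(self.time_index):
            raise ValueError("row count must equal length of time_index")
        if self.climatology.shape != (4, self.values.shape[1]):
            raise ValueError("climatology must be (4, space)")

    @property
    def n_time(self) -> int:
        return self.values.shape[0]

    @property
    def n_space(self) -> int:
        return self.values.shape[1]

    @property
    def missing_fraction(self) -> np.ndarray:
        """Per-column fraction of missing time steps."""
        return np.isnan(self.values).mean(axis=0)

    def observed(self) -> np.ndarray:
        """Anomalies + climatology: the observed field at observed entries."""
        qidx = self.time_index.quarter.to_numpy() - 1
        return self.values + self.climatology[qidx, :]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{lat}_{lon}" for lat, lon in self.space_index]
        return pd.DataFrame(self.values, index=self.time_index, columns=cols)

    def copy(self) -> "AnomalyMatrix":
        return AnomalyMatrix(
            self.values.copy(),
            self.time_index.copy(),
            list(self.space_index),
            self.climatology.copy(),
        )


@dataclass(frozen=True)
class TrendFit:
    """OLS linear-trend fit of a time series."""

    slope: float  # units per time step (quarter or year)
    intercept: float
    p_value: float  # two-sided, t distribution with n-2 df
    total_change: float  # slope x (last time - first time)
    stderr: float
    n: int


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with its two-sided t-test p-value."""

    r: float
    p_value: float
    n: int


def numeric_time(index) -> np.ndarray:
    """Map a series index to a numeric time axis for trend fitting.

    Quarterly PeriodIndex -> quarter ordinals (slope per quarter); integer or
    float index (e.g. years) -> values as floats (slope per year).
    """
    if isinstance(index, pd.PeriodIndex):
        return index.asi8.astype(float)
    arr = np.asarray(index, dtype=float)
    if arr.ndim != 1:
        raise ValueError("index must be one-dimensional")
    return arr


def fit_trend(series: pd.Series) -> TrendFit:
    """OLS slope of a series against its numeric time axis.

    Missing values are dropped; at least three points are required.  The
    two-sided p-value uses the t distribution with n-2 degrees of freedom
    and ignores serial autocorrelation (plain linear regression).
    """
    from scipy import stats

    series = series.dropna()
    if len(series) < 3:
        raise InsufficientDataError(
            f"linear trend needs >= 3 points, got {len(series)}"
        )
    t = numeric_time(series.index)
    y = series.to_numpy(dtype=float)
    res = stats.linregress(t, y)
    pval = float(res.pvalue)
    if not np.isfinite(pval):
        # degenerate residuals: an exact line (p -> 0) or a constant (p -> 1)
        pval = 0.0 if abs(res.slope) > 0 else 1.0
    return TrendFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        p_value=pval,
        total_change=float(res.slope * (t[-1] - t[0])),
        stderr=float(res.stderr),
        n=len(series),
    )
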