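"""Ingestion and gridding of effort records and SST-anomaly fields.

Monthly purse-seine effort records (fishing hours plus catch split by
operation mode) arrive as CSV at 1x1 degree cell centres; SST anomalies as
CF-style NetCDF or long-format CSV on a 5x5 degree grid.  This module
subsets both to the study region, aggregates them onto a gap-free quarterly
axis (effort by summing, SSTA by averaging), removes the per-cell
quarter-of-year climatology, and derives regional summary series.
"""

from __future__ import annotations

import logging
from typing import NamedTuple

import numpy as np
import pandas as pd

from .containers import (
    AnomalyMatrix,
    EffortCube,
    QuarterCube,
    RegionBox,
    SSTACube,
    STUDY_REGION,
    TrendFit,
    cell_centres,
    fit_trend,
    parent_centre,
    quarter_range,
)
from .errors import EmptyInputError, InsufficientDataError, SchemaError

log = logging.getLogger(__name__)

#: documented CSV schema for effort records
EFFORT_COLUMNS = (
    "year",
    "month",
    "lat",
    "lon",
    "effort_hours",
    "catch_fad_t",
    "catch_free_t",
    "fleet",
)

_NUMERIC = ("year", "month", "lat", "lon", "effort_hours", "catch_fad_t", "catch_free_t")


class EffortTable(NamedTuple):
    """Validated effort records plus the count of rejected input rows."""

    records: pd.DataFrame
    n_rejected: int


def read_effort_table(path) -> EffortTable:
    """Read an effort CSV, rejecting malformed rows.

    Rows with non-numeric or negative effort, negative catches, or a month
    outside 1-12 are dropped and counted.  Missing catch fields are read as
    zero tonnes, a missing fleet label as the empty string.
    """
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"effort file is empty: {path}") from None
    missing = [c for c in EFFORT_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"effort CSV missing required column(s): {', '.join(missing)}")
    if len(raw) == 0:
        raise EmptyInputError(f"effort file has a header but no rows: {path}")

    df = raw.copy()
    for col in _NUMERIC:
        df[col] = pd.to_numeric(df[col].replace("", np.nan), errors="coerce")
    df["catch_fad_t"] = df["catch_fad_t"].fillna(0.0)
    df["catch_free_t"] = df["catch_free_t"].fillna(0.0)

    ok = (
        df["year"].notna()
        & df["month"].between(1, 12)
        & df["lat"].notna()
        & df["lon"].notna()
        & (df["effort_hours"] >= 0)  # False for NaN
        & (df["catch_fad_t"] >= 0)
        & (df["catch_free_t"] >= 0)
    )
    n_rejected = int((~ok).sum())
    if n_rejected:
        log.warning("read_effort_table: rejected %d malformed row(s)", n_rejected)
    records = df.loc[ok].reset_index(drop=True)
    records["year"] = records["year"].astype(int)
    records["month"] = records["month"].astype(int)
    records["fleet"] = records["fleet"].astype(str)
    return EffortTable(records[list(EFFORT_COLUMNS)], n_rejected)


def subset_region(records: pd.DataFrame, box: RegionBox = STUDY_REGION) -> pd.DataFrame:
    """Retain records whose cell centre lies inside the closed study box."""
    keep = box.contains(records["lat"].to_numpy(), records["lon"].to_numpy())
    return records.loc[keep].reset_index(drop=True)


def _quarter_index(records: pd.DataFrame) -> pd.PeriodIndex:
    return pd.PeriodIndex.from_fields(
        year=records["year"].to_numpy(),
        quarter=(records["month"].to_numpy() + 2) // 3,
        freq="Q",
    )


def aggregate_effort(
    records: pd.DataFrame,
    cell_deg: int = 5,
    box: RegionBox = STUDY_REGION,
    period: tuple[int, int] | None = None,
) -> EffortCube:
    """Sum effort onto a quarterly grid; cell-quarters with no record are missing.

    1-degree records map to the 5-degree parent cell containing their centre.
    Records outside the grid defined by ``box`` raise (subset first).
    """
    if cell_deg not in (1, 5):
        raise ValueError("cell_deg must be 1 or 5")
    if len(records) == 0:
        raise EmptyInputError("no records to aggregate")
    lats = cell_centres(box.lat_min, box.lat_max, cell_deg)
    lons = cell_centres(box.lon_min, box.lon_max, cell_deg)

    if cell_deg == 1:
        rlat = records["lat"].to_numpy(dtype=float)
        rlon = records["lon"].to_numpy(dtype=float)
    else:
        rlat = parent_centre(records["lat"].to_numpy(), 5.0)
        rlon = parent_centre(records["lon"].to_numpy(), 5.0)
    li = np.searchsorted(lats, rlat)
    oi = np.searchsorted(lons, rlon)
    bad = (
        (li >= len(lats))
        | (oi >= len(lons))
        | (lats[np.clip(li, 0, len(lats) - 1)] != rlat)
        | (lons[np.clip(oi, 0, len(lons) - 1)] != rlon)
    )
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} record(s) fall outside the cube grid; subset to the region first"
        )

    if period is None:
        period = (int(records["year"].min()), int(records["year"].max()))
    tindex = quarter_range(*period)
    q = _quarter_index(records)
    ti = tindex.get_indexer(q)
    if (ti < 0).any():
        raise ValueError("record quarter outside the cube period")

    values = np.full((len(tindex), len(lats), len(lons)), np.nan)
    flat = ti * (len(lats) * len(lons)) + li * len(lons) + oi
    sums = np.bincount(
        flat, weights=records["effort_hours"].to_numpy(dtype=float), minlength=values.size
    )
    touched = np.zeros(values.size, dtype=bool)
    touched[np.unique(flat)] = True
    vflat = values.ravel()
    vflat[touched] = sums[touched]
    return EffortCube(vflat.reshape(values.shape), tindex, lats, lons, float(cell_deg))


def read_ssta_table(path, box: RegionBox = STUDY_REGION,
                    period: tuple[int, int] | None = None) -> SSTACube:
    """Read long-format monthly SSTA CSV and aggregate to a quarterly 5x5 cube.

    Expected columns: ``year,month,lat,lon,ssta``.  Monthly values are
    averaged within each quarter (missing months ignored).
    """
    df = pd.read_csv(path)
    missing = [c for c in ("year", "month", "lat", "lon", "ssta") if c not in df.columns]
    if missing:
        raise SchemaError(f"SSTA CSV missing required column(s): {', '.join(missing)}")
    df = df.dropna(subset=["ssta"])
    keep = box.contains(df["lat"].to_numpy(), df["lon"].to_numpy())
    df = df.loc[keep].reset_index(drop=True)
    if len(df) == 0:
        raise EmptyInputError("no SSTA values inside the study region")

    lats = cell_centres(box.lat_min, box.lat_max, 5)
    lons = cell_centres(box.lon_min, box.lon_max, 5)
    if period is None:
        period = (int(df["year"].min()), int(df["year"].max()))
    tindex = quarter_range(*period)
    q = _quarter_index(df)
    ti = tindex.get_indexer(q)
    li = np.searchsorted(lats, df["lat"].to_numpy(dtype=float))
    oi = np.searchsorted(lons, df["lon"].to_numpy(dtype=float))
    flat = ti * (len(lats) * len(lons)) + li * len(lons) + oi
    sums = np.bincount(flat, weights=df["ssta"].to_numpy(dtype=float),
                       minlength=len(tindex) * len(lats) * len(lons))
    counts = np.bincount(flat, minlength=sums.size)
    values = np.full(sums.size, np.nan)
    values[counts > 0] = sums[counts > 0] / counts[counts > 0]
    return SSTACube(values.reshape(len(tindex), len(lats), len(lons)),
                    tindex, lats, lons, 5.0)


def read_ssta_netcdf(path, var: str = "ssta", box: RegionBox = STUDY_REGION) -> SSTACube:
    """Read a CF-style (time, lat, lon) anomaly NetCDF and aggregate to quarters."""
    import xarray as xr

    ds = xr.open_dataset(path, engine="scipy")
    da = ds[var]
    da = da.sel(
        lat=da.lat[(da.lat >= box.lat_min) & (da.lat <= box.lat_max)],
        lon=da.lon[(da.lon >= box.lon_min) & (da.lon <= box.lon_max)],
    )
    t = pd.DatetimeIndex(da["time"].values)
    frame = pd.DataFrame(
        da.values.reshape(len(t), -1), index=t.to_period("Q")
    )
    quarterly = frame.groupby(level=0).mean()
    tindex = pd.period_range(quarterly.index[0], quarterly.index[-1], freq="Q")
    quarterly = quarterly.reindex(tindex)
    return SSTACube(
        quarterly.to_numpy().reshape(len(tindex), da.sizes["lat"], da.sizes["lon"]),
        tindex,
        da["lat"].values,
        da["lon"].values,
        5.0,
    )


def compute_anomaly(cube: QuarterCube) -> AnomalyMatrix:
    """Deseasonalise a cube: subtract each cell's quarter-of-year mean.

    The climatology is the mean over all observed years of that
    quarter-of-year at that cell, computed over the entire data period.
    Columns with no observation at all are dropped; a cell-quarter-of-year
    stratum that is entirely missing stays missing (logged).
    """
    n_t = cube.n_quarters
    if n_t < 8:
        raise InsufficientDataError("anomaly computation needs >= 2 full years")
    flat = cube.values.reshape(n_t, -1)
    has_obs = ~np.all(np.isnan(flat), axis=0)
    if not has_obs.any():
        raise EmptyInputError("cube has no observed cells")
    flat = flat[:, has_obs]
    grid = [
        (lat, lon)
        for lat in cube.lats
        for lon in cube.lons
    ]
    space_index = [cell for cell, keep in zip(grid, has_obs) if keep]

    qoy = cube.time_index.quarter.to_numpy()
    clim = np.full((4, flat.shape[1]), np.nan)
    with np.errstate(invalid="ignore"):
        for q in range(1, 5):
            rows = flat[qoy == q]
            if len(rows):
                any_obs = ~np.all(np.isnan(rows), axis=0)
                clim[q - 1, any_obs] = np.nanmean(rows[:, any_obs], axis=0)
    n_empty = int(np.isnan(clim).sum())
    if n_empty:
        log.warning(
            "compute_anomaly: %d cell-quarter-of-year strata entirely missing", n_empty
        )
    anomalies = flat - clim[qoy - 1, :]
    return AnomalyMatrix(anomalies, cube.time_index, space_index, clim)


def regional_mean_series(cube: QuarterCube, box: RegionBox | None = None) -> pd.Series:
    """Unweighted mean over non-missing in-box cells, per quarter.

    No cos(latitude) area weighting is applied: the region straddles the
    equator and the grid is coarse, so equal weights are used.
    """
    flat = cube.values.reshape(cube.n_quarters, -1)
    if box is not None:
        glat, glon = np.meshgrid(cube.lats, cube.lons, indexing="ij")
        inside = box.contains(glat.ravel(), glon.ravel())
        flat = flat[:, inside]
    with np.errstate(invalid="ignore"):
        all_nan = np.all(np.isnan(flat), axis=1)
        means = np.full(cube.n_quarters, np.nan)
        if (~all_nan).any():
            means[~all_nan] = np.nanmean(flat[~all_nan], axis=1)
    return pd.Series(means, index=cube.time_index, name="regional_mean")


def linear_trend(series: pd.Series) -> TrendFit:
    """OLS trend of a quarterly or annual series (see :func:`fit_trend`)."""
    return fit_trend(series)


def fad_catch_proportion(records: pd.DataFrame) -> pd.Series:
    """Quarterly % of total catch (all species) taken on FADs.

    100 x sum(catch_fad) / sum(catch_fad + catch_free); quarters with zero
    total catch are missing.
    """
    q = _quarter_index(records)
    fad = records.groupby(q)["catch_fad_t"].sum()
    free = records.groupby(q)["catch_free_t"].sum()
    total = fad + free
    prop = 100.0 * fad / total.where(total > 0)
    prop.name = "fad_prop"
    prop.index.name = "quarter"
    return prop
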