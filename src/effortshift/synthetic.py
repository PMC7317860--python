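"""Synthetic gridded effort, SSTA and covariate generator with known truth.

The generator emulates the statistical structure the analysis pipeline
assumes, with every target quantity recorded for parameter-recovery tests:

* an SSTA field built from orthonormal spatial modes with prescribed
  variance fractions (a near-uniform, sign-coherent warming mode leading),
  an optional long-term linear trend, and white noise;
* an effort field over a realistic fished footprint whose leading anomaly
  mode is a north/south dipole, whose PC1 has a configured correlation with
  the SSTA PC1 (Gaussian-copula construction with exact sample moments),
  with a quarter-of-year climatology, a southern centre-of-gravity drift,
  and MCAR missingness whose held-out true values are recorded;
* a quarterly covariate table (SSTA mean, quarter factor, FAD catch
  proportion, TAC and closure flags, SFPA counts) with responses assembled
  from configured coefficients.

Positivity of effort is achieved additively: a seasonal baseline, scaled so
its floor sits several standard deviations above zero, carries a
spatially-uniform-variance structured anomaly; this keeps the targeted
mode-variance fractions exact (an exponential link would modulate the
anomaly covariance by the baseline pattern).  The southern COG drift is
injected as a within-5-degree-parent tilt of the 1-degree child weights,
solved per year so that the expected southern COG moves linearly at the
configured rate while the 5x5 quarterly sums - the EOF side of the
analysis - are exactly unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .containers import (
    EffortCube,
    RegionBox,
    SSTACube,
    STUDY_REGION,
    cell_centres,
    quarter_range,
)
from .errors import ConfigError

log = logging.getLogger(__name__)


def _gauss(x, mu, sd):
    return np.exp(-0.5 * ((np.asarray(x, dtype=float) - mu) / sd) ** 2)


@dataclass
class SyntheticConfig:
    """Study conditions for the generator (defaults mirror the analysis setup)."""

    seed: int = 0
    years: tuple = (1991, 2017)
    box: RegionBox = STUDY_REGION
    # --- SSTA field ---
    ssta_mode_fracs: tuple = (0.70, 0.10, 0.05)
    ssta_cell_var: float = 0.09  # degC^2 per-cell anomaly variance
    ssta_mean: float = 0.4  # degC regional offset vs the product baseline
    ssta_trend_total: float = 0.82  # degC rise over trend_span
    trend_span: tuple = (1856, 2017)
    include_trend: bool = True
    # --- effort field ---
    effort_mode_fracs: tuple = (0.19, 0.12, 0.09, 0.08, 0.07, 0.06, 0.05, 0.04)
    effort_cell_sd: float = 75.0  # hours, per 5-deg cell-quarter anomaly SD
    pc_correlation: float = 0.5  # effortA PC1 vs SSTA PC1
    cog_drift_deg_per_year: float = -0.05  # southern-hemisphere drift
    missing_frac: float = 0.15  # MCAR missing cell-quarters
    seasonal_amp: float = 0.15  # quarter-of-year climatology amplitude
    positivity_margin: float = 6.0  # baseline floor in units of anomaly SD
    footprint_threshold: float = 0.25  # keep 5-deg cells above this rel. weight
    catchability_t_per_hour: float = 0.05
    # --- covariates ---
    fad_prop_range: tuple = (25.9, 91.7)
    agr_num_range: tuple = (4, 10)
    agr_vessel_range: tuple = (25, 41)
    covariate_effects_effort: dict = field(
        default_factory=lambda: {"fad_prop": 1.0, "agr_vessel": 0.8, "ssta": 0.3}
    )
    covariate_effects_pc1: dict = field(
        default_factory=lambda: {"agr_vessel": 1.0, "ssta": 0.8, "tac": 0.6}
    )
    covariate_noise_ratio: float = 0.5  # noise SD as a fraction of signal SD
    effort_response_loc_scale: tuple = (26559.0, 7361.0)
    pc1_response_loc_scale: tuple = (0.0, 2.2)


@dataclass
class SyntheticTruth:
    """Ground truth recorded alongside a generated dataset."""

    # SSTA
    ssta_space: list | None = None
    ssta_modes: np.ndarray | None = None
    ssta_pcs: np.ndarray | None = None
    ssta_drivers: np.ndarray | None = None  # standardized, orthogonal PC drivers
    ssta_eigenvalues: np.ndarray | None = None
    ssta_noise_var: float | None = None
    ssta_trend_slope_per_quarter: float | None = None
    # effort
    effort_space: list | None = None  # fished 5-deg footprint cells
    effort_modes: np.ndarray | None = None
    effort_pcs: np.ndarray | None = None
    effort_eigenvalues: np.ndarray | None = None
    effort_noise_var: float | None = None
    pc_correlation: float | None = None
    cog_slope_deg_per_year: float | None = None
    masked: pd.DataFrame | None = None  # quarter, lat, lon, true_total
    fad_prop: pd.Series | None = None
    baseline: np.ndarray | None = None  # per-footprint-cell baseline hours
    n_clipped: int = 0
    # covariates
    coefficients_effort: dict | None = None
    coefficients_pc1: dict | None = None
    noise_ratio: float | None = None


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((config.seed, stream)))


def _orthonormal_drivers(z: np.ndarray) -> np.ndarray:
    """Zero-mean, exactly orthogonal, unit-sample-variance time series.

    Columns are centred and QR-orthogonalised, then rescaled so each has
    sample variance 1 (ddof=1); signs keep a positive projection on the
    original columns.
    """
    z = z - z.mean(axis=0)
    q, _ = np.linalg.qr(z)
    for i in range(q.shape[1]):
        if q[:, i] @ z[:, i] < 0:
            q[:, i] = -q[:, i]
    q = q - q.mean(axis=0)  # numerically re-centre
    q /= q.std(axis=0, ddof=1)
    return q


def _spatial_modes(raws: list, rng: np.random.Generator, n_modes: int, n_space: int) -> np.ndarray:
    """Orthonormal spatial modes: prescribed patterns first, then random fill."""
    cols = [np.asarray(r, dtype=float) for r in raws[:n_modes]]
    while len(cols) < n_modes:
        cols.append(rng.standard_normal(n_space))
    M = np.column_stack(cols)
    q, _ = np.linalg.qr(M)
    for i in range(n_modes):
        j = int(np.argmax(np.abs(q[:, i])))
        if q[j, i] < 0:
            q[:, i] = -q[:, i]
    return q


def _check_fracs(fracs, what: str) -> np.ndarray:
    fr = np.asarray(fracs, dtype=float)
    if np.any(fr <= 0) or fr.sum() > 1 + 1e-12:
        raise ConfigError(f"{what} mode variance fractions must be positive and sum to <= 1")
    return fr


def generate_ssta(config: SyntheticConfig, years: tuple | None = None):
    """Generate a quarterly SSTA cube over the full study grid.

    Returns ``(SSTACube, SyntheticTruth)``.  Pass ``years`` to override the
    study span (e.g. the long 1856-2017 run used for the trend analysis).
    """
    rng = _rng(config, 1)
    years = tuple(years or config.years)
    quarters = quarter_range(*years)
    n_t = len(quarters)
    lats = cell_centres(config.box.lat_min, config.box.lat_max, 5)
    lons = cell_centres(config.box.lon_min, config.box.lon_max, 5)
    glat, glon = np.meshgrid(lats, lons, indexing="ij")
    glat, glon = glat.ravel(), glon.ravel()
    n_s = len(glat)

    fr = _check_fracs(config.ssta_mode_fracs, "SSTA")
    n_m = len(fr)
    raws = [1.0 + 0.3 * np.cos(np.pi * glat / 60.0), glat / 30.0, glon / 30.0]
    modes = _spatial_modes(raws, rng, n_m, n_s)
    total_var = n_s * config.ssta_cell_var
    lam = fr * total_var
    noise_var = max((1.0 - fr.sum()) * total_var / n_s, 0.0)

    drivers = _orthonormal_drivers(rng.standard_normal((n_t, n_m)))
    pcs = drivers * np.sqrt(lam)
    fld = pcs @ modes.T + rng.normal(0.0, np.sqrt(noise_var), (n_t, n_s))

    slope = 0.0
    if config.include_trend:
        n_long = len(quarter_range(*config.trend_span))
        slope = config.ssta_trend_total / (n_long - 1)
        t_rel = quarters.asi8.astype(float)
        t_rel -= t_rel.mean()
        fld += slope * t_rel[:, None]
    fld += config.ssta_mean

    cube = SSTACube(fld.reshape(n_t, len(lats), len(lons)), quarters, lats, lons, 5.0)
    truth = SyntheticTruth(
        ssta_space=list(zip(glat, glon)),
        ssta_modes=modes,
        ssta_pcs=pcs,
        ssta_drivers=drivers,
        ssta_eigenvalues=lam,
        ssta_noise_var=noise_var,
        ssta_trend_slope_per_quarter=slope,
    )
    return cube, truth


def ssta_to_monthly_frame(cube: SSTACube) -> pd.DataFrame:
    """Long-format monthly CSV rows (each quarter's value on its 3 months)."""
    rows = []
    glat, glon = np.meshgrid(cube.lats, cube.lons, indexing="ij")
    glat, glon = glat.ravel(), glon.ravel()
    for t, period in enumerate(cube.time_index):
        vals = cube.values[t].ravel()
        ok = ~np.isnan(vals)
        for m in range(3):
            month = 3 * (period.quarter - 1) + m + 1
            rows.append(
                pd.DataFrame(
                    {
                        "year": period.year,
                        "month": month,
                        "lat": glat[ok],
                        "lon": glon[ok],
                        "ssta": vals[ok],
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# effort generator
# ---------------------------------------------------------------------------

_LAT_BUMPS = ((10.0, 5.0, 0.8), (-12.0, 6.0, 1.0))  # (centre, width, weight)
_LON_BUMP = (-10.0, 12.0)
_CHILD_OFFSETS = np.arange(-2.0, 3.0)  # 1-deg child centres within a 5-deg parent


def _lat_profile(lat):
    out = np.zeros_like(np.asarray(lat, dtype=float))
    for mu, sd, w in _LAT_BUMPS:
        out = out + w * _gauss(lat, mu, sd)
    return out


def _lon_profile(lon):
    return _gauss(lon, *_LON_BUMP)


def _seasonal(quarter):
    """Quarter-of-year multiplier of the effort baseline."""
    return 1.0 + 0.15 * np.cos(2.0 * np.pi * (np.asarray(quarter) - 1) / 4.0)


def _footprint(config: SyntheticConfig):
    lats = cell_centres(config.box.lat_min, config.box.lat_max, 5)
    lons = cell_centres(config.box.lon_min, config.box.lon_max, 5)
    glat, glon = np.meshgrid(lats, lons, indexing="ij")
    glat, glon = glat.ravel(), glon.ravel()
    w = _lat_profile(glat) * _lon_profile(glon)
    keep = w >= config.footprint_threshold * w.max()
    return glat[keep], glon[keep], w[keep]


def _child_grid(plat: np.ndarray, plon: np.ndarray):
    """1-degree child cells of each 5-degree parent: (P, 25) lat/lon arrays."""
    dla, dlo = np.meshgrid(_CHILD_OFFSETS, _CHILD_OFFSETS, indexing="ij")
    clat = plat[:, None] + dla.ravel()[None, :]
    clon = plon[:, None] + dlo.ravel()[None, :]
    return clat, clon


def _solve_tilt(plat, clat, u, base_w, years, drift):
    """Per-year southern tilt coefficients giving an exactly linear COG drift.

    ``u`` are the static child weights (P, 25); the tilt multiplies southern
    children by (1 + tau * (child_lat - parent_lat)).  tau is solved per
    year so the baseline-weighted southern mean latitude moves by
    ``drift * (year - mid-year)`` relative to its tau=0 value.
    """
    south = plat < 0
    if not south.any() or drift == 0:
        return {int(y): 0.0 for y in years}
    dlat = clat[south] - plat[south, None]
    us = u[south]
    ws = base_w[south]
    lat_s = clat[south]

    def mean_lat(tau: float) -> float:
        w = us * (1.0 + tau * dlat)
        w = w / w.sum(axis=1, keepdims=True)
        per_parent = (w * lat_s).sum(axis=1)
        return float((ws * per_parent).sum() / ws.sum())

    base = mean_lat(0.0)
    mid = float(np.mean(years))
    dmax = float(np.abs(dlat).max())
    bound = 0.999 / dmax  # keep all tilted weights positive
    taus = {}
    for y in years:
        target = drift * (float(y) - mid)
        f = lambda tau: mean_lat(tau) - base - target
        if f(-bound) * f(bound) > 0:
            raise ConfigError(
                "cog_drift_deg_per_year too large for the within-parent tilt"
            )
        taus[int(y)] = float(brentq(f, -bound, bound, xtol=1e-12))
    return taus


def generate_effort(config: SyntheticConfig, ssta_truth: SyntheticTruth | None = None,
                    as_records: bool = True):
    """Generate purse-seine effort with known anomaly structure.

    Returns ``(records, truth)`` where ``records`` is a monthly 1x1-degree
    effort/catch table matching the documented CSV schema (default), or
    ``(EffortCube, truth)`` with ``as_records=False`` for the quarterly
    5x5 cube directly (faster; identical by construction, since child
    records are an exact disaggregation of the cell-quarter totals).
    """
    rng = _rng(config, 2)
    quarters = quarter_range(*config.years)
    n_t = len(quarters)
    years_axis = np.arange(config.years[0], config.years[1] + 1)

    r = float(config.pc_correlation)
    if not -1.0 <= r <= 1.0:
        raise ConfigError(f"pc_correlation must lie in [-1, 1], got {r}")

    plat, plon, w5 = _footprint(config)
    n_s = len(plat)
    fr = _check_fracs(config.effort_mode_fracs, "effort")
    n_m = len(fr)
    raws = [np.tanh((-5.0 - plat) / 7.5), plon / 30.0]
    modes = _spatial_modes(raws, rng, n_m, n_s)
    total_var = n_s * config.effort_cell_sd ** 2
    lam = fr * total_var
    noise_var = max((1.0 - fr.sum()) * total_var / n_s, 0.0)

    drivers = _orthonormal_drivers(rng.standard_normal((n_t, n_m)))
    if r != 0.0:
        if ssta_truth is None or ssta_truth.ssta_drivers is None:
            raise ConfigError("ssta_truth is required when pc_correlation != 0")
        z_s = ssta_truth.ssta_drivers[:, 0]
        if len(z_s) != n_t:
            raise ConfigError("SSTA truth does not span the effort study period")
        eta = drivers[:, 0] - (drivers[:, 0] @ z_s) / (z_s @ z_s) * z_s
        eta = eta - eta.mean()
        eta /= eta.std(ddof=1)
        z1 = r * z_s + np.sqrt(1.0 - r ** 2) * eta
        drivers = _orthonormal_drivers(np.column_stack([z1, drivers[:, 1:]]))
    pcs = drivers * np.sqrt(lam)
    anomalies = pcs @ modes.T + rng.normal(0.0, np.sqrt(noise_var), (n_t, n_s))

    # seasonal baseline with its floor `positivity_margin` SDs above zero
    sd_cell = np.sqrt(modes ** 2 @ lam + noise_var)
    s_min = float(_seasonal(np.arange(1, 5)).min())
    baseline = w5 / w5.min() * (config.positivity_margin * sd_cell.max() / s_min)
    season = _seasonal(quarters.quarter.to_numpy())
    totals = season[:, None] * baseline[None, :] + anomalies
    n_clipped = int((totals < 0).sum())
    if n_clipped:
        log.warning("generate_effort: clipped %d negative cell-quarter total(s)", n_clipped)
        totals = np.maximum(totals, 0.0)

    mask = rng.random((n_t, n_s)) < config.missing_frac
    ti, si = np.nonzero(mask)
    masked = pd.DataFrame(
        {
            "quarter": quarters[ti],
            "lat": plat[si],
            "lon": plon[si],
            "true_total": totals[ti, si],
        }
    )

    # FAD catch share: monotone ramp + noise inside the documented range
    lo, hi = config.fad_prop_range
    ramp = np.linspace(lo + 4.0, hi - 4.0, n_t)
    fad_prop = np.clip(ramp + rng.normal(0.0, 4.0, n_t), lo, hi)
    fad_series = pd.Series(fad_prop, index=quarters, name="fad_prop")

    truth = SyntheticTruth(
        effort_space=list(zip(plat, plon)),
        effort_modes=modes,
        effort_pcs=pcs,
        effort_eigenvalues=lam,
        effort_noise_var=noise_var,
        pc_correlation=r,
        cog_slope_deg_per_year=config.cog_drift_deg_per_year,
        masked=masked,
        fad_prop=fad_series,
        baseline=baseline,
        n_clipped=n_clipped,
    )

    if not as_records:
        lats = cell_centres(config.box.lat_min, config.box.lat_max, 5)
        lons = cell_centres(config.box.lon_min, config.box.lon_max, 5)
        vals = np.full((n_t, len(lats), len(lons)), np.nan)
        li = np.searchsorted(lats, plat)
        oi = np.searchsorted(lons, plon)
        obs = totals.copy()
        obs[mask] = np.nan
        vals[:, li, oi] = obs
        cube = EffortCube(vals, quarters, lats, lons, 5.0)
        return cube, truth

    # --- disaggregate to monthly 1x1-degree records ---
    clat, clon = _child_grid(plat, plon)
    u = _lat_profile(clat) * _lon_profile(clon)  # (P, 25) static child weights
    taus = _solve_tilt(plat, clat, u, baseline, years_axis, config.cog_drift_deg_per_year)

    south = plat < 0
    dlat = clat - plat[:, None]
    tau_t = np.array([taus[p.year] for p in quarters])  # (T,)
    w = np.broadcast_to(u, (n_t, n_s, 25)).copy()
    w[:, south, :] *= 1.0 + tau_t[:, None, None] * dlat[None, south, :]
    w /= w.sum(axis=2, keepdims=True)

    keep_tq = ~mask  # masked cell-quarters produce no records at all
    child_q = totals[:, :, None] * w  # (T, P, 25) quarterly child effort

    frames = []
    fleet_labels = np.array(["EU-ES", "EU-FR", "GH-PS"])[np.arange(n_s) % 3]
    q_of = quarters.quarter.to_numpy()
    y_of = quarters.year.to_numpy()
    for t in range(n_t):
        cells = np.nonzero(keep_tq[t])[0]
        if len(cells) == 0:
            continue
        eff = child_q[t][cells] / 3.0  # equal thirds across the 3 months
        lat_f = clat[cells].ravel()
        lon_f = clon[cells].ravel()
        fleet_f = np.repeat(fleet_labels[cells], 25)
        share = fad_prop[t] / 100.0
        for m in range(3):
            month = 3 * (q_of[t] - 1) + m + 1
            e = eff.ravel()
            catch = e * config.catchability_t_per_hour
            frames.append(
                pd.DataFrame(
                    {
                        "year": y_of[t],
                        "month": month,
                        "lat": lat_f,
                        "lon": lon_f,
                        "effort_hours": e,
                        "catch_fad_t": catch * share,
                        "catch_free_t": catch * (1.0 - share),
                        "fleet": fleet_f,
                    }
                )
            )
    records = pd.concat(frames, ignore_index=True)
    return records, truth


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------


def _bounded_walk(rng, n, start, lo, hi):
    steps = rng.choice([-1, 0, 1], size=n, p=[0.25, 0.5, 0.25])
    out = np.empty(n, dtype=int)
    v = start
    for i in range(n):
        v = int(np.clip(v + steps[i], lo, hi))
        out[i] = v
    return out


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def generate_covariates(
    config: SyntheticConfig,
    ssta_series: pd.Series | None = None,
    fad_prop: pd.Series | None = None,
    effort_series: pd.Series | None = None,
    pc1_series: pd.Series | None = None,
):
    """Generate the quarterly driver table and its responses.

    Regime variables emulate the management history: the TAC flag switches
    on in 1998, seasonal time-area closures (quarters 4 and 1) from 1997,
    and the SFPA count/vessel allowances follow bounded integer random
    walks inside their documented ranges.  Responses are linear
    combinations of the configured standardized predictors plus Gaussian
    noise, rescaled to realistic location/scale - unless measured series
    are passed in, which are then used verbatim.

    Returns ``(table, truth)``.
    """
    rng = _rng(config, 3)
    quarters = quarter_range(*config.years)
    n_t = len(quarters)
    qtr = quarters.quarter.to_numpy()
    yr = quarters.year.to_numpy()

    if ssta_series is not None:
        ssta = ssta_series.reindex(quarters).to_numpy(dtype=float)
    else:
        innov = rng.normal(0.0, 0.2 * np.sqrt(1 - 0.7 ** 2), n_t)
        e = np.empty(n_t)
        prev = 0.0
        for t in range(n_t):
            prev = 0.7 * prev + innov[t]
            e[t] = prev
        ssta = np.clip(0.4 + e, -0.2, 1.1)

    if fad_prop is not None:
        fad = fad_prop.reindex(quarters).to_numpy(dtype=float)
    else:
        lo, hi = config.fad_prop_range
        fad = np.clip(
            np.linspace(lo + 4.0, hi - 4.0, n_t) + rng.normal(0.0, 4.0, n_t), lo, hi
        )

    tac = (yr >= 1998).astype(int)
    closure = ((yr >= 1997) & np.isin(qtr, (1, 4))).astype(int)
    agr_num = _bounded_walk(rng, n_t, 8, *config.agr_num_range)
    agr_vessel = _bounded_walk(rng, n_t, 31, *config.agr_vessel_range)

    table = pd.DataFrame(
        {
            "ssta": ssta,
            "quarter": qtr,
            "fad_prop": fad,
            "tac": tac,
            "closure": closure,
            "agr_num": agr_num,
            "agr_vessel": agr_vessel,
        },
        index=quarters,
    )

    def _response(effects: dict, loc: float, scale: float, stream: int) -> np.ndarray:
        rr = _rng(config, stream)
        signal = np.zeros(n_t)
        for name, beta in effects.items():
            signal = signal + beta * _standardize(table[name].to_numpy(dtype=float))
        sig_sd = signal.std(ddof=1)
        if sig_sd == 0:
            sig_sd = 1.0
        noise = rr.normal(0.0, config.covariate_noise_ratio * sig_sd, n_t)
        y = signal + noise
        return loc + scale * _standardize(y)

    if effort_series is not None:
        table["response_effort"] = effort_series.reindex(quarters).to_numpy(dtype=float)
        coeff_e = None
    else:
        table["response_effort"] = _response(
            config.covariate_effects_effort, *config.effort_response_loc_scale, stream=4
        )
        coeff_e = dict(config.covariate_effects_effort)
    if pc1_series is not None:
        table["response_pc1"] = pc1_series.reindex(quarters).to_numpy(dtype=float)
        coeff_p = None
    else:
        table["response_pc1"] = _response(
            config.covariate_effects_pc1, *config.pc1_response_loc_scale, stream=5
        )
        coeff_p = dict(config.covariate_effects_pc1)

    truth = SyntheticTruth(
        coefficients_effort=coeff_e,
        coefficients_pc1=coeff_p,
        noise_ratio=config.covariate_noise_ratio,
    )
    return table, truth


def alignment_sign(space_est, mode_est, space_true, mode_true) -> float:
    """Sign of the inner product of an estimated and a true spatial mode.

    The estimated decomposition may cover a subset of the true cells (e.g.
    after the <25%-missing selection); cells are matched by their (lat,
    lon) centres.  Used to orient estimated PCs against truth before
    comparing correlations.
    """
    lookup = {tuple(c): v for c, v in zip(space_true, mode_true)}
    dot = sum(v * lookup[tuple(c)] for c, v in zip(space_est, mode_est) if tuple(c) in lookup)
    return 1.0 if dot >= 0 else -1.0


@dataclass
class SyntheticBundle:
    """A complete synthetic study dataset with its ground truth."""

    config: SyntheticConfig
    effort_records: pd.DataFrame
    effort_truth: SyntheticTruth
    ssta_cube: SSTACube
    ssta_truth: SyntheticTruth
    covariates: pd.DataFrame
    covariate_truth: SyntheticTruth


def generate_all(config: SyntheticConfig, as_records: bool = True) -> SyntheticBundle:
    """Generate the three linked inputs (SSTA, effort, covariates)."""
    ssta_cube, ssta_truth = generate_ssta(config)
    effort, effort_truth = generate_effort(config, ssta_truth, as_records=as_records)
    covariates, cov_truth = generate_covariates(config, fad_prop=effort_truth.fad_prop)
    return SyntheticBundle(
        config, effort, effort_truth, ssta_cube, ssta_truth, covariates, cov_truth
    )


def write_bundle(bundle: SyntheticBundle, outdir) -> dict:
    """Write effort.csv, ssta.csv, covariates.csv and truth.json to a directory."""
    import json
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "effort": outdir / "effort.csv",
        "ssta": outdir / "ssta.csv",
        "covariates": outdir / "covariates.csv",
        "truth": outdir / "truth.json",
    }
    bundle.effort_records.to_csv(paths["effort"], index=False)
    ssta_to_monthly_frame(bundle.ssta_cube).to_csv(paths["ssta"], index=False)
    bundle.covariates.rename_axis("period").to_csv(paths["covariates"])
    summary = {
        "seed": bundle.config.seed,
        "years": list(bundle.config.years),
        "pc_correlation": bundle.effort_truth.pc_correlation,
        "cog_slope_deg_per_year": bundle.effort_truth.cog_slope_deg_per_year,
        "effort_mode_fracs": list(bundle.config.effort_mode_fracs),
        "ssta_mode_fracs": list(bundle.config.ssta_mode_fracs),
        "missing_frac": bundle.config.missing_frac,
        "n_masked": int(len(bundle.effort_truth.masked)),
        "n_footprint_cells": len(bundle.effort_truth.effort_space),
    }
    paths["truth"].write_text(json.dumps(summary, indent=2))
    return {k: str(v) for k, v in paths.items()}
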