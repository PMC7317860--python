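"""Ingestion, aggregation, anomaly and summary-series contracts."""

import numpy as np
import pandas as pd
import pytest

from effortshift.containers import STUDY_REGION, RegionBox, quarter_range
from effortshift.errors import EmptyInputError, InsufficientDataError, SchemaError
from effortshift.grid_ingest import (
    aggregate_effort,
    compute_anomaly,
    fad_catch_proportion,
    linear_trend,
    read_effort_table,
    regional_mean_series,
    subset_region,
)

from .conftest import make_records, random_records

HEADER = "year,month,lat,lon,effort_hours,catch_fad_t,catch_free_t,fleet\n"


class TestReadEffortTable:
    def test_well_formed_rows_are_read_verbatim(self, tmp_path):
        p = tmp_path / "e.csv"
        p.write_text(
            HEADER
            + "1991,1,0.5,-20.5,10,1,2,A\n"
            + "1992,7,5.5,-10.5,3.5,0,0,B\n"
            + "2017,12,-3.5,2.5,0,0.5,,C\n"
        )
        records, n_rejected = read_effort_table(p)
        assert len(records) == 3 and n_rejected == 0
        assert records.loc[2, "catch_free_t"] == 0.0  # empty field -> 0 tonnes

    def test_negative_or_non_numeric_effort_rejected_with_count(self, tmp_path):
        p = tmp_path / "e.csv"
        p.write_text(
            HEADER
            + "1991,1,0.5,-20.5,-1,0,0,A\n"
            + "1991,2,0.5,-20.5,abc,0,0,A\n"
            + "1991,3,0.5,-20.5,7,0,0,A\n"
        )
        records, n_rejected = read_effort_table(p)
        assert len(records) == 1 and n_rejected == 2

    def test_missing_column_names_the_column(self, tmp_path):
        p = tmp_path / "e.csv"
        p.write_text("year,month,lat,lon,catch_fad_t,catch_free_t,fleet\n1991,1,0.5,0.5,0,0,A\n")
        with pytest.raises(SchemaError, match="effort_hours"):
            read_effort_table(p)

    def test_empty_file_raises(self, tmp_path):
        p = tmp_path / "e.csv"
        p.write_text("")
        with pytest.raises(EmptyInputError):
            read_effort_table(p)
        p.write_text(HEADER)
        with pytest.raises(EmptyInputError):
            read_effort_table(p)

    def test_year_span_of_generated_file(self, tmp_path, default_bundle):
        p = tmp_path / "effort.csv"
        default_bundle["records"].to_csv(p, index=False)
        records, n_rejected = read_effort_table(p)
        assert n_rejected == 0
        assert records["year"].min() == 1991 and records["year"].max() == 2017


class TestSubsetRegion:
    def test_interior_point_retained_exterior_dropped(self):
        records = make_records([(1991, 1, 0.5, -20.5, 1.0), (1991, 1, 35.5, -20.5, 1.0)])
        kept = subset_region(records)
        assert len(kept) == 1 and kept.loc[0, "lat"] == 0.5

    def test_boundary_cells_retained_closed_interval(self):
        records = make_records([(1991, 1, 29.0, 19.0, 1.0), (1991, 1, -30.0, -35.0, 1.0)])
        assert len(subset_region(records)) == 2

    def test_matches_brute_force_point_in_box(self):
        rng = np.random.default_rng(7)
        records = make_records(
            [
                (1991, 1, float(rng.uniform(-60, 60)), float(rng.uniform(-80, 40)), 1.0)
                for _ in range(100)
            ]
        )
        kept = subset_region(records)
        expect = sum(
            1
            for _, r in records.iterrows()
            if -30 <= r["lat"] <= 29 and -35 <= r["lon"] <= 19
        )
        assert len(kept) == expect


class TestAggregateEffort:
    def test_same_cell_same_quarter_sums(self):
        records = make_records([(1991, 1, 0.5, -20.5, 10.0), (1991, 2, 0.5, -20.5, 5.0)])
        cube = aggregate_effort(records, cell_deg=1)
        t = cube.time_index.get_loc(pd.Period("1991Q1"))
        i = np.searchsorted(cube.lats, 0.5)
        j = np.searchsorted(cube.lons, -20.5)
        assert cube.values[t, i, j] == 15.0

    def test_july_lands_in_quarter_three(self):
        cube = aggregate_effort(make_records([(1991, 7, 0.5, -20.5, 4.0)]), cell_deg=1)
        t = cube.time_index.get_loc(pd.Period("1991Q3"))
        assert np.nansum(cube.values[t]) == 4.0
        assert np.nansum(cube.values) == 4.0

    def test_empty_cells_are_missing_not_zero(self):
        cube = aggregate_effort(make_records([(1991, 1, 0.5, -20.5, 4.0)]), cell_deg=5)
        assert np.isnan(cube.values).sum() == cube.values.size - 1

    def test_matches_brute_force_group_and_sum(self):
        rng = np.random.default_rng(11)
        records = random_records(rng, 200)
        cube = aggregate_effort(records, cell_deg=5, period=(1991, 2017))
        # independent oracle: explicit group-and-sum over records
        expected = {}
        for _, r in records.iterrows():
            key = (
                pd.Period(year=int(r["year"]), quarter=(int(r["month"]) + 2) // 3, freq="Q"),
                np.floor(r["lat"] / 5) * 5 + 2.5,
                np.floor(r["lon"] / 5) * 5 + 2.5,
            )
            expected[key] = expected.get(key, 0.0) + r["effort_hours"]
        for (period, lat, lon), total in expected.items():
            t = cube.time_index.get_loc(period)
            i = np.searchsorted(cube.lats, lat)
            j = np.searchsorted(cube.lons, lon)
            assert cube.values[t, i, j] == pytest.approx(total, rel=1e-12)
        assert np.nansum(cube.values) == pytest.approx(records["effort_hours"].sum(), rel=1e-9)

    def test_regrid_1_to_5_conserves_mass(self):
        rng = np.random.default_rng(13)
        records = random_records(rng, 300)
        c1 = aggregate_effort(records, cell_deg=1, period=(1991, 2017))
        c5 = aggregate_effort(records, cell_deg=5, period=(1991, 2017))
        assert np.nansum(c1.values) == pytest.approx(np.nansum(c5.values), rel=1e-9)

    def test_out_of_grid_record_is_a_hard_error(self):
        with pytest.raises(ValueError, match="outside"):
            aggregate_effort(make_records([(1991, 1, 45.5, 0.5, 1.0)]), cell_deg=1)

    def test_study_period_has_108_quarters(self):
        assert len(quarter_range(1991, 2017)) == 108


class TestComputeAnomaly:
    def _constant_cube(self, value=7.0, years=(1991, 1994)):
        records = make_records(
            [(y, m, 0.5, -20.5, 1.0) for y in range(years[0], years[1] + 1) for m in (1, 4, 7, 10)]
        )
        cube = aggregate_effort(records, cell_deg=1, period=years)
        cube.values[~np.isnan(cube.values)] = value
        return cube

    def test_constant_field_has_zero_anomaly(self):
        am = compute_anomaly(self._constant_cube())
        obs = am.values[~np.isnan(am.values)]
        assert np.allclose(obs, 0.0, atol=1e-12)

    def test_two_point_centring(self):
        records = make_records([(1991, 1, 0.5, -20.5, 2.0), (1992, 2, 0.5, -20.5, 4.0)])
        cube = aggregate_effort(records, cell_deg=1, period=(1991, 1992))
        am = compute_anomaly(cube)
        vals = am.values[~np.isnan(am.values)]
        assert sorted(vals.tolist()) == [-1.0, 1.0]

    def test_sinusoidal_climatology_matches_closed_form(self):
        # field(q-of-year) = A*sin(pi*q/2) constant across years: anomaly == 0
        years = (1991, 2000)
        cube = self._constant_cube(0.0, years)
        qoy = cube.time_index.quarter.to_numpy()
        seasonal = 3.0 * np.sin(np.pi * qoy / 2.0)
        cube.values[:, :, :] = np.where(np.isnan(cube.values), np.nan, seasonal[:, None, None])
        am = compute_anomaly(cube)
        assert np.nanmax(np.abs(am.values)) < 1e-9

    def test_round_trip_reproduces_observed_values(self, default_bundle):
        cube = aggregate_effort(default_bundle["records"], cell_deg=5, period=(1991, 2017))
        am = compute_anomaly(cube)
        grid = [(la, lo) for la in cube.lats for lo in cube.lons]
        cols = [grid.index(c) for c in am.space_index]
        observed_cube = cube.values.reshape(cube.n_quarters, -1)[:, cols]
        recon = am.observed()
        ok = ~np.isnan(observed_cube)
        assert np.allclose(recon[ok], observed_cube[ok], rtol=1e-12, atol=1e-9)

    def test_stratum_means_are_zero(self, default_bundle):
        cube = aggregate_effort(default_bundle["records"], cell_deg=5, period=(1991, 2017))
        am = compute_anomaly(cube)
        qoy = am.time_index.quarter.to_numpy()
        for q in range(1, 5):
            sub = am.values[qoy == q]
            col_means = np.nanmean(sub, axis=0)
            assert np.nanmax(np.abs(col_means)) < 1e-10


class TestRegionalMeanAndTrend:
    def _cube_from(self, values_2d, years=(1991, 1993)):
        records = make_records(
            [(y, m, 2.5, -12.5, 1.0) for y in range(years[0], years[1] + 1) for m in range(1, 13)]
        )
        cube = aggregate_effort(records, cell_deg=5, period=years)
        cube.values[:] = np.nan
        cube.values[:, : values_2d.shape[0], : values_2d.shape[1]] = values_2d
        return cube

    def test_uniform_field_mean(self):
        cube = self._cube_from(np.full((2, 2), 0.3))
        series = regional_mean_series(cube)
        assert np.allclose(series.to_numpy(), 0.3)

    def test_two_cell_mean(self):
        cube = self._cube_from(np.array([[0.2, 0.6]]))
        assert regional_mean_series(cube).iloc[0] == pytest.approx(0.4)

    def test_matches_brute_force_in_box_mean(self, default_bundle):
        cube = default_bundle["ssta_cube"]
        box = RegionBox(lat_min=-10, lat_max=10, lon_min=-20, lon_max=0)
        series = regional_mean_series(cube, box)
        t = 17
        vals = [
            cube.values[t, i, j]
            for i, la in enumerate(cube.lats)
            for j, lo in enumerate(cube.lons)
            if box.contains(la, lo)
        ]
        assert series.iloc[t] == pytest.approx(np.mean(vals), rel=1e-12)

    def test_exact_line_recovered(self):
        idx = quarter_range(1991, 2000)
        t = idx.asi8.astype(float)
        fit = linear_trend(pd.Series(2.0 * t + 1.0, index=idx))
        assert fit.slope == pytest.approx(2.0)
        assert fit.total_change == pytest.approx(2.0 * (t[-1] - t[0]))
        assert fit.p_value < 1e-10

    def test_constant_series_has_zero_slope(self):
        idx = quarter_range(1991, 1995)
        fit = linear_trend(pd.Series(3.3, index=idx))
        assert fit.slope == 0.0 and fit.total_change == 0.0

    def test_too_few_points_raises(self):
        idx = quarter_range(1991, 1991)[:2]
        with pytest.raises(InsufficientDataError):
            linear_trend(pd.Series([1.0, 2.0], index=idx))

    def test_noisy_slope_recovered_within_two_se(self):
        rng = np.random.default_rng(5)
        idx = quarter_range(1856, 2017)
        t = idx.asi8.astype(float)
        y = 0.005 * t + rng.normal(0, 0.3, len(t))
        fit = linear_trend(pd.Series(y, index=idx))
        assert abs(fit.slope - 0.005) < 2 * fit.stderr


class TestFadCatchProportion:
    def test_simple_ratio(self):
        records = make_records([(1991, 1, 0.5, 0.5, 1.0, 30.0, 70.0)])
        assert fad_catch_proportion(records).iloc[0] == pytest.approx(30.0)

    def test_all_fad_is_100(self):
        records = make_records([(1991, 1, 0.5, 0.5, 1.0, 50.0, 0.0)])
        assert fad_catch_proportion(records).iloc[0] == pytest.approx(100.0)

    def test_zero_catch_quarter_is_missing(self):
        records = make_records([(1991, 1, 0.5, 0.5, 1.0, 0.0, 0.0)])
        assert np.isnan(fad_catch_proportion(records).iloc[0])

    def test_matches_brute_force_per_quarter(self):
        rng = np.random.default_rng(3)
        records = random_records(rng, 150)
        prop = fad_catch_proportion(records)
        q = pd.PeriodIndex.from_fields(
            year=records["year"], quarter=(records["month"] + 2) // 3, freq="Q"
        )
        for period in prop.index:
            sub = records[q == period]
            expect = 100.0 * sub["catch_fad_t"].sum() / (
                sub["catch_fad_t"].sum() + sub["catch_free_t"].sum()
            )
            assert prop[period] == pytest.approx(expect, rel=1e-12)
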