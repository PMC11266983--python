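"""Occurrence parsing/filtering and weather-cube I/O."""

from datetime import date, time

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from phenoniche.data_io import (
    FilterConfig,
    Grid,
    OccurrenceRecord,
    WeatherCube,
    aggregate_subdaily,
    ConfigurationError,
    filter_occurrences,
    meters_to_degrees,
    read_occurrences,
    read_weather_cube,
    resample_cube,
)


def _write_csv(tmp_path, rows, header="gbifID,decimalLatitude,decimalLongitude,eventDate"):
    p = tmp_path / "occ.csv"
    p.write_text("\n".join([header] + rows) + "\n")
    return p


class TestReadOccurrences:
    def test_identity_parse(self, tmp_path):
        p = _write_csv(tmp_path, ["r1,45.2,7.6,2021-07-03"])
        recs, rej = read_occurrences(p)
        assert not rej
        (r,) = recs
        assert (r.lat, r.lon, r.event_date) == (45.2, 7.6, date(2021, 7, 3))

    def test_incomplete_date_rejected_not_crashed(self, tmp_path):
        p = _write_csv(tmp_path, ["r1,45.2,7.6,2021-07", "r2,45.2,7.6,2021-07-03"])
        recs, rej = read_occurrences(p)
        assert len(recs) == 1
        assert rej == [("r1", "incomplete date")]

    def test_empty_file_with_header(self, tmp_path):
        recs, rej = read_occurrences(_write_csv(tmp_path, []))
        assert recs == [] and rej == []

    def test_missing_mandatory_column(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("gbifID,decimalLatitude,eventDate\nr1,45.2,2021-07-03\n")
        with pytest.raises(ConfigurationError, match="decimalLongitude"):
            read_occurrences(p)

    def test_time_parsed_from_iso_datetime(self, tmp_path):
        p = _write_csv(tmp_path, ["r1,45.2,7.6,2021-06-01T00:00:00"])
        recs, _ = read_occurrences(p)
        assert recs[0].event_time == time(0, 0, 0)

    def test_uncertainty_meters_converted_at_latitude(self, tmp_path):
        header = "gbifID,decimalLatitude,decimalLongitude,eventDate,coordinateUncertaintyInMeters"
        p = _write_csv(tmp_path, ["r1,60.0,7.6,2021-07-03,5000"], header)
        recs, _ = read_occurrences(p)
        assert recs[0].coord_uncertainty_deg == pytest.approx(
            meters_to_degrees(5000, 60.0)
        )
        # at 60N a metre spans more longitude than latitude
        assert meters_to_degrees(5000, 60.0) > 5000 / 111_320


def _rec(**kw):
    base = dict(
        record_id="x", taxon="t", lat=45.0, lon=7.0, event_date=date(2018, 6, 15),
    )
    base.update(kw)
    return OccurrenceRecord(**base)


class TestFilterOccurrences:
    CFG = FilterConfig()

    @pytest.mark.parametrize(
        "rec,reason",
        [
            (_rec(event_date=date(2018, 6, 1), event_time=time(0, 0, 0)),
             "midnight first of month"),
            (_rec(coord_uncertainty_deg=0.25), "uncertainty too coarse"),
            (_rec(event_date=date(2014, 6, 15)), "year out of range"),
            (_rec(has_photo=False), "no photographic evidence"),
            (_rec(evidence_ok=False), "evidence check failed"),
        ],
    )
    def test_rejection_reasons(self, rec, reason):
        kept, rej = filter_occurrences([rec], self.CFG)
        assert kept == [] and rej == [("x", reason)]

    @pytest.mark.parametrize(
        "rec",
        [
            _rec(event_date=date(2018, 6, 1), event_time=time(14, 22, 10)),
            _rec(coord_uncertainty_deg=0.05),
            _rec(coord_uncertainty_deg=None),  # missing uncertainty kept by default
        ],
    )
    def test_kept(self, rec):
        kept, rej = filter_occurrences([rec], self.CFG)
        assert kept == [rec] and rej == []

    def test_first_failing_rule_wins(self):
        rec = _rec(event_date=date(2014, 6, 1), event_time=time(0, 0),
                   coord_uncertainty_deg=0.5)
        _, rej = filter_occurrences([rec], self.CFG)
        assert rej == [("x", "year out of range")]

    def test_partition_and_idempotence(self):
        records = [
            _rec(record_id=str(i), coord_uncertainty_deg=u,
                 event_date=date(2013 + i % 10, 6, 15))
            for i, u in enumerate([0.01, 0.5, None] * 10)
        ]
        kept, rej = filter_occurrences(records, self.CFG)
        assert len(kept) + len(rej) == len(records)
        kept2, rej2 = filter_occurrences(kept, self.CFG)
        assert kept2 == kept and rej2 == []


class TestWeatherCube:
    def test_grid_cell_assignment_half_open(self):
        g = Grid(40.0, 0.0, 0.25, 4, 4)
        r, c = g.cell_of([40.0, 40.249999, 40.25], [0.0, 0.0, 0.0])
        assert list(r) == [0, 0, 1]

    def test_non_contiguous_dates_rejected(self):
        g = Grid(40.0, 0.0, 0.5, 2, 2)
        dates = pd.DatetimeIndex(["2020-01-01", "2020-01-02", "2020-01-04"])
        with pytest.raises(ValueError, match="contiguous"):
            WeatherCube.from_arrays(g, dates, {"tmean": np.zeros((3, 2, 2))})

    def test_netcdf_roundtrip_bit_exact(self, flat_cube, tmp_path):
        p = tmp_path / "cube.nc"
        flat_cube.to_netcdf(p)
        back = WeatherCube.from_netcdf(p)
        for v in flat_cube.variables:
            np.testing.assert_array_equal(flat_cube.values(v), back.values(v))
        assert back.grid == flat_cube.grid

    def test_read_weather_cube_mismatched_grids(self, tmp_path):
        g1, g2 = Grid(40, 0, 0.5, 2, 2), Grid(40, 0, 0.25, 2, 2)
        d = pd.date_range("2020-01-01", periods=3)
        WeatherCube.from_arrays(g1, d, {"tmean": np.zeros((3, 2, 2))}).to_netcdf(
            tmp_path / "a.nc"
        )
        WeatherCube.from_arrays(g2, d, {"precip": np.zeros((3, 2, 2))}).to_netcdf(
            tmp_path / "b.nc"
        )
        with pytest.raises(ConfigurationError, match="0.25"):
            read_weather_cube([tmp_path / "a.nc", tmp_path / "b.nc"])

    def test_read_weather_cube_span_mismatch(self, tmp_path):
        g = Grid(40, 0, 0.5, 2, 2)
        WeatherCube.from_arrays(
            g, pd.date_range("2020-01-01", periods=3), {"tmean": np.zeros((3, 2, 2))}
        ).to_netcdf(tmp_path / "a.nc")
        WeatherCube.from_arrays(
            g, pd.date_range("2020-01-01", periods=4), {"precip": np.zeros((4, 2, 2))}
        ).to_netcdf(tmp_path / "b.nc")
        with pytest.raises(ConfigurationError, match="span"):
            read_weather_cube([tmp_path / "a.nc", tmp_path / "b.nc"])

    def test_read_weather_cube_merges_chunks(self, tmp_path):
        g = Grid(40, 0, 0.5, 2, 2)
        a = WeatherCube.from_arrays(
            g, pd.date_range("2020-01-01", periods=3),
            {"tmean": np.arange(12).reshape(3, 2, 2).astype(float)},
        )
        b = WeatherCube.from_arrays(
            g, pd.date_range("2020-01-04", periods=2),
            {"tmean": np.ones((2, 2, 2))},
        )
        a.to_netcdf(tmp_path / "a.nc")
        b.to_netcdf(tmp_path / "b.nc")
        cube = read_weather_cube([tmp_path / "b.nc", tmp_path / "a.nc"])
        assert len(cube.dates) == 5


class TestAggregateSubdaily:
    def _slices(self, values_by_var, n_days=2, per_day=24):
        times = pd.date_range("2021-03-01", periods=n_days * per_day, freq="h")
        data = {
            v: (("time", "lat", "lon"), a) for v, a in values_by_var.items()
        }
        return xr.Dataset(data, coords={"time": times, "lat": [40.25], "lon": [0.25]})

    def test_constant_temperature(self):
        shape = (48, 1, 1)
        ds = self._slices(
            {"tmean": np.full(shape, 10.0), "tmin": np.full(shape, 10.0),
             "tmax": np.full(shape, 10.0)}
        )
        cube = aggregate_subdaily(ds)
        for v in ("tmean", "tmin", "tmax"):
            np.testing.assert_allclose(cube.values(v), 10.0)

    def test_precip_sums(self):
        a = np.zeros((48, 1, 1))
        a[[0, 6, 12, 18], 0, 0] = [1, 0, 2, 0]
        cube = aggregate_subdaily(self._slices({"precip": a}))
        assert cube.values("precip")[0, 0, 0] == pytest.approx(3.0)
        assert cube.values("precip")[1, 0, 0] == pytest.approx(0.0)

    def test_matches_bruteforce_on_crafted_day(self):
        rng = np.random.default_rng(5)
        vals = {v: rng.normal(size=(24, 1, 1)) for v in
                ("tmin", "tmean", "tmax", "precip", "snow", "wind")}
        cube = aggregate_subdaily(self._slices(vals, n_days=1))
        day = {v: a[:, 0, 0] for v, a in vals.items()}
        assert cube.values("tmin")[0, 0, 0] == pytest.approx(day["tmin"].min())
        assert cube.values("tmax")[0, 0, 0] == pytest.approx(day["tmax"].max())
        assert cube.values("tmean")[0, 0, 0] == pytest.approx(day["tmean"].mean())
        assert cube.values("precip")[0, 0, 0] == pytest.approx(day["precip"].sum())
        assert cube.values("wind")[0, 0, 0] == pytest.approx(day["wind"].mean())

    def test_missing_run_errors_with_day(self):
        times = pd.date_range("2021-03-01", periods=40, freq="h")  # second day short
        ds = xr.Dataset(
            {"tmean": (("time", "lat", "lon"), np.zeros((40, 1, 1)))},
            coords={"time": times, "lat": [40.25], "lon": [0.25]},
        )
        with pytest.raises(ValueError, match="2021-03-02"):
            aggregate_subdaily(ds)


class TestResampleCube:
    def _cube(self, tmean, precip=None, cell=0.125):
        T, R, C = tmean.shape
        g = Grid(40.0, 0.0, cell, R, C)
        arrays = {"tmean": tmean}
        if precip is not None:
            arrays["precip"] = precip
        return WeatherCube.from_arrays(g, pd.date_range("2020-01-01", periods=T), arrays)

    def test_block_mean_and_precip_sum(self):
        tmean = np.array([[[1.0, 2.0], [3.0, 4.0]]])
        precip = np.ones((1, 2, 2))
        out = resample_cube(self._cube(tmean, precip), 0.25)
        assert out.values("tmean")[0, 0, 0] == pytest.approx(2.5)
        assert out.values("precip")[0, 0, 0] == pytest.approx(4.0)

    def test_constant_cube_stays_constant_both_ways(self):
        tmean = np.full((2, 4, 4), 7.0)
        up = resample_cube(self._cube(tmean), 0.25)
        down = resample_cube(self._cube(tmean), 0.0625)
        np.testing.assert_allclose(up.values("tmean"), 7.0)
        np.testing.assert_allclose(down.values("tmean"), 7.0)
        assert down.grid.n_rows == 8

    def test_bad_targets(self):
        cube = self._cube(np.zeros((1, 2, 2)))
        with pytest.raises(ValueError):
            resample_cube(cube, -0.1)
        with pytest.raises(ValueError, match="integer multiple"):
            resample_cube(cube, 0.3)
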