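"""Reading, validation and quality filtering of occurrence tables and daily weather cubes.

Occurrence tables are Darwin-Core-flavoured CSV (``decimalLatitude``,
``decimalLongitude``, ``eventDate`` ...).  Weather is handled as a
:class:`WeatherCube`: a contiguous daily stack of up to six gridded variables
(``tmin``, ``tmean``, ``tmax`` in degC, ``precip`` in mm/day, ``snow`` in cm,
``wind`` in m/s) on a regular WGS84 lat/lon grid, stored as an
:class:`xarray.Dataset` and serialised as NetCDF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date as Date
from datetime import time as Time
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr

#: canonical variable order of a weather cube
VARIABLES = ("tmin", "tmean", "tmax", "precip", "snow", "wind")

#: how sub-daily slices collapse to a daily value, per variable
SUBDAILY_AGG = {
    "tmin": "min",
    "tmax": "max",
    "tmean": "mean",
    "wind": "mean",
    "snow": "mean",
    "precip": "sum",
}

#: spatial aggregation used when coarsening a grid (mean, except precip: sum)
SPATIAL_AGG = {v: ("sum" if v == "precip" else "mean") for v in VARIABLES}

#: default Darwin-Core-like column mapping for occurrence CSVs
DEFAULT_COLUMN_MAP = {
    "record_id": "gbifID",
    "taxon": "species",
    "lat": "decimalLatitude",
    "lon": "decimalLongitude",
    "event_date": "eventDate",
    "event_time": "eventTime",
    "coord_uncertainty_m": "coordinateUncertaintyInMeters",
    "has_photo": "hasPhoto",
    "evidence_ok": "evidenceOk",
    "source": "institutionCode",
}

#: column names used by this package's own CSV output (records_to_frame)
NATIVE_COLUMN_MAP = {
    "record_id": "record_id",
    "taxon": "taxon",
    "lat": "lat",
    "lon": "lon",
    "event_date": "event_date",
    "event_time": "event_time",
    "coord_uncertainty_deg": "coord_uncertainty_deg",
    "has_photo": "has_photo",
    "evidence_ok": "evidence_ok",
    "source": "source",
}

_METERS_PER_DEGREE_LAT = 111_320.0


class ConfigurationError(ValueError):
    """A required column, variable or file is missing or inconsistent."""


@dataclass(frozen=True)
class Grid:
    """Regular WGS84 lat/lon grid; ``lat0``/``lon0`` are the lower-left *edges*.

    Cells are half-open: a point belongs to cell ``(r, c)`` iff
    ``lat0 + r*cell <= lat < lat0 + (r+1)*cell`` (same for longitude).
    """

    lat0: float
    lon0: float
    cell: float
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.cell <= 0:
            raise ValueError(f"cell size must be positive, got {self.cell}")

    @property
    def lat_centers(self) -> np.ndarray:
        return self.lat0 + (np.arange(self.n_rows) + 0.5) * self.cell

    @property
    def lon_centers(self) -> np.ndarray:
        return self.lon0 + (np.arange(self.n_cols) + 0.5) * self.cell

    def cell_of(self, lat, lon):
        """Vectorised point->cell lookup; returns integer (row, col) arrays."""
        row = np.floor((np.asarray(lat, float) - self.lat0) / self.cell).astype(int)
        col = np.floor((np.asarray(lon, float) - self.lon0) / self.cell).astype(int)
        return row, col

    def contains(self, row, col):
        row = np.asarray(row)
        col = np.asarray(col)
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)


@dataclass
class OccurrenceRecord:
    """One time-stamped, georeferenced observation with quality flags."""

    record_id: str
    taxon: str
    lat: float
    lon: float
    event_date: Date
    event_time: Time | None = None
    coord_uncertainty_deg: float | None = None
    has_photo: bool = True
    evidence_ok: bool = True
    source: str = ""

    def __post_init__(self) -> None:
        if not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"latitude {self.lat} out of [-90, 90]")
        if not (-180.0 <= self.lon <= 180.0):
            raise ValueError(f"longitude {self.lon} out of [-180, 180]")
        if self.coord_uncertainty_deg is not None and self.coord_uncertainty_deg < 0:
            raise ValueError("coordinate uncertainty must be nonnegative")


@dataclass(frozen=True)
class FilterConfig:
    """Quality-filter rules applied to occurrence records, in fixed order.

    Records are rejected by the first failing rule among: incomplete date
    (parse time), year range, midnight-on-the-first-of-month, coordinate
    bounds, coordinate uncertainty, photo flag, evidence flag.
    """

    year_range: tuple[int, int] = (2015, 2021)
    max_uncertainty_deg: float = 0.1
    drop_first_of_month_midnight: bool = True
    require_photo: bool = True
    require_evidence: bool = True
    #: GBIF commonly omits the uncertainty field; by default such records pass
    keep_missing_uncertainty: bool = True

    def __post_init__(self) -> None:
        if self.year_range[0] > self.year_range[1]:
            raise ValueError("year_range must satisfy first <= last")
        if self.max_uncertainty_deg <= 0:
            raise ValueError("max_uncertainty_deg must be positive")


def meters_to_degrees(meters: float, lat: float) -> float:
    """Conservative metre->degree conversion at a given latitude.

    Returns the larger of the latitudinal and longitudinal angular spans, so a
    record is only kept when it is precise along *both* axes.
    """
    d_lat = meters / _METERS_PER_DEGREE_LAT
    cos_lat = math.cos(math.radians(lat))
    if cos_lat <= 1e-6:
        return d_lat
    return max(d_lat, meters / (_METERS_PER_DEGREE_LAT * cos_lat))


def _parse_event_date(raw) -> tuple[Date | None, Time | None, str | None]:
    """Parse an ISO-8601 eventDate; a missing day/month is a rejection."""
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None, None, "incomplete date"
    text = str(raw).strip()
    if not text:
        return None, None, "incomplete date"
    date_part, _, time_part = text.partition("T")
    pieces = date_part.split("-")
    if len(pieces) != 3 or not all(p.isdigit() for p in pieces):
        return None, None, "incomplete date"
    try:
        d = Date(int(pieces[0]), int(pieces[1]), int(pieces[2]))
    except ValueError:
        return None, None, "invalid date"
    t = None
    if time_part:
        try:
            t = Time.fromisoformat(time_part.rstrip("Z").split("+")[0])
        except ValueError:
            t = None
    return d, t, None


def read_occurrences(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> tuple[list[OccurrenceRecord], list[tuple[str, str]]]:
    """Read an occurrence CSV into records plus a per-row rejection log.

    ``column_map`` maps internal field names (keys of
    :data:`DEFAULT_COLUMN_MAP`) to CSV column names.  Rows with unparsable
    dates or coordinates become rejection entries, never exceptions.  The
    uncertainty column may be metres (``coord_uncertainty_m``, converted at
    the record's latitude) or degrees (``coord_uncertainty_deg``).
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, dtype=str)
    for key in ("lat", "lon", "event_date"):
        if cmap[key] not in df.columns:
            raise ConfigurationError(
                f"mandatory column {cmap[key]!r} (for {key}) missing from {path}"
            )

    records: list[OccurrenceRecord] = []
    rejections: list[tuple[str, str]] = []
    id_col = cmap["record_id"] if cmap["record_id"] in df.columns else None
    for i, row in df.iterrows():
        rid = str(row[id_col]) if id_col else f"row{i}"
        d, t, err = _parse_event_date(row[cmap["event_date"]])
        if err:
            rejections.append((rid, err))
            continue
        tcol = cmap.get("event_time")
        if tcol and tcol in df.columns and pd.notna(row[tcol]) and str(row[tcol]).strip():
            try:
                t = Time.fromisoformat(str(row[tcol]).strip())
            except ValueError:
                pass
        try:
            lat = float(row[cmap["lat"]])
            lon = float(row[cmap["lon"]])
        except (TypeError, ValueError):
            rejections.append((rid, "unparsable coordinates"))
            continue
        if not (-90 <= lat <= 90 and -180 <= lon <= 180):
            rejections.append((rid, "coordinates out of bounds"))
            continue
        unc = None
        if cmap.get("coord_uncertainty_deg") and cmap["coord_uncertainty_deg"] in df.columns:
            v = row[cmap["coord_uncertainty_deg"]]
            unc = float(v) if pd.notna(v) and str(v).strip() else None
        elif cmap["coord_uncertainty_m"] in df.columns:
            v = row[cmap["coord_uncertainty_m"]]
            if pd.notna(v) and str(v).strip():
                unc = meters_to_degrees(float(v), lat)

        def _flag(key: str, default: bool) -> bool:
            col = cmap.get(key)
            if col and col in df.columns and pd.notna(row[col]):
                return str(row[col]).strip().lower() in ("1", "true", "t", "yes", "y")
            return default

        records.append(
            OccurrenceRecord(
                record_id=rid,
                taxon=str(row[cmap["taxon"]]) if cmap["taxon"] in df.columns else "",
                lat=lat,
                lon=lon,
                event_date=d,
                event_time=t,
                coord_uncertainty_deg=unc,
                has_photo=_flag("has_photo", True),
                evidence_ok=_flag("evidence_ok", True),
                source=str(row[cmap["source"]]) if cmap["source"] in df.columns else "",
            )
        )
    return records, rejections


def _first_failing_rule(rec: OccurrenceRecord, cfg: FilterConfig) -> str | None:
    if rec.event_date is None:
        return "incomplete date"
    y0, y1 = cfg.year_range
    if not (y0 <= rec.event_date.year <= y1):
        return "year out of range"
    if (
        cfg.drop_first_of_month_midnight
        and rec.event_date.day == 1
        and rec.event_time is not None
        and rec.event_time == Time(0, 0, 0)
    ):
        return "midnight first of month"
    if not (-90 <= rec.lat <= 90 and -180 <= rec.lon <= 180):
        return "coordinates out of bounds"
    if rec.coord_uncertainty_deg is None:
        if not cfg.keep_missing_uncertainty:
            return "missing coordinate uncertainty"
    elif rec.coord_uncertainty_deg >= cfg.max_uncertainty_deg:
        return "uncertainty too coarse"
    if cfg.require_photo and not rec.has_photo:
        return "no photographic evidence"
    if cfg.require_evidence and not rec.evidence_ok:
        return "evidence check failed"
    return None


def filter_occurrences(
    records: Sequence[OccurrenceRecord], cfg: FilterConfig
) -> tuple[list[OccurrenceRecord], list[tuple[str, str]]]:
    """Apply quality rules; each rejected record carries its first failing rule."""
    kept: list[OccurrenceRecord] = []
    rejected: list[tuple[str, str]] = []
    for rec in records:
        reason = _first_failing_rule(rec, cfg)
        if reason is None:
            kept.append(rec)
        else:
            rejected.append((rec.record_id, reason))
    return kept, rejected


@dataclass
class WeatherCube:
    """Daily multi-variable raster time series on a regular lat/lon grid."""

    data: xr.Dataset  # dims (time, lat, lon); coords are cell centres
    grid: Grid

    def __post_init__(self) -> None:
        dates = self.dates
        if len(dates) > 1:
            deltas = np.diff(dates.values).astype("timedelta64[D]").astype(int)
            if not np.all(deltas == 1):
                gaps = dates[:-1][deltas != 1]
                raise ValueError(f"cube dates not contiguous daily after {list(gaps)}")

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(v for v in VARIABLES if v in self.data.data_vars)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.data.time.values).normalize()

    def values(self, var: str) -> np.ndarray:
        """(time, row, col) array for one variable."""
        return self.data[var].values

    def date_index(self, dates) -> np.ndarray:
        """Positions of calendar dates along the time axis (-1 if absent)."""
        idx = self.dates
        target = pd.DatetimeIndex(pd.to_datetime(np.atleast_1d(np.asarray(dates, dtype=object)))).normalize()
        return idx.get_indexer(target)

    @classmethod
    def from_arrays(
        cls, grid: Grid, dates: pd.DatetimeIndex, arrays: Mapping[str, np.ndarray]
    ) -> "WeatherCube":
        unknown = set(arrays) - set(VARIABLES)
        if unknown:
            raise ConfigurationError(f"unknown weather variables: {sorted(unknown)}")
        ds = xr.Dataset(
            {v: (("time", "lat", "lon"), np.asarray(a, float)) for v, a in arrays.items()},
            coords={
                "time": pd.DatetimeIndex(dates),
                "lat": grid.lat_centers,
                "lon": grid.lon_centers,
            },
        )
        return cls(ds, grid)

    def to_netcdf(self, path: str | Path) -> None:
        ds = self.data.copy()
        ds.attrs.update(
            lat0=self.grid.lat0, lon0=self.grid.lon0, cell=self.grid.cell
        )
        ds.to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path: str | Path) -> "WeatherCube":
        ds = xr.open_dataset(path, engine="scipy").load()
        return cls(ds, _grid_from_dataset(ds))


def _grid_from_dataset(ds: xr.Dataset) -> Grid:
    lat = np.asarray(ds.lat.values, float)
    lon = np.asarray(ds.lon.values, float)
    if "cell" in ds.attrs:
        cell = float(ds.attrs["cell"])
        lat0 = float(ds.attrs.get("lat0", lat[0] - cell / 2))
        lon0 = float(ds.attrs.get("lon0", lon[0] - cell / 2))
    else:
        if len(lat) > 1:
            cell = float(lat[1] - lat[0])
        elif len(lon) > 1:
            cell = float(lon[1] - lon[0])
        else:
            cell = 0.5  # single-cell dataset without metadata: nominal size
        lat0 = float(lat[0]) - cell / 2
        lon0 = float(lon[0]) - cell / 2
    return Grid(lat0, lon0, cell, len(lat), len(lon))


def read_weather_cube(
    paths: Sequence[str | Path], var_names: Mapping[str, str] | None = None
) -> WeatherCube:
    """Read and merge NetCDF weather files into one contiguous daily cube.

    Each file holds one or more variables over any sub-span of dates;
    ``var_names`` maps file variable names to canonical names.  Mismatched
    grids, date gaps, or variables with differing spans are errors.
    """
    rename = dict(var_names or {})
    per_var: dict[str, list[xr.DataArray]] = {}
    ref_grid: Grid | None = None
    for p in paths:
        ds = xr.open_dataset(p, engine="scipy").load()
        ds = ds.rename({k: v for k, v in rename.items() if k in ds.data_vars})
        g = _grid_from_dataset(ds)
        if ref_grid is None:
            ref_grid = g
        elif not (
            math.isclose(g.cell, ref_grid.cell)
            and math.isclose(g.lat0, ref_grid.lat0)
            and math.isclose(g.lon0, ref_grid.lon0)
            and (g.n_rows, g.n_cols) == (ref_grid.n_rows, ref_grid.n_cols)
        ):
            raise ConfigurationError(
                f"grid of {p} (cell {g.cell}) differs from reference (cell {ref_grid.cell})"
            )
        for v in ds.data_vars:
            if v not in VARIABLES:
                raise ConfigurationError(f"unrecognised variable {v!r} in {p}")
            per_var.setdefault(v, []).append(ds[v])
    if not per_var:
        raise ConfigurationError("no weather variables found in inputs")
    assert ref_grid is not None

    merged: dict[str, xr.DataArray] = {}
    spans = {}
    for v, chunks in per_var.items():
        da = xr.concat(sorted(chunks, key=lambda c: c.time.values[0]), dim="time")
        dates = pd.DatetimeIndex(da.time.values).normalize()
        full = pd.date_range(dates[0], dates[-1], freq="D")
        missing = full.difference(dates)
        if len(missing):
            raise ConfigurationError(
                f"variable {v!r}: missing dates {[str(d.date()) for d in missing[:5]]}"
            )
        merged[v] = da
        spans[v] = (dates[0], dates[-1])
    if len(set(spans.values())) > 1:
        raise ConfigurationError(f"variables cover different date spans: {spans}")
    return WeatherCube(xr.Dataset(merged), ref_grid)


def aggregate_subdaily(
    slices: xr.Dataset, runs_per_day: int = 4, slices_per_run: int = 6
) -> WeatherCube:
    """Collapse forecast-style sub-daily fields to a daily cube.

    Every calendar day must be covered by ``runs_per_day * slices_per_run``
    time stamps (four model runs, first six hours of each).  Temperatures,
    wind and snow average over the day (with min/max for tmin/tmax); total
    precipitation sums.
    """
    expected = runs_per_day * slices_per_run
    times = pd.DatetimeIndex(slices.time.values)
    days = times.normalize()
    counts = pd.Series(1, index=days).groupby(level=0).sum()
    bad = counts[counts != expected]
    if len(bad):
        raise ValueError(
            f"days with missing forecast runs (expected {expected} slices): "
            f"{[str(d.date()) for d in bad.index[:5]]}"
        )
    grid = _grid_from_dataset(slices)
    day_key = xr.DataArray(days.values, coords={"time": slices.time}, name="day")
    out = {}
    for v in slices.data_vars:
        if v not in VARIABLES:
            raise ConfigurationError(f"unrecognised variable {v!r}")
        grouped = slices[v].groupby(day_key)
        agg = SUBDAILY_AGG[v]
        da = getattr(grouped, agg)()
        out[v] = da.rename({"day": "time"})
    return WeatherCube(xr.Dataset(out), grid)


def resample_cube(cube: WeatherCube, target_cell: float) -> WeatherCube:
    """Resample to a new cell size: block aggregation up, nearest-cell down.

    Coarsening requires the target to be an integer multiple of the source
    cell (mean per block; precipitation sums); refining requires an integer
    divisor (each source cell is replicated).
    """
    if target_cell <= 0:
        raise ValueError("target_cell must be positive")
    src = cube.grid.cell
    if math.isclose(target_cell, src):
        return cube
    out = {}
    if target_cell > src:
        k = target_cell / src
        if not math.isclose(k, round(k)):
            raise ValueError(
                f"target cell {target_cell} is not an integer multiple of {src}"
            )
        k = int(round(k))
        nr, nc = cube.grid.n_rows // k, cube.grid.n_cols // k
        if nr == 0 or nc == 0:
            raise ValueError("grid smaller than one target cell")
        for v in cube.variables:
            a = cube.values(v)[:, : nr * k, : nc * k]
            blocks = a.reshape(a.shape[0], nr, k, nc, k)
            if SPATIAL_AGG[v] == "sum":
                out[v] = blocks.sum(axis=(2, 4))
            else:
                out[v] = blocks.mean(axis=(2, 4))
        grid = Grid(cube.grid.lat0, cube.grid.lon0, target_cell, nr, nc)
    else:
        k = src / target_cell
        if not math.isclose(k, round(k)):
            raise ValueError(f"source cell {src} is not an integer multiple of {target_cell}")
        k = int(round(k))
        grid = Grid(
            cube.grid.lat0, cube.grid.lon0, target_cell,
            cube.grid.n_rows * k, cube.grid.n_cols * k,
        )
        for v in cube.variables:
            out[v] = np.repeat(np.repeat(cube.values(v), k, axis=1), k, axis=2)
    return WeatherCube.from_arrays(grid, cube.dates, out)


def records_to_frame(records: Iterable[OccurrenceRecord]) -> pd.DataFrame:
    rows = [
        {
            "record_id": r.record_id,
            "taxon": r.taxon,
            "lat": r.lat,
            "lon": r.lon,
            "event_date": r.event_date.isoformat(),
            "event_time": r.event_time.isoformat() if r.event_time else "",
            "coord_uncertainty_deg": r.coord_uncertainty_deg,
            "has_photo": r.has_photo,
            "evidence_ok": r.evidence_ok,
            "source": r.source,
        }
        for r in records
    ]
    return pd.DataFrame(rows)
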