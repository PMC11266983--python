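"""Daily gridded prediction maps, suitability masking, bilinear downsampling.

A day map scores every unmasked grid cell as if a record existed at the cell
centre on that date, using the same trailing-window features the models were
trained on.  Masked (unsuitable / out-of-range) cells carry NaN, never 0.
Bilinear downsampling to a finer cell size is a visualisation aid only;
analyses stay at the working resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as Date
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import xarray as xr

from .data_io import Grid, WeatherCube
from .features import FeatureConfig, _WindowStats
from .models import EnsembleModel, predict_scores


@dataclass
class PredictionMap:
    """One day's niche-membership probabilities on the weather grid."""

    date: Date
    grid: Grid
    values: np.ndarray  # (n_rows, n_cols), in [0,1] or NaN under mask
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("prediction values must lie in [0, 1]")

    def to_dataarray(self) -> xr.DataArray:
        return xr.DataArray(
            self.values,
            dims=("lat", "lon"),
            coords={"lat": self.grid.lat_centers, "lon": self.grid.lon_centers},
            name="probability",
            attrs={"date": self.date.isoformat(), **{
                k: str(v) for k, v in self.provenance.items()
            }},
        )


def _cell_features(
    cube: WeatherCube,
    cfg: FeatureConfig,
    t_idx: np.ndarray,
    rows: np.ndarray,
    cols: np.ndarray,
    stats: _WindowStats | None = None,
) -> pd.DataFrame:
    """Feature rows for (time, cell) pairs, as if records sat at cell centres."""
    max_w = max(cfg.windows)
    if np.any(t_idx - max_w + 1 < 0):
        raise ValueError(
            f"insufficient lookback: need {max_w} days of weather before the "
            "earliest requested date"
        )
    stats = stats or _WindowStats(cube, cfg.variables)
    from .features import WINDOW_AGG

    data = {}
    for v in cfg.variables:
        for w in cfg.windows:
            data[f"{v}_{WINDOW_AGG[v]}_{w}d"] = stats.aggregate(v, w, t_idx, rows, cols)
    if cfg.include_coords:
        data["lat"] = cube.grid.lat_centers[rows]
        data["lon"] = cube.grid.lon_centers[cols]
    return pd.DataFrame(data, columns=cfg.feature_names)


def predict_day_map(
    model: EnsembleModel,
    cube: WeatherCube,
    date: Date,
    cfg: FeatureConfig,
    mask: np.ndarray,
) -> PredictionMap:
    """Score every unmasked cell for one date (mask True = suitable)."""
    mask = np.asarray(mask, bool)
    if mask.shape != (cube.grid.n_rows, cube.grid.n_cols):
        raise ValueError("mask shape does not match the cube grid")
    values = np.full(mask.shape, np.nan)
    rr, cc = np.nonzero(mask)
    if len(rr):
        t = cube.date_index([date])
        if t[0] < 0:
            raise ValueError(f"date {date} not covered by the weather cube")
        t_idx = np.full(len(rr), t[0])
        X = _cell_features(cube, cfg, t_idx, rr, cc)
        values[rr, cc] = predict_scores(model, X)
    return PredictionMap(
        date=date,
        grid=cube.grid,
        values=values,
        provenance={"model_hash": model.train_meta.get("config_hash", "")},
    )


def predict_period_means(
    model: EnsembleModel,
    cube: WeatherCube,
    mask: np.ndarray,
    first: Date,
    last: Date,
    cfg: FeatureConfig,
) -> dict[Date, float]:
    """Daily mean predicted probability over the unmasked cells, batched."""
    mask = np.asarray(mask, bool)
    rr, cc = np.nonzero(mask)
    if len(rr) == 0:
        raise ValueError("mask selects no cells")
    dates = pd.date_range(first, last, freq="D")
    t_idx = cube.date_index(dates)
    if np.any(t_idx < 0):
        raise ValueError("period not fully covered by the weather cube")
    n_c = len(rr)
    t = np.repeat(t_idx, n_c)
    r = np.tile(rr, len(dates))
    c = np.tile(cc, len(dates))
    stats = _WindowStats(cube, cfg.variables)
    X = _cell_features(cube, cfg, t, r, c, stats=stats)
    scores = predict_scores(model, X).reshape(len(dates), n_c)
    daily = scores.mean(axis=1)
    return {d.date(): float(v) for d, v in zip(dates, daily)}


def downsample_bilinear(pmap: PredictionMap, target_cell: float = 0.02) -> PredictionMap:
    """Bilinear interpolation onto a finer grid, for visualisation.

    Nodes are source cell centres; beyond the outermost centres values extend
    by nearest-node padding.  An output cell is missing iff any node with
    nonzero interpolation weight is missing.  Values are clipped to [0, 1].
    """
    src = pmap.grid
    if target_cell >= src.cell:
        raise ValueError(
            f"target cell {target_cell} must be finer than source {src.cell}"
        )
    n_rows = int(round(src.n_rows * src.cell / target_cell))
    n_cols = int(round(src.n_cols * src.cell / target_cell))
    out_grid = Grid(src.lat0, src.lon0, target_cell, n_rows, n_cols)

    def _axis(out_centers, src_centers):
        u = (out_centers - src_centers[0]) / (src_centers[1] - src_centers[0])
        u = np.clip(u, 0.0, len(src_centers) - 1.0)
        i0 = np.floor(u).astype(int)
        i0 = np.minimum(i0, len(src_centers) - 2)
        frac = u - i0
        return i0, frac

    i0, fy = _axis(out_grid.lat_centers, src.lat_centers)
    j0, fx = _axis(out_grid.lon_centers, src.lon_centers)
    fy = fy[:, None]
    fx = fx[None, :]
    V = pmap.values
    corners = (
        (V[np.ix_(i0, j0)], (1 - fy) * (1 - fx)),
        (V[np.ix_(i0, j0 + 1)], (1 - fy) * fx),
        (V[np.ix_(i0 + 1, j0)], fy * (1 - fx)),
        (V[np.ix_(i0 + 1, j0 + 1)], fy * fx),
    )
    out = np.zeros((n_rows, n_cols))
    missing = np.zeros((n_rows, n_cols), bool)
    for v, w in corners:
        contributes = w > 0
        missing |= contributes & np.isnan(v)
        out += np.where(contributes, w * np.nan_to_num(v), 0.0)
    out = np.clip(out, 0.0, 1.0)
    out[missing] = np.nan
    return PredictionMap(
        date=pmap.date, grid=out_grid, values=out, provenance=dict(pmap.provenance)
    )


def write_maps_netcdf(maps: Sequence[PredictionMap], path: str | Path) -> None:
    """Stack day maps (shared grid) into one NetCDF file."""
    if not maps:
        raise ValueError("no maps to write")
    g = maps[0].grid
    for m in maps:
        if m.grid != g:
            raise ValueError("maps must share a grid")
    arr = np.stack([m.values for m in maps])
    ds = xr.Dataset(
        {"probability": (("time", "lat", "lon"), arr)},
        coords={
            "time": pd.to_datetime([m.date for m in maps]),
            "lat": g.lat_centers,
            "lon": g.lon_centers,
        },
        attrs={"lat0": g.lat0, "lon0": g.lon0, "cell": g.cell},
    )
    ds.to_netcdf(path, engine="scipy")
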