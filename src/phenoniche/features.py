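"""Date-referenced environmental features and the greedy correlation pre-filter.

Each labelled record is summarised by trailing-window aggregates of the
weather variables at its grid cell — window ``w`` covers days ``d-w+1 .. d``
inclusive, where ``d`` is the record's date — plus, optionally, its raw
coordinates.  Temperatures, wind and snow average over the window;
precipitation accumulates.  Before every model training the feature set is
reduced so that no pair of surviving columns has |Pearson r| at or above the
cutoff (default 0.8).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import VARIABLES, WeatherCube
from .sampling import LabeledRecord

#: per-variable window aggregator
WINDOW_AGG = {v: ("sum" if v == "precip" else "mean") for v in VARIABLES}

DEFAULT_WINDOWS = (1, 3, 7, 14, 30, 60, 90, 180, 365)


@dataclass(frozen=True)
class FeatureConfig:
    """Which variables/windows to extract; names are ``<var>_<agg>_<w>d``."""

    variables: tuple[str, ...] = VARIABLES
    windows: tuple[int, ...] = DEFAULT_WINDOWS
    include_coords: bool = True

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.windows):
            raise ValueError("windows must be strictly positive")
        if list(self.windows) != sorted(set(self.windows)):
            raise ValueError("windows must be sorted and unique")
        unknown = set(self.variables) - set(VARIABLES)
        if unknown:
            raise ValueError(f"unknown variables: {sorted(unknown)}")

    @property
    def feature_names(self) -> list[str]:
        names = [
            f"{v}_{WINDOW_AGG[v]}_{w}d" for v in self.variables for w in self.windows
        ]
        if self.include_coords:
            names += ["lat", "lon"]
        return names


@dataclass
class FeatureMatrix:
    """Feature rows aligned 1:1 with surviving labelled records."""

    X: pd.DataFrame  # feature columns only, finite values
    meta: pd.DataFrame  # record_id, pair_id, date, label, lat, lon
    dropped: list[tuple[str, str]] = field(default_factory=list)

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    @property
    def labels(self) -> np.ndarray:
        return self.meta["label"].to_numpy()

    @property
    def years(self) -> np.ndarray:
        return pd.DatetimeIndex(self.meta["date"]).year.to_numpy()

    def subset(self, mask: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            self.X.loc[mask].reset_index(drop=True),
            self.meta.loc[mask].reset_index(drop=True),
        )

    def to_csv(self, path) -> None:
        meta = self.meta[["record_id", "pair_id", "date", "label"]].reset_index(drop=True)
        pd.concat([meta, self.X.reset_index(drop=True)], axis=1).to_csv(path, index=False)


class _WindowStats:
    """Cumulative sums over time enabling O(1) trailing-window aggregates."""

    def __init__(self, cube: WeatherCube, variables: Sequence[str]):
        self.csum: dict[str, np.ndarray] = {}
        self.ncnt: dict[str, np.ndarray] = {}
        T = len(cube.dates)
        for v in variables:
            a = cube.values(v)
            nan = np.isnan(a)
            filled = np.where(nan, 0.0, a)
            self.csum[v] = np.concatenate(
                [np.zeros((1,) + a.shape[1:]), np.cumsum(filled, axis=0)], axis=0
            )
            self.ncnt[v] = np.concatenate(
                [np.zeros((1,) + a.shape[1:], int), np.cumsum(nan, axis=0)], axis=0
            )

    def aggregate(self, var: str, w: int, t: np.ndarray, r: np.ndarray, c: np.ndarray):
        """Trailing aggregate for window w ending at time index t (inclusive)."""
        total = self.csum[var][t + 1, r, c] - self.csum[var][t + 1 - w, r, c]
        nans = self.ncnt[var][t + 1, r, c] - self.ncnt[var][t + 1 - w, r, c]
        out = total if WINDOW_AGG[var] == "sum" else total / w
        return np.where(nans > 0, np.nan, out)


def extract_features(
    records: Sequence[LabeledRecord], cube: WeatherCube, cfg: FeatureConfig
) -> FeatureMatrix:
    """Extract trailing-window features for each labelled record.

    Records whose lookback window leaves the cube's date range are dropped
    with reason ``lookback_out_of_range``; records off-grid or hitting a
    missing weather value are likewise dropped, never imputed.
    """
    if not records:
        raise ValueError("no records to extract features for")
    missing_vars = set(cfg.variables) - set(cube.variables)
    if missing_vars:
        raise ValueError(f"cube lacks variables: {sorted(missing_vars)}")
    lats = np.array([r.lat for r in records])
    lons = np.array([r.lon for r in records])
    t = cube.date_index([r.date for r in records])
    rr, cc = cube.grid.cell_of(lats, lons)
    max_w = max(cfg.windows)

    dropped: list[tuple[str, str]] = []
    ok = np.ones(len(records), bool)
    on_grid = cube.grid.contains(rr, cc) & (t >= 0)
    lookback_ok = t - max_w + 1 >= 0
    for i, rec in enumerate(records):
        if not on_grid[i]:
            dropped.append((rec.record_id, "outside_cube"))
            ok[i] = False
        elif not lookback_ok[i]:
            dropped.append((rec.record_id, "lookback_out_of_range"))
            ok[i] = False

    idx = np.nonzero(ok)[0]
    stats = _WindowStats(cube, cfg.variables)
    cols: dict[str, np.ndarray] = {}
    for v in cfg.variables:
        for w in cfg.windows:
            cols[f"{v}_{WINDOW_AGG[v]}_{w}d"] = stats.aggregate(
                v, w, t[idx], rr[idx], cc[idx]
            )
    if cfg.include_coords:
        cols["lat"] = lats[idx]
        cols["lon"] = lons[idx]
    X = pd.DataFrame(cols, columns=cfg.feature_names)

    finite = np.isfinite(X.to_numpy()).all(axis=1)
    for j in np.nonzero(~finite)[0]:
        dropped.append((records[idx[j]].record_id, "missing_covariate"))
    keep = idx[finite]
    X = X.loc[finite].reset_index(drop=True)
    meta = pd.DataFrame(
        {
            "record_id": [records[i].record_id for i in keep],
            "pair_id": [records[i].pair_id for i in keep],
            "date": pd.to_datetime([records[i].date for i in keep]),
            "label": [records[i].label for i in keep],
            "lat": lats[keep],
            "lon": lons[keep],
        }
    )
    return FeatureMatrix(X, meta, dropped)


def correlation_prefilter(
    X: pd.DataFrame, cutoff: float = 0.8
) -> tuple[list[str], list[tuple[str, str]]]:
    """Greedy elimination of highly correlated feature columns.

    Zero-variance columns go first (correlation undefined).  Then, while any
    pair of remaining columns has |Pearson r| >= cutoff, the pair with the
    largest |r| is found and its member with the larger mean absolute
    correlation to all other remaining columns is dropped (ties break to the
    later column).  The survivors have all pairwise |r| < cutoff.
    """
    if X.shape[1] < 2:
        raise ValueError("need at least 2 columns")
    dropped: list[tuple[str, str]] = []
    variances = X.var(axis=0, ddof=0)
    keep = [c for c in X.columns if variances[c] > 0]
    for c in X.columns:
        if variances[c] == 0:
            dropped.append((c, "zero_variance"))
    if not keep:
        raise ValueError("all columns have zero variance")

    corr = X[keep].corr().abs().to_numpy()
    names = list(keep)
    active = list(range(len(names)))
    while len(active) > 1:
        sub = corr[np.ix_(active, active)]
        np.fill_diagonal(sub, 0.0)
        i_loc, j_loc = np.unravel_index(np.argmax(sub), sub.shape)
        worst = sub[i_loc, j_loc]
        if worst < cutoff:
            break
        i, j = active[min(i_loc, j_loc)], active[max(i_loc, j_loc)]
        mean_i = sub[min(i_loc, j_loc)].sum() / (len(active) - 1)
        mean_j = sub[max(i_loc, j_loc)].sum() / (len(active) - 1)
        victim = j if mean_j >= mean_i else i
        other = i if victim == j else j
        dropped.append(
            (names[victim], f"|r|={worst:.4f} with {names[other]}")
        )
        active.remove(victim)
    return [names[i] for i in active], dropped
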