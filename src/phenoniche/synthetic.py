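"""Synthetic weather, events and benchmark records with known ground truth.

The generator emulates the inputs of the real workflow at desk scale: a
seasonal, spatially structured daily weather cube (AR(1) day-to-day
persistence, latitudinal temperature gradient, seasonal precipitation);
event records drawn from a *known* relative phenological niche (a product of
smooth interval responses on trailing-window weather aggregates); and
benchmark-taxon records driven purely by observer effort.  Observer-effort
bias (weekends, months, same-day weather) enters event generation
multiplicatively with suitability, which is exactly the confound the
temporal bias correction targets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date as Date, time as Time, timedelta
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import Grid, OccurrenceRecord, WeatherCube
from .features import WINDOW_AGG, _WindowStats

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class WeatherGenConfig:
    """Parameters of the synthetic daily weather cube.

    Mean temperature is an annual-mean surface with a latitudinal lapse, a
    seasonal sinusoid peaking at ``peak_doy``, and per-cell AR(1) daily noise
    (lag-1 correlation ``ar1_rho``, stationary sd ``ar1_sigma`` degC).
    Precipitation is a seasonally varying wet-day process with gamma
    magnitudes; wind is lognormal; snow follows cold days.
    """

    lat0: float = 42.0
    lon0: float = 2.0
    cell: float = 0.25
    n_rows: int = 20
    n_cols: int = 20
    first_date: Date = Date(2015, 1, 1)
    last_date: Date = Date(2021, 12, 31)
    tmean_south: float = 13.0  # annual mean at the southern edge, degC
    lat_lapse: float = -0.8  # degC per degree of latitude northward
    seasonal_amplitude: float = 9.0
    peak_doy: int = 200  # mid-July peak (northern hemisphere)
    ar1_rho: float = 0.7
    ar1_sigma: float = 2.2
    tmin_offset: float = 4.5
    tmax_offset: float = 4.5
    diurnal_noise: float = 1.0
    wet_prob_mean: float = 0.35
    wet_prob_amplitude: float = 0.15  # wetter winters
    precip_gamma_shape: float = 0.8
    precip_gamma_scale: float = 6.0  # mm
    wind_lognorm_mu: float = 1.0  # log m/s
    wind_lognorm_sigma: float = 0.5
    snow_per_degree: float = 1.2  # cm per degC below freezing
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.ar1_rho < 1):
            raise ValueError("ar1_rho must be in [0, 1)")
        if self.ar1_sigma <= 0:
            raise ValueError("ar1_sigma must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("degenerate spatial extent")

    @property
    def grid(self) -> Grid:
        return Grid(self.lat0, self.lon0, self.cell, self.n_rows, self.n_cols)


def gen_weather(cfg: WeatherGenConfig) -> WeatherCube:
    """Simulate the daily weather cube; deterministic given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    grid = cfg.grid
    dates = pd.date_range(cfg.first_date, cfg.last_date, freq="D")
    T, R, C = len(dates), grid.n_rows, grid.n_cols
    doy = dates.dayofyear.to_numpy()

    seasonal = cfg.seasonal_amplitude * np.cos(
        2 * np.pi * (doy - cfg.peak_doy) / DAYS_PER_YEAR
    )
    base = cfg.tmean_south + cfg.lat_lapse * (grid.lat_centers - grid.lat_centers[0])
    mean_field = seasonal[:, None, None] + base[None, :, None] + np.zeros((T, R, C))

    innov_sd = cfg.ar1_sigma * np.sqrt(1 - cfg.ar1_rho**2)
    noise = np.empty((T, R, C))
    noise[0] = rng.normal(0, cfg.ar1_sigma, (R, C))
    eps = rng.normal(0, innov_sd, (T, R, C))
    for t in range(1, T):
        noise[t] = cfg.ar1_rho * noise[t - 1] + eps[t]
    tmean = mean_field + noise

    tmin = tmean - cfg.tmin_offset - np.abs(rng.normal(0, cfg.diurnal_noise, (T, R, C)))
    tmax = tmean + cfg.tmax_offset + np.abs(rng.normal(0, cfg.diurnal_noise, (T, R, C)))

    wet_p = cfg.wet_prob_mean + cfg.wet_prob_amplitude * np.cos(
        2 * np.pi * (doy - 15) / DAYS_PER_YEAR
    )
    wet = rng.random((T, R, C)) < np.clip(wet_p, 0.02, 0.98)[:, None, None]
    magnitude = rng.gamma(cfg.precip_gamma_shape, cfg.precip_gamma_scale, (T, R, C))
    precip = np.where(wet, magnitude, 0.0)

    wind = rng.lognormal(cfg.wind_lognorm_mu, cfg.wind_lognorm_sigma, (T, R, C))
    snow = np.maximum(0.0, -tmean) * cfg.snow_per_degree

    return WeatherCube.from_arrays(
        grid,
        dates,
        {"tmin": tmin, "tmean": tmean, "tmax": tmax,
         "precip": precip, "snow": snow, "wind": wind},
    )


@dataclass(frozen=True)
class NicheCondition:
    """One axis of the niche: a smooth suitable interval on a trailing aggregate."""

    variable: str
    window_days: int
    low: float
    high: float
    softness: float = 0.5  # degC (or unit) width of the sigmoid edges

    def response(self, x: np.ndarray) -> np.ndarray:
        from scipy.special import expit

        return expit((x - self.low) / self.softness) * expit(
            (self.high - x) / self.softness
        )


@dataclass(frozen=True)
class NicheDef:
    """The ground-truth relative phenological niche (an interval hypervolume)."""

    conditions: tuple[NicheCondition, ...]
    base_rate: float = 0.01  # expected events per fully suitable cell-day

    def suitability(self, cube: WeatherCube) -> np.ndarray:
        """(time, row, col) suitability in [0, 1]; NaN before full lookback."""
        stats = _WindowStats(cube, tuple({c.variable for c in self.conditions}))
        T = len(cube.dates)
        R, C = cube.grid.n_rows, cube.grid.n_cols
        suit = np.ones((T, R, C))
        for cond in self.conditions:
            csum = stats.csum[cond.variable]
            w = cond.window_days
            vals = csum[w:] - csum[:-w]
            if WINDOW_AGG[cond.variable] == "mean":
                vals = vals / w
            agg = np.full((T, R, C), np.nan)
            agg[w - 1:] = vals
            suit *= cond.response(agg)
        return suit

    @property
    def max_window(self) -> int:
        return max(c.window_days for c in self.conditions)


@dataclass(frozen=True)
class EffortDef:
    """Observer-effort multipliers and same-day weather slopes (log scale)."""

    weekend_multiplier: float = 1.0
    month_multipliers: tuple[float, ...] = (1.0,) * 12
    temp_slope: float = 0.0  # per degC of same-day tmean
    precip_slope: float = 0.0  # per mm of same-day precipitation
    wind_slope: float = 0.0  # per m/s of same-day wind

    def __post_init__(self) -> None:
        if self.weekend_multiplier <= 0 or any(m <= 0 for m in self.month_multipliers):
            raise ValueError("effort multipliers must be positive")

    def log_effort(self, cube: WeatherCube) -> np.ndarray:
        dates = cube.dates
        log_e = np.zeros((len(dates), cube.grid.n_rows, cube.grid.n_cols))
        dow = dates.dayofweek.to_numpy()
        month = dates.month.to_numpy()
        day_term = np.where(dow >= 5, np.log(self.weekend_multiplier), 0.0)
        day_term = day_term + np.log(np.asarray(self.month_multipliers))[month - 1]
        log_e += day_term[:, None, None]
        log_e += self.temp_slope * cube.values("tmean")
        log_e += self.precip_slope * cube.values("precip")
        log_e += self.wind_slope * cube.values("wind")
        return log_e


NEUTRAL_EFFORT = EffortDef()


def _sample_records(
    cube: WeatherCube,
    weight: np.ndarray,
    n: int,
    seed: int,
    prefix: str,
    taxon: str,
) -> list[OccurrenceRecord]:
    """Draw (cell, day) pairs proportional to ``weight`` and jitter coordinates."""
    rng = np.random.default_rng(seed)
    w = np.where(np.isfinite(weight), weight, 0.0).ravel()
    total = w.sum()
    if total <= 0 or n == 0:
        return []
    flat = rng.choice(len(w), size=n, p=w / total)
    t, r, c = np.unravel_index(flat, weight.shape)
    grid = cube.grid
    lat = grid.lat_centers[r] + rng.uniform(-0.5, 0.5, n) * grid.cell * 0.98
    lon = grid.lon_centers[c] + rng.uniform(-0.5, 0.5, n) * grid.cell * 0.98
    dates = cube.dates
    hours = rng.integers(8, 19, size=n)
    minutes = rng.integers(0, 60, size=n)
    out = []
    for i in range(n):
        d = dates[t[i]]
        out.append(
            OccurrenceRecord(
                record_id=f"{prefix}{i}",
                taxon=taxon,
                lat=float(lat[i]),
                lon=float(lon[i]),
                event_date=Date(d.year, d.month, d.day),
                event_time=Time(int(hours[i]), int(minutes[i])),
                coord_uncertainty_deg=0.01,
                has_photo=True,
                evidence_ok=True,
                source="synthetic",
            )
        )
    return out


def _date_mask(cube: WeatherCube, date_range: tuple[Date, Date] | None) -> np.ndarray:
    dates = cube.dates
    if date_range is None:
        return np.ones(len(dates), bool)
    lo, hi = pd.Timestamp(date_range[0]), pd.Timestamp(date_range[1])
    return (dates >= lo) & (dates <= hi)


def gen_events(
    cube: WeatherCube,
    niche: NicheDef,
    effort: EffortDef = NEUTRAL_EFFORT,
    n_target: int = 1500,
    seed: int = 0,
    date_range: tuple[Date, Date] | None = None,
) -> list[OccurrenceRecord]:
    """Draw event records with acceptance probability ~ suitability x effort."""
    import warnings

    suit = niche.suitability(cube)
    eff = np.exp(effort.log_effort(cube))
    eff /= np.nanmax(eff)
    weight = np.nan_to_num(suit) * eff
    weight[~_date_mask(cube, date_range)] = 0.0
    if weight.sum() <= 0:
        warnings.warn("zero total suitability; no events generated", stacklevel=2)
        return []
    return _sample_records(cube, weight, n_target, seed, "ev", "event_species")


def gen_benchmark(
    cube: WeatherCube,
    effort: EffortDef = NEUTRAL_EFFORT,
    n: int = 2000,
    seed: int = 0,
    date_range: tuple[Date, Date] | None = None,
) -> list[OccurrenceRecord]:
    """Benchmark-taxon records driven by observer effort only (year-round)."""
    eff = np.exp(effort.log_effort(cube))
    eff /= eff.max()
    eff[~_date_mask(cube, date_range)] = 0.0
    return _sample_records(cube, eff, n, seed, "bench", "benchmark_taxon")


@dataclass
class Scenario:
    """A complete synthetic study: weather, truth, events and benchmark."""

    cube: WeatherCube
    events: list[OccurrenceRecord]
    benchmark: list[OccurrenceRecord]
    niche: NicheDef
    effort: EffortDef
    event_range: tuple[Date, Date]

    def truth_json(self, path: str | Path) -> None:
        payload = {
            "niche": [
                {"variable": c.variable, "window_days": c.window_days,
                 "low": c.low, "high": c.high, "softness": c.softness}
                for c in self.niche.conditions
            ],
            "effort": {
                "weekend_multiplier": self.effort.weekend_multiplier,
                "month_multipliers": list(self.effort.month_multipliers),
                "temp_slope": self.effort.temp_slope,
                "precip_slope": self.effort.precip_slope,
                "wind_slope": self.effort.wind_slope,
            },
            "event_range": [d.isoformat() for d in self.event_range],
            "n_events": len(self.events),
            "n_benchmark": len(self.benchmark),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


DEFAULT_NICHE = NicheDef(
    conditions=(NicheCondition("tmean", 30, low=15.0, high=18.0, softness=0.3),),
    base_rate=0.01,
)

DEFAULT_BIASED_EFFORT = EffortDef(
    weekend_multiplier=3.0,
    temp_slope=0.04,
    precip_slope=-0.10,
    wind_slope=-0.25,
)


def default_scenario(
    seed: int = 0,
    n_events: int = 1500,
    n_benchmark: int = 2000,
    n_years: int = 6,
    effort: EffortDef = DEFAULT_BIASED_EFFORT,
    niche: NicheDef = DEFAULT_NICHE,
    weather: WeatherGenConfig | None = None,
) -> Scenario:
    """The study conditions used throughout the tests and examples.

    A 20x20-cell, 0.25-degree domain with daily weather from 2015; events are
    drawn for the last ``n_years`` calendar years (the leading year provides
    lookback for yearlong features) from a 30-day mean-temperature window
    niche, with weekend- and weather-biased observer effort.
    """
    ss = np.random.SeedSequence(seed)
    s_weather, s_events, s_bench = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)
    )
    last = Date(2015 + n_years, 12, 31)
    wcfg = weather or WeatherGenConfig(
        first_date=Date(2015, 1, 1), last_date=last, seed=s_weather
    )
    cube = gen_weather(wcfg)
    event_range = (Date(wcfg.first_date.year + 1, 1, 1), wcfg.last_date)
    events = gen_events(
        cube, niche, effort, n_target=n_events, seed=s_events, date_range=event_range
    )
    benchmark = gen_benchmark(
        cube, effort, n=n_benchmark, seed=s_bench, date_range=event_range
    )
    return Scenario(cube, events, benchmark, niche, effort, event_range)
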