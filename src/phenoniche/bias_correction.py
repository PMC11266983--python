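"""Spatial and temporal recording-bias correction for occurrence data.

Spatial bias: deduplication to one record per day and grid cell, then capping
of regionally overrepresented 250 km blocks at the Q3 + 1.5*IQR outlier
threshold of per-block counts.  Temporal bias: a binomial GLM relates records
of a benchmark taxon (assumed to track observer effort, not phenology) to
calendar and same-day weather covariates; the fitted effort surface then
drives inverse-probability resampling of the event records.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from datetime import date as Date, timedelta
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .data_io import Grid, OccurrenceRecord, WeatherCube

_EARTH_RADIUS_M = 6_371_007.2  # authalic sphere

#: weekday names in pandas dayofweek order (0 = Monday)
WEEKDAYS = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")
REFERENCE_WEEKDAY = "Fri"
REFERENCE_MONTH = 4  # April


def equal_area_xy(lat, lon):
    """Lambert cylindrical equal-area coordinates (metres) on a sphere."""
    lat = np.asarray(lat, float)
    lon = np.asarray(lon, float)
    x = _EARTH_RADIUS_M * np.radians(lon)
    y = _EARTH_RADIUS_M * np.sin(np.radians(lat))
    return x, y


def thin_cell_day(
    records: Sequence[OccurrenceRecord], grid: Grid, seed: int
) -> list[OccurrenceRecord]:
    """Keep one uniformly chosen record per (date, grid cell) combination."""
    if not records:
        return []
    rng = np.random.default_rng(seed)
    rows, cols = grid.cell_of([r.lat for r in records], [r.lon for r in records])
    groups: dict[tuple, list[int]] = {}
    for i, rec in enumerate(records):
        groups.setdefault((rec.event_date, int(rows[i]), int(cols[i])), []).append(i)
    kept_idx = sorted(
        idxs[rng.integers(len(idxs))] for idxs in (groups[k] for k in sorted(groups))
    )
    return [records[i] for i in kept_idx]


@dataclass
class BlockCounts:
    """Per-250km-block record counts with the upper outlier threshold."""

    table: pd.DataFrame  # columns block_row, block_col, count, capped_to
    q1: float
    q3: float
    iqr: float
    threshold: float


def regional_thin(
    records: Sequence[OccurrenceRecord],
    block_km: float = 250.0,
    seed: int = 0,
) -> tuple[list[OccurrenceRecord], BlockCounts | None]:
    """Cap overrepresented regions on an equal-area grid of square blocks.

    Counts per block feed the Q3 + 1.5*IQR upper-outlier rule (quartiles via
    linear interpolation over *non-empty* blocks); blocks above the threshold
    are subsampled uniformly to round-half-up(threshold) records.  With fewer
    than four non-empty blocks quartiles are not meaningful and the call is a
    warning no-op.
    """
    if not records:
        return [], None
    x, y = equal_area_xy([r.lat for r in records], [r.lon for r in records])
    size = block_km * 1000.0
    bids = list(zip(np.floor(x / size).astype(int), np.floor(y / size).astype(int)))
    groups: dict[tuple[int, int], list[int]] = {}
    for i, b in enumerate(bids):
        groups.setdefault(b, []).append(i)
    counts = np.array([len(v) for v in groups.values()], float)
    if len(groups) < 4:
        warnings.warn(
            "fewer than 4 non-empty 250 km blocks; regional thinning skipped",
            stacklevel=2,
        )
        return list(records), None
    q1, q3 = np.percentile(counts, [25, 75])  # linear interpolation
    iqr = q3 - q1
    threshold = q3 + 1.5 * iqr
    cap = int(math.floor(threshold + 0.5))  # round half-up
    rng = np.random.default_rng(seed)
    kept_idx: list[int] = []
    rows = []
    for b in sorted(groups):
        idxs = groups[b]
        capped = len(idxs) > threshold
        if capped:
            chosen = sorted(rng.choice(len(idxs), size=cap, replace=False))
            kept_idx.extend(idxs[j] for j in chosen)
        else:
            kept_idx.extend(idxs)
        rows.append(
            {
                "block_row": b[1],
                "block_col": b[0],
                "count": len(idxs),
                "capped_to": cap if capped else len(idxs),
            }
        )
    kept_idx.sort()
    table = pd.DataFrame(rows)
    return (
        [records[i] for i in kept_idx],
        BlockCounts(table, float(q1), float(q3), float(iqr), float(threshold)),
    )


def build_effort_background(
    benchmark: Sequence[OccurrenceRecord],
    date_range: tuple[Date, Date],
    seed: int,
) -> list[OccurrenceRecord]:
    """Background for the effort model: same coordinates, random dates.

    One background record per benchmark record, with a date drawn i.i.d.
    uniformly over the days of ``date_range`` (inclusive).
    """
    if not benchmark:
        raise ValueError("benchmark record set is empty")
    first, last = date_range
    n_days = (last - first).days + 1
    if n_days < 1:
        raise ValueError("empty date_range")
    rng = np.random.default_rng(seed)
    offsets = rng.integers(0, n_days, size=len(benchmark))
    out = []
    for rec, off in zip(benchmark, offsets):
        out.append(
            OccurrenceRecord(
                record_id=f"bg_{rec.record_id}",
                taxon=rec.taxon,
                lat=rec.lat,
                lon=rec.lon,
                event_date=first + timedelta(days=int(off)),
                coord_uncertainty_deg=rec.coord_uncertainty_deg,
                source="background",
            )
        )
    return out


@dataclass
class EffortModel:
    """Binomial GLM of recording effort over calendar and weather covariates.

    Coefficients are log-odds contrasts against Friday (day of week) and
    April (month); ``beta_tmean``/``beta_precip``/``beta_wind`` are slopes on
    same-day mean temperature (degC), total precipitation (mm) and mean wind
    speed (m/s).
    """

    intercept: float
    dow_coefs: dict[str, float]  # 6 contrasts, Friday absent
    month_coefs: dict[int, float]  # 11 contrasts, April absent
    beta_tmean: float
    beta_precip: float
    beta_wind: float
    p_values: dict[str, float] = field(default_factory=dict)
    deviance: float = float("nan")
    n: int = 0

    def __post_init__(self) -> None:
        if len(self.dow_coefs) != 6 or len(self.month_coefs) != 11:
            raise ValueError("expected 6 day-of-week and 11 month contrasts")

    def linear_predictor(self, covariates: pd.DataFrame) -> np.ndarray:
        eta = np.full(len(covariates), self.intercept)
        eta += covariates["dow"].map(lambda d: self.dow_coefs.get(d, 0.0)).to_numpy()
        eta += covariates["month"].map(lambda m: self.month_coefs.get(int(m), 0.0)).to_numpy()
        eta += self.beta_tmean * covariates["tmean"].to_numpy()
        eta += self.beta_precip * covariates["precip"].to_numpy()
        eta += self.beta_wind * covariates["wind"].to_numpy()
        return eta

    def to_json(self, path: str | Path, date_range: tuple[Date, Date] | None = None) -> None:
        payload = {
            "intercept": self.intercept,
            "dow_coefs": self.dow_coefs,
            "month_coefs": {str(k): v for k, v in self.month_coefs.items()},
            "beta_tmean": self.beta_tmean,
            "beta_precip": self.beta_precip,
            "beta_wind": self.beta_wind,
            "p_values": self.p_values,
            "deviance": self.deviance,
            "n": self.n,
            "reference_levels": {"dow": REFERENCE_WEEKDAY, "month": REFERENCE_MONTH},
        }
        if date_range:
            payload["date_range"] = [d.isoformat() for d in date_range]
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "EffortModel":
        d = json.loads(Path(path).read_text())
        return cls(
            intercept=d["intercept"],
            dow_coefs=d["dow_coefs"],
            month_coefs={int(k): v for k, v in d["month_coefs"].items()},
            beta_tmean=d["beta_tmean"],
            beta_precip=d["beta_precip"],
            beta_wind=d["beta_wind"],
            p_values=d.get("p_values", {}),
            deviance=d.get("deviance", float("nan")),
            n=d.get("n", 0),
        )


def effort_covariates(
    records: Sequence[OccurrenceRecord], cube: WeatherCube
) -> pd.DataFrame:
    """Calendar + same-day weather covariates for each record.

    Raises if any record falls outside the cube's dates or grid, or hits a
    missing covariate value.
    """
    dates = [r.event_date for r in records]
    t_idx = cube.date_index(dates)
    rows, cols = cube.grid.cell_of([r.lat for r in records], [r.lon for r in records])
    inside = cube.grid.contains(rows, cols)
    bad = [
        records[i].record_id
        for i in range(len(records))
        if t_idx[i] < 0 or not inside[i]
    ]
    if bad:
        raise ValueError(f"records outside cube date range or grid: {bad[:5]}")
    out = pd.DataFrame(
        {
            "record_id": [r.record_id for r in records],
            "dow": [WEEKDAYS[r.event_date.weekday()] for r in records],
            "month": [r.event_date.month for r in records],
            "tmean": cube.values("tmean")[t_idx, rows, cols],
            "precip": cube.values("precip")[t_idx, rows, cols],
            "wind": cube.values("wind")[t_idx, rows, cols],
        }
    )
    nan_rows = out[["tmean", "precip", "wind"]].isna().any(axis=1)
    if nan_rows.any():
        raise ValueError(
            f"missing weather covariates for records: {list(out.record_id[nan_rows][:5])}"
        )
    return out


def fit_effort_glm(
    benchmark: Sequence[OccurrenceRecord],
    background: Sequence[OccurrenceRecord],
    cube: WeatherCube,
) -> EffortModel:
    """Fit the benchmark-vs-background logistic effort model.

    Predictors: day of week, month (categorical; references Friday/April),
    same-day mean temperature, total precipitation and wind speed.
    """
    df1 = effort_covariates(benchmark, cube)
    df0 = effort_covariates(background, cube)
    df = pd.concat([df1.assign(label=1), df0.assign(label=0)], ignore_index=True)
    formula = (
        f"label ~ C(dow, Treatment('{REFERENCE_WEEKDAY}'))"
        f" + C(month, Treatment({REFERENCE_MONTH})) + tmean + precip + wind"
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
            fit = smf.glm(formula, df, family=sm.families.Binomial()).fit()
    except (
        sm.tools.sm_exceptions.PerfectSeparationError,
        sm.tools.sm_exceptions.PerfectSeparationWarning,
    ) as e:
        raise RuntimeError(
            "perfect separation in effort GLM; add data or penalise the fit"
        ) from e
    params = fit.params
    if not np.all(np.isfinite(params.values)):
        raise RuntimeError("non-finite effort GLM coefficients")

    def _pick(prefix: str) -> dict:
        out = {}
        for name, val in params.items():
            if name.startswith(prefix):
                level = name[len(prefix):].rstrip("]")
                out[level] = float(val)
        return out

    dow_prefix = f"C(dow, Treatment('{REFERENCE_WEEKDAY}'))[T."
    month_prefix = f"C(month, Treatment({REFERENCE_MONTH}))[T."
    dow = _pick(dow_prefix)
    months = {int(k): v for k, v in _pick(month_prefix).items()}
    pvals = {str(k): float(v) for k, v in fit.pvalues.items()}
    return EffortModel(
        intercept=float(params["Intercept"]),
        dow_coefs=dow,
        month_coefs=months,
        beta_tmean=float(params["tmean"]),
        beta_precip=float(params["precip"]),
        beta_wind=float(params["wind"]),
        p_values=pvals,
        deviance=float(fit.deviance),
        n=len(df),
    )


def effort_scores(
    model: EffortModel, records: Sequence[OccurrenceRecord], cube: WeatherCube
) -> np.ndarray:
    """Predicted recording-effort probability for each record, in (0, 1)."""
    cov = effort_covariates(records, cube)
    eta = model.linear_predictor(cov)
    return 1.0 / (1.0 + np.exp(-eta))


def ipw_resample(
    records: Sequence[OccurrenceRecord],
    scores: np.ndarray,
    seed: int,
    method: str = "bernoulli",
    n: int | None = None,
    stabilize: float = 0.0,
) -> list[OccurrenceRecord]:
    """Inverse-probability resampling against estimated recording effort.

    ``bernoulli`` (default): record i is kept with probability
    ``min(scores) / scores[i]`` (the least-effort record is always kept).
    ``stabilize`` > 0 replaces the minimum by that quantile of the scores and
    caps probabilities at 1 — standard truncation of inverse-probability
    weights, preventing a single extreme low-effort record from thinning the
    whole dataset.  ``fixed_size``: draw exactly ``n`` records without
    replacement with weights proportional to ``1 / scores``.
    """
    scores = np.asarray(scores, float)
    if len(scores) != len(records):
        raise ValueError("scores not aligned with records")
    if np.any(scores <= 0):
        raise ValueError("effort scores must be strictly positive")
    if not (0.0 <= stabilize < 1.0):
        raise ValueError("stabilize must be a quantile in [0, 1)")
    rng = np.random.default_rng(seed)
    if method == "bernoulli":
        ref = np.quantile(scores, stabilize) if stabilize > 0 else scores.min()
        p = np.minimum(1.0, ref / scores)
        keep = rng.random(len(records)) < p
        return [r for r, k in zip(records, keep) if k]
    if method == "fixed_size":
        if n is None or not (0 < n <= len(records)):
            raise ValueError("fixed_size resampling needs 0 < n <= len(records)")
        w = 1.0 / scores
        idx = rng.choice(len(records), size=n, replace=False, p=w / w.sum())
        return [records[i] for i in sorted(idx)]
    raise ValueError(f"unknown resampling method {method!r}")
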