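"""Temporally independent evaluation and regional validation.

Leave-one-year-out (LOYO): each calendar year is scored by models trained on
the remaining years; discrimination between event records and temporal
pseudoabsences is measured by the AUC (the probability that a presence
outranks a pseudoabsence, ties counted one half).  Regional validation
compares the daily region-averaged prediction of a model trained *without*
the region's records against the raw timing of observations there, via the
point-biserial correlation over 10-day bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as Date
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .data_io import OccurrenceRecord, WeatherCube
from .features import FeatureConfig, FeatureMatrix
from .models import EnsembleModel, TrainConfig, predict_scores, train_ensemble


def loyo_partition(fm: FeatureMatrix, year: int) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Split a labelled feature matrix into train (other years) and test (year).

    Pseudoabsences belong to the year of their own random date, so the test
    side represents the held-out year's conditions for both classes.
    """
    years = fm.years
    if year not in years:
        raise ValueError(f"year {year} not present in data")
    if len(np.unique(years)) < 2:
        raise ValueError("leave-one-year-out needs at least 2 years")
    test_mask = years == year
    return fm.subset(~test_mask), fm.subset(test_mask)


def auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Ranking AUC; equals the Mann-Whitney pairwise probability with ties at 0.5."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, float)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(labels, scores))


def point_biserial(binary: Sequence[int], x: Sequence[float]) -> tuple[float, float]:
    """Point-biserial correlation (Pearson on a 0/1 and a continuous variable).

    Returns (r, p); p comes from the t-transform t = r*sqrt((n-2)/(1-r^2)).
    Undefined (NaN, NaN) when either variable is constant.
    """
    b = np.asarray(binary, float)
    x = np.asarray(x, float)
    n = len(b)
    if n != len(x):
        raise ValueError("length mismatch")
    if n < 3 or b.std() == 0 or x.std() == 0:
        return float("nan"), float("nan")
    r = float(np.corrcoef(b, x)[0, 1])
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return r, p


def evaluate_loyo(
    fm: FeatureMatrix,
    cfg: TrainConfig,
    years: Sequence[int] | None = None,
    corr_cutoff: float = 0.8,
    correction: str = "corrected",
    weather_source: str = "synthetic",
) -> tuple[pd.DataFrame, dict[int, EnsembleModel]]:
    """LOYO evaluation of the forest, the BRT, and their ensemble.

    Returns a tidy report (year x algorithm rows with AUC and test counts)
    shaped like the per-year evaluation tables, plus the per-year models.
    """
    all_years = sorted(set(fm.years))
    years = sorted(years) if years is not None else all_years
    rows = []
    fitted: dict[int, EnsembleModel] = {}
    for year in years:
        train, test = loyo_partition(fm, year)
        model = train_ensemble(train, cfg, corr_cutoff=corr_cutoff)
        fitted[year] = model
        y_true = test.labels
        if len(np.unique(y_true)) < 2:
            continue
        member_scores = {
            "rf": predict_scores(model.forest, test.X),
            "brt": predict_scores(model.brt, test.X),
        }
        member_scores["ensemble"] = 0.5 * (member_scores["rf"] + member_scores["brt"])
        for algo in ("brt", "rf", "ensemble"):
            rows.append(
                {
                    "year": year,
                    "algorithm": algo,
                    "weather_source": weather_source,
                    "correction": correction,
                    "auc": auc(y_true, member_scores[algo]),
                    "n_test_presences": int((y_true == 1).sum()),
                    "n_test_pseudoabsences": int((y_true == 0).sum()),
                }
            )
    return pd.DataFrame(rows), fitted


@dataclass
class RegionalValidation:
    """Point-biserial agreement between regional mean prediction and raw timing."""

    years: list[int]
    excluded_years: list[int]
    r: float
    p_value: float
    bins: pd.DataFrame  # year, bin_start, mean_prediction, observed
    per_year_r: dict[int, float] = field(default_factory=dict)


def _year_bins(year: int, bin_length: int) -> list[tuple[Date, Date]]:
    """Consecutive bins anchored at Jan 1; the final bin holds the remainder
    (5-6 days for 10-day bins)."""
    from datetime import timedelta

    start = Date(year, 1, 1)
    n_days = (Date(year, 12, 31) - start).days + 1
    starts = list(range(0, n_days, bin_length))
    bins = []
    for i, s in enumerate(starts):
        hi = starts[i + 1] - 1 if i + 1 < len(starts) else n_days - 1
        bins.append((start + timedelta(days=s), start + timedelta(days=hi)))
    return bins


def regional_validate(
    model: EnsembleModel,
    cube: WeatherCube,
    region_mask: np.ndarray,
    obs: Sequence[OccurrenceRecord],
    years: Sequence[int],
    feature_cfg: FeatureConfig,
    bin_length: int = 10,
    min_records: int = 10,
) -> RegionalValidation:
    """Validate a region-holdout model against raw observation timing.

    For each year with at least ``min_records`` raw observations inside the
    region, the ensemble prediction is averaged over unmasked cells per day,
    days are grouped into consecutive ``bin_length``-day bins anchored at
    Jan 1 (the final bin absorbs the remainder), and a bin is an observed 1
    iff at least one raw record falls in it.  r pools bins across included
    years; ``obs`` must be raw (unthinned, unresampled) records.
    """
    from .mapping import predict_period_means  # local import to avoid a cycle

    region_mask = np.asarray(region_mask, bool)
    if region_mask.shape != (cube.grid.n_rows, cube.grid.n_cols):
        raise ValueError("region mask shape does not match the cube grid")
    rr, cc = cube.grid.cell_of([r.lat for r in obs], [r.lon for r in obs])
    inside = cube.grid.contains(rr, cc)
    in_region = np.zeros(len(obs), bool)
    in_region[inside] = region_mask[rr[inside], cc[inside]]

    included, excluded = [], []
    for year in years:
        n = sum(
            1 for i, r in enumerate(obs) if in_region[i] and r.event_date.year == year
        )
        (included if n >= min_records else excluded).append(year)

    rows = []
    per_year_r: dict[int, float] = {}
    for year in included:
        bins = _year_bins(year, bin_length)
        daily = predict_period_means(
            model, cube, region_mask, Date(year, 1, 1), Date(year, 12, 31), feature_cfg
        )
        obs_dates = {
            r.event_date
            for i, r in enumerate(obs)
            if in_region[i] and r.event_date.year == year
        }
        for lo, hi in bins:
            days = pd.date_range(lo, hi, freq="D")
            pred = float(np.nanmean([daily[d.date()] for d in days]))
            seen = int(any(lo <= d <= hi for d in obs_dates))
            rows.append(
                {"year": year, "bin_start": lo.isoformat(), "mean_prediction": pred,
                 "observed": seen}
            )
        ydf = [r for r in rows if r["year"] == year]
        r_y, _ = point_biserial(
            [r["observed"] for r in ydf], [r["mean_prediction"] for r in ydf]
        )
        per_year_r[year] = r_y
    bins_df = pd.DataFrame(rows)
    if len(bins_df):
        r, p = point_biserial(bins_df["observed"], bins_df["mean_prediction"])
    else:
        r, p = float("nan"), float("nan")
    return RegionalValidation(
        years=included, excluded_years=excluded, r=r, p_value=p,
        bins=bins_df, per_year_r=per_year_r,
    )
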