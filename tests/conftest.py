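"""Shared fixtures: small synthetic scenarios and trained models.

Everything is generated programmatically with fixed seeds; heavyweight
objects are session-scoped so the suite builds each of them once.
"""

from __future__ import annotations

from datetime import date

import numpy as np
import pandas as pd
import pytest

from phenoniche import (
    FeatureConfig,
    FilterConfig,
    TrainConfig,
    assemble_labeled,
    extract_features,
    generate_pseudoabsences,
    regional_thin,
    thin_cell_day,
    train_ensemble,
)
from phenoniche.data_io import Grid, WeatherCube
from phenoniche.synthetic import WeatherGenConfig, default_scenario, gen_weather

#: small training profile for unit tests (not the documented fast profile)
TINY_TRAIN = TrainConfig(
    rf_trees=150, brt_learning_rate=0.05, brt_max_trees=400, brt_step_size=30, seed=7
)


@pytest.fixture(scope="session")
def tiny_cube() -> WeatherCube:
    """4x4-cell cube over two years; enough lookback for 365-day windows."""
    cfg = WeatherGenConfig(
        n_rows=4, n_cols=4, first_date=date(2019, 1, 1), last_date=date(2020, 12, 31),
        seed=11,
    )
    return gen_weather(cfg)


@pytest.fixture(scope="session")
def scenario_small():
    """400 events over two modelled years on the default 20x20 domain."""
    return default_scenario(seed=21, n_events=400, n_benchmark=800, n_years=2)


@pytest.fixture(scope="session")
def fm_small(scenario_small):
    sc = scenario_small
    thinned = thin_cell_day(sc.events, sc.cube.grid, 31)
    thinned, _ = regional_thin(thinned, seed=32)
    years = sorted({r.event_date.year for r in thinned})
    span = (date(years[0], 1, 1), date(years[-1], 12, 31))
    pas = generate_pseudoabsences(thinned, span, n_per=12, seed=33)
    return extract_features(assemble_labeled(thinned, pas), sc.cube, FeatureConfig())


@pytest.fixture(scope="session")
def model_small(fm_small):
    return train_ensemble(fm_small, TINY_TRAIN)


@pytest.fixture()
def flat_cube() -> WeatherCube:
    """Spatially and temporally constant cube (tmean 9 degC) for oracles."""
    grid = Grid(40.0, 0.0, 0.5, 3, 3)
    dates = pd.date_range("2020-01-01", "2021-12-31", freq="D")
    shape = (len(dates), 3, 3)
    arrays = {
        "tmin": np.full(shape, 4.0),
        "tmean": np.full(shape, 9.0),
        "tmax": np.full(shape, 14.0),
        "precip": np.full(shape, 2.0),
        "snow": np.zeros(shape),
        "wind": np.full(shape, 3.0),
    }
    return WeatherCube.from_arrays(grid, dates, arrays)
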