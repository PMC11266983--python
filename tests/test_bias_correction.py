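"""Spatial thinning, 250 km capping, effort GLM and IPW resampling."""

from datetime import date

import numpy as np
import pandas as pd
import pytest

from phenoniche.bias_correction import (
    build_effort_background,
    effort_covariates,
    effort_scores,
    fit_effort_glm,
    ipw_resample,
    regional_thin,
    thin_cell_day,
    EffortModel,
)
from phenoniche.data_io import Grid, OccurrenceRecord
from phenoniche.synthetic import (
    EffortDef,
    WeatherGenConfig,
    gen_benchmark,
    gen_weather,
)

GRID = Grid(40.0, 0.0, 0.25, 20, 20)


def _rec(i, lat, lon, d):
    return OccurrenceRecord(str(i), "t", lat, lon, d)


class TestThinCellDay:
    def test_same_cell_same_day_one_survives(self):
        recs = [_rec(i, 40.1 + 0.01 * i, 0.1, date(2020, 6, 1)) for i in range(3)]
        assert len(thin_cell_day(recs, GRID, seed=1)) == 1

    def test_same_cell_distinct_days_all_kept(self):
        recs = [_rec(i, 40.1, 0.1, date(2020, 6, 1 + i)) for i in range(3)]
        assert len(thin_cell_day(recs, GRID, seed=1)) == 3

    def test_output_size_equals_distinct_pairs_bruteforce(self):
        rng = np.random.default_rng(9)
        recs = [
            _rec(i, 40 + rng.uniform(0, 5), rng.uniform(0, 5),
                 date(2020, 6, 1) + pd.Timedelta(days=int(rng.integers(0, 20))).to_pytimedelta())
            for i in range(500)
        ]
        pairs = {
            (r.event_date, *map(int, GRID.cell_of(r.lat, r.lon))) for r in recs
        }
        thinned = thin_cell_day(recs, GRID, seed=2)
        assert len(thinned) == len(pairs)

    def test_idempotent_and_seed_deterministic(self):
        rng = np.random.default_rng(10)
        recs = [
            _rec(i, 40 + rng.uniform(0, 1), rng.uniform(0, 1), date(2020, 6, 5))
            for i in range(60)
        ]
        once = thin_cell_day(recs, GRID, seed=3)
        assert thin_cell_day(once, GRID, seed=99) == once
        assert thin_cell_day(recs, GRID, seed=3) == once


class TestRegionalThin:
    def _block_records(self, counts):
        # widely separated longitudes at the equator -> distinct 250 km blocks
        recs = []
        for b, n in enumerate(counts):
            for i in range(n):
                recs.append(_rec(f"{b}_{i}", 0.1, b * 20.0, date(2020, 1, 1)))
        return recs

    def test_equal_counts_zero_iqr_nothing_removed(self):
        recs = self._block_records([5, 5, 5, 5])
        kept, bc = regional_thin(recs, seed=1)
        assert len(kept) == 20
        assert bc.threshold == 5.0

    def test_hand_traced_outlier_capping(self):
        # counts {2,4,6,100}: linear-interpolation quartiles Q1=3.5, Q3=29.5,
        # IQR=26 -> threshold 68.5; the 100-record block caps to 69
        recs = self._block_records([2, 4, 6, 100])
        kept, bc = regional_thin(recs, seed=2)
        assert (bc.q1, bc.q3, bc.iqr) == (3.5, 29.5, 26.0)
        assert bc.threshold == 68.5
        row = bc.table.set_index("count").loc[100]
        assert row["capped_to"] == 69
        assert len(kept) == 2 + 4 + 6 + 69

    def test_never_touches_blocks_at_or_below_threshold(self):
        recs = self._block_records([3, 8, 10, 200])
        kept, bc = regional_thin(recs, seed=3)
        small_ids = {r.record_id for r in recs if not r.record_id.startswith("3_")}
        assert small_ids <= {r.record_id for r in kept}

    def test_degenerate_single_block_warns_noop(self):
        recs = [_rec(i, 0.1, 0.1, date(2020, 1, 1)) for i in range(50)]
        with pytest.warns(UserWarning, match="fewer than 4"):
            kept, bc = regional_thin(recs, seed=4)
        assert kept == recs and bc is None


class TestEffortBackground:
    def test_counts_and_coordinate_multiset(self):
        recs = [_rec(i, 40 + i * 0.01, i * 0.01, date(2020, 3, 1)) for i in range(500)]
        bg = build_effort_background(recs, (date(2019, 1, 1), date(2020, 12, 31)), seed=5)
        assert len(bg) == 500
        assert sorted((r.lat, r.lon) for r in bg) == sorted((r.lat, r.lon) for r in recs)
        assert all(date(2019, 1, 1) <= r.event_date <= date(2020, 12, 31) for r in bg)

    def test_single_day_range(self):
        recs = [_rec(0, 40.0, 0.0, date(2020, 3, 1))]
        bg = build_effort_background(recs, (date(2020, 7, 7), date(2020, 7, 7)), seed=6)
        assert bg[0].event_date == date(2020, 7, 7)

    def test_dates_uniform_over_years(self):
        from scipy.stats import chisquare

        recs = [_rec(i, 40.0, 0.0, date(2020, 3, 1)) for i in range(10_000)]
        span = (date(2015, 1, 1), date(2021, 12, 31))
        bg = build_effort_background(recs, span, seed=7)
        years = pd.Series([r.event_date.year for r in bg]).value_counts().sort_index()
        days = pd.Series(
            pd.date_range(*span, freq="D").year
        ).value_counts().sort_index()
        expected = days / days.sum() * len(bg)
        _, p = chisquare(years.to_numpy(), expected.to_numpy())
        assert p > 0.01

    def test_empty_benchmark_errors(self):
        with pytest.raises(ValueError, match="empty"):
            build_effort_background([], (date(2020, 1, 1), date(2020, 2, 1)), seed=0)


def _effort_model(**kw):
    base = dict(
        intercept=0.0,
        dow_coefs={d: 0.0 for d in ("Mon", "Tue", "Wed", "Thu", "Sat", "Sun")},
        month_coefs={m: 0.0 for m in range(1, 13) if m != 4},
        beta_tmean=0.0,
        beta_precip=0.0,
        beta_wind=0.0,
    )
    base.update(kw)
    return EffortModel(**base)


class TestEffortModelScores:
    def test_all_zero_coefficients_score_half(self, flat_cube):
        recs = [_rec(0, 40.3, 0.3, date(2020, 6, 15))]
        s = effort_scores(_effort_model(), recs, flat_cube)
        assert s[0] == pytest.approx(0.5)

    def test_closed_form_linear_predictor(self, flat_cube):
        m = _effort_model(intercept=-1.0, beta_tmean=0.1, beta_precip=-0.2,
                          dow_coefs={"Mon": 0.5, "Tue": 0, "Wed": 0, "Thu": 0,
                                     "Sat": 0, "Sun": 0},
                          month_coefs={**{m: 0.0 for m in range(1, 13) if m != 4},
                                       6: 0.3})
        rec = _rec(0, 40.3, 0.3, date(2020, 6, 15))  # a Monday in June
        eta = -1.0 + 0.5 + 0.3 + 0.1 * 9.0 - 0.2 * 2.0
        s = effort_scores(m, [rec], flat_cube)
        assert s[0] == pytest.approx(1 / (1 + np.exp(-eta)), abs=1e-12)

    def test_monotone_in_temperature(self, flat_cube):
        m = _effort_model(beta_tmean=0.2)
        warm = flat_cube.data.copy()
        warm["tmean"] = warm["tmean"] + 5
        from phenoniche.data_io import WeatherCube

        warm_cube = WeatherCube(warm, flat_cube.grid)
        recs = [_rec(0, 40.3, 0.3, date(2020, 6, 15))]
        assert effort_scores(m, recs, warm_cube)[0] > effort_scores(m, recs, flat_cube)[0]

    def test_out_of_range_record_errors(self, flat_cube):
        recs = [_rec("far", 40.3, 0.3, date(2030, 1, 1))]
        with pytest.raises(ValueError, match="far"):
            effort_scores(_effort_model(), recs, flat_cube)

    def test_json_roundtrip(self, tmp_path):
        m = _effort_model(intercept=0.7, beta_wind=-0.3)
        m.to_json(tmp_path / "m.json", date_range=(date(2015, 1, 1), date(2021, 12, 31)))
        back = EffortModel.from_json(tmp_path / "m.json")
        assert back.intercept == 0.7 and back.beta_wind == -0.3
        assert back.month_coefs == m.month_coefs


class TestFitEffortGLM:
    def test_recovers_injected_signs_and_statsmodels_agreement(self):
        cube = gen_weather(
            WeatherGenConfig(n_rows=6, n_cols=6, first_date=date(2018, 1, 1),
                             last_date=date(2020, 12, 31), seed=3)
        )
        span = (date(2018, 1, 1), date(2020, 12, 31))
        effort = EffortDef(weekend_multiplier=3.0, precip_slope=-0.1, wind_slope=-0.25)
        bench = gen_benchmark(cube, effort, n=1500, seed=4, date_range=span)
        bg = build_effort_background(bench, span, seed=5)
        model = fit_effort_glm(bench, bg, cube)
        assert model.dow_coefs["Sat"] > 0 and model.dow_coefs["Sun"] > 0
        assert model.beta_precip < 0 and model.beta_wind < 0

        # dual route: hand-built linear predictor vs statsmodels' own predict
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        df1 = effort_covariates(bench, cube).assign(label=1)
        df0 = effort_covariates(bg, cube).assign(label=0)
        df = pd.concat([df1, df0], ignore_index=True)
        fit = smf.glm(
            "label ~ C(dow, Treatment('Fri')) + C(month, Treatment(4))"
            " + tmean + precip + wind",
            df, family=sm.families.Binomial(),
        ).fit()
        np.testing.assert_allclose(
            1 / (1 + np.exp(-model.linear_predictor(df))),
            fit.predict(df),
            atol=1e-8,
        )


class TestIPWResample:
    def test_uniform_scores_identity(self):
        recs = [_rec(i, 40.0, 0.0, date(2020, 1, 1)) for i in range(100)]
        assert ipw_resample(recs, np.full(100, 0.7), seed=1) == recs

    def test_two_score_inclusion_probability(self):
        # scores {0.2, 0.4} -> p = {1.0, 0.5}; check by Monte Carlo over seeds
        recs = [_rec(i, 40.0, 0.0, date(2020, 1, 1)) for i in range(2)]
        kept_low = kept_high = 0
        n = 2000
        for s in range(n):
            kept = {r.record_id for r in ipw_resample(recs, np.array([0.2, 0.4]), seed=s)}
            kept_low += "0" in kept
            kept_high += "1" in kept
        assert kept_low == n  # p = 1 exactly
        assert abs(kept_high / n - 0.5) < 4 * np.sqrt(0.25 / n)

    def test_expected_kept_count(self):
        rng = np.random.default_rng(2)
        scores = rng.uniform(0.1, 0.9, 200)
        recs = [_rec(i, 40.0, 0.0, date(2020, 1, 1)) for i in range(200)]
        p = scores.min() / scores
        counts = [len(ipw_resample(recs, scores, seed=s)) for s in range(1000)]
        sd = np.sqrt(np.sum(p * (1 - p)) / 1000)
        assert abs(np.mean(counts) - p.sum()) < 3 * sd

    def test_stabilized_keeps_more(self):
        scores = np.array([0.001] + [0.5] * 99)
        recs = [_rec(i, 40.0, 0.0, date(2020, 1, 1)) for i in range(100)]
        plain = ipw_resample(recs, scores, seed=3)
        stab = ipw_resample(recs, scores, seed=3, stabilize=0.1)
        assert len(stab) > len(plain)

    def test_fixed_size_draw(self):
        scores = np.linspace(0.1, 0.9, 50)
        recs = [_rec(i, 40.0, 0.0, date(2020, 1, 1)) for i in range(50)]
        out = ipw_resample(recs, scores, seed=4, method="fixed_size", n=20)
        assert len(out) == 20 and len({r.record_id for r in out}) == 20

    def test_nonpositive_score_errors(self):
        recs = [_rec(0, 40.0, 0.0, date(2020, 1, 1))]
        with pytest.raises(ValueError, match="positive"):
            ipw_resample(recs, np.array([0.0]), seed=1)
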