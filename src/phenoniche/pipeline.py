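"""Config-driven orchestration of the full workflow.

Order of stages: read/filter occurrences -> spatial thinning (cell-day +
regional capping) -> optional temporal bias correction (effort GLM + IPW)
-> temporal pseudoabsences -> feature extraction -> leave-one-year-out
training/evaluation -> optional daily maps.  With ``correction="both"`` the
temporally corrected and uncorrected datasets are carried side by side and
both evaluated.  Every stochastic stage draws its seed from one master seed
through a fixed named split, so stages are individually reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import date as Date
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import bias_correction as bc
from .data_io import FilterConfig, OccurrenceRecord, WeatherCube, filter_occurrences
from .evaluation import evaluate_loyo, regional_validate
from .features import FeatureConfig, extract_features
from .mapping import downsample_bilinear, predict_day_map, write_maps_netcdf
from .models import TrainConfig, train_ensemble
from .sampling import assemble_labeled, generate_pseudoabsences, write_labeled_csv

_STAGES = ("thin", "regional", "background", "ipw", "pseudoabsence", "train")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def stage_seeds(master: int) -> dict[str, int]:
    """Expand one master seed into named per-stage seeds (fixed order)."""
    children = np.random.SeedSequence(master).spawn(len(_STAGES))
    return {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(_STAGES, children)
    }


@dataclass
class PipelineConfig:
    out_dir: Path
    filter: FilterConfig = field(default_factory=FilterConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    correction: str = "both"  # "both" | "on" | "off"
    ipw_stabilize: float = 0.10  # quantile truncation of inverse-probability weights
    n_per: int = 12
    seed: int = 0
    corr_cutoff: float = 0.8
    eval_years: tuple[int, ...] | None = None
    map_dates: tuple[Date, ...] = ()
    map_target_cell: float | None = None  # e.g. 0.02 for visualisation output
    validation_region: np.ndarray | None = None  # boolean mask on the cube grid

    def __post_init__(self) -> None:
        if self.correction not in ("both", "on", "off"):
            raise ValueError("correction must be 'both', 'on' or 'off'")
        self.out_dir = Path(self.out_dir)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def run(
    cfg: PipelineConfig,
    occurrences: Sequence[OccurrenceRecord],
    cube: WeatherCube,
    benchmark: Sequence[OccurrenceRecord] | None = None,
    mask: np.ndarray | None = None,
) -> dict:
    """Execute the workflow end to end; returns (and writes) a run manifest."""
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(cfg.seed)
    manifest: dict = {
        "seed": cfg.seed,
        "stage_seeds": seeds,
        "config": {
            "correction": cfg.correction,
            "n_per": cfg.n_per,
            "train_hash": cfg.train.config_hash(),
        },
        "outputs": {},
        "stages": [],
    }

    import logging
    import time

    log = logging.getLogger("phenoniche.pipeline")
    t_prev = time.perf_counter()

    def _done(stage: str, **info) -> None:
        nonlocal t_prev
        now = time.perf_counter()
        manifest["stages"].append(
            {"stage": stage, "elapsed_s": round(now - t_prev, 3), **info}
        )
        log.info("stage %s done in %.1fs %s", stage, now - t_prev, info)
        t_prev = now

    def _fail(stage: str, exc: Exception):
        (out / "manifest.partial.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise PipelineError(stage, str(exc)) from exc

    try:
        kept, rejected = filter_occurrences(occurrences, cfg.filter)
        pd.DataFrame(rejected, columns=["record_id", "reason"]).to_csv(
            out / "rejections.csv", index=False
        )
        if not kept:
            raise ValueError("no records survive quality filtering")
        _done("filter", n_in=len(occurrences), n_kept=len(kept))
    except PipelineError:
        raise
    except Exception as e:
        _fail("filter", e)

    try:
        thinned = bc.thin_cell_day(kept, cube.grid, seeds["thin"])
        thinned, blocks = bc.regional_thin(thinned, seed=seeds["regional"])
        if blocks is not None:
            blocks.table.to_csv(out / "block_counts.csv", index=False)
        _done("spatial_bias", n_after_cell_day=len(thinned))
    except Exception as e:
        _fail("spatial_bias", e)

    variants: dict[str, list[OccurrenceRecord]] = {}
    if cfg.correction in ("both", "off"):
        variants["uncorrected"] = thinned
    if cfg.correction in ("both", "on"):
        try:
            if benchmark is None:
                raise ValueError("temporal correction requires benchmark records")
            bench_kept, _ = filter_occurrences(benchmark, cfg.filter)
            if not bench_kept:
                raise ValueError("no benchmark records survive filtering")
            span = (
                min(r.event_date for r in bench_kept),
                max(r.event_date for r in bench_kept),
            )
            background = bc.build_effort_background(bench_kept, span, seeds["background"])
            effort_model = bc.fit_effort_glm(bench_kept, background, cube)
            effort_model.to_json(out / "effort_model.json", date_range=span)
            scores = bc.effort_scores(effort_model, thinned, cube)
            variants["corrected"] = bc.ipw_resample(
                thinned, scores, seeds["ipw"], stabilize=cfg.ipw_stabilize
            )
            _done(
                "temporal_bias",
                n_benchmark=len(bench_kept),
                n_corrected=len(variants["corrected"]),
            )
        except Exception as e:
            _fail("temporal_bias", e)

    reports = []
    models = {}
    for name, events in variants.items():
        try:
            years = sorted({r.event_date.year for r in events})
            pa_range = (Date(years[0], 1, 1), Date(years[-1], 12, 31))
            pas = generate_pseudoabsences(
                events, pa_range, n_per=cfg.n_per,
                seed=seeds["pseudoabsence"], collision="allow",
            )
            labeled = assemble_labeled(events, pas)
            write_labeled_csv(labeled, out / f"labeled_{name}.csv")
            fm = extract_features(labeled, cube, cfg.features)
            _done(f"features_{name}", n_rows=len(fm.X), n_dropped=len(fm.dropped))
        except Exception as e:
            _fail(f"features_{name}", e)
        try:
            report, _ = evaluate_loyo(
                fm, cfg.train, years=cfg.eval_years,
                corr_cutoff=cfg.corr_cutoff, correction=name,
            )
            reports.append(report)
            models[name] = train_ensemble(fm, cfg.train, corr_cutoff=cfg.corr_cutoff)
            models[name].save(out / f"model_{name}.pkl")
            _done(f"train_{name}", selected_brt_trees=models[name].brt.selected_trees)
        except Exception as e:
            _fail(f"train_{name}", e)

    eval_report = pd.concat(reports, ignore_index=True)
    eval_report = eval_report.sort_values(
        ["correction", "year", "algorithm"], kind="mergesort"
    ).reset_index(drop=True)
    eval_report.to_csv(out / "eval_report.csv", index=False, float_format="%.6f")
    manifest["outputs"]["eval_report"] = "eval_report.csv"

    if cfg.map_dates:
        try:
            map_model = models.get("corrected", next(iter(models.values())))
            m = mask if mask is not None else np.ones(
                (cube.grid.n_rows, cube.grid.n_cols), bool
            )
            maps = [
                predict_day_map(map_model, cube, d, cfg.features, m)
                for d in cfg.map_dates
            ]
            write_maps_netcdf(maps, out / "maps.nc")
            manifest["outputs"]["maps"] = "maps.nc"
            if cfg.map_target_cell:
                fine = [downsample_bilinear(pm, cfg.map_target_cell) for pm in maps]
                write_maps_netcdf(fine, out / "maps_fine.nc")
                manifest["outputs"]["maps_fine"] = "maps_fine.nc"
            _done("mapping", n_maps=len(maps))
        except Exception as e:
            _fail("mapping", e)

    if cfg.validation_region is not None:
        try:
            region = np.asarray(cfg.validation_region, bool)
            name = "corrected" if "corrected" in variants else "uncorrected"
            events = variants[name]
            rr, cc = cube.grid.cell_of(
                [r.lat for r in events], [r.lon for r in events]
            )
            outside = ~region[rr, cc]
            held = [e for e, o in zip(events, outside) if o]
            years = sorted({r.event_date.year for r in held})
            pa_range = (Date(years[0], 1, 1), Date(years[-1], 12, 31))
            pas = generate_pseudoabsences(
                held, pa_range, n_per=cfg.n_per, seed=seeds["pseudoabsence"]
            )
            fm = extract_features(assemble_labeled(held, pas), cube, cfg.features)
            region_model = train_ensemble(fm, cfg.train, corr_cutoff=cfg.corr_cutoff)
            rv = regional_validate(
                region_model, cube, region, kept, years, cfg.features
            )
            rv.bins.to_csv(out / "regional_validation.csv", index=False)
            (out / "regional_validation.json").write_text(
                json.dumps(
                    {"r": rv.r, "p_value": rv.p_value, "years": rv.years,
                     "excluded_years": rv.excluded_years,
                     "per_year_r": {str(k): v for k, v in rv.per_year_r.items()}},
                    indent=2,
                )
            )
            manifest["outputs"]["regional_validation"] = "regional_validation.csv"
            _done("regional_validation", r=rv.r, years=rv.years)
        except Exception as e:
            _fail("regional_validation", e)

    manifest["outputs"]["rejections"] = "rejections.csv"
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
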