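"""Class-imbalance-aware learners whose averaged score estimates membership
in the relative phenological niche.

Two members handle the 1:12 presence/pseudoabsence imbalance differently: a
balanced random forest draws, for every tree, a bootstrap of equal numbers of
presences and pseudoabsences; boosted regression trees instead down-weight
each pseudoabsence to ``pa_weight`` (1/12 by default, i.e. 8.3% of a
presence).  The ensemble score is the arithmetic mean of the two members'
scores, in [0, 1].
"""

from __future__ import annotations

import hashlib
import json
import pickle
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import lightgbm as lgb
import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureMatrix, correlation_prefilter


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of the two ensemble members.

    Defaults: a 2000-tree balanced forest, and boosted trees with interaction
    depth 3, learning rate 0.005, 66% bag fraction, 4 internal CV folds and
    at most 7500 trees.  ``fast()`` gives a reduced-compute profile with the
    learning rate raised and the tree budget cut proportionally, for tests
    and small synthetic studies.
    """

    rf_trees: int = 2000
    rf_balanced_sampsize: bool = True
    brt_tree_complexity: int = 3
    brt_learning_rate: float = 0.005
    brt_bag_fraction: float = 0.66
    brt_cv_folds: int = 4
    brt_max_trees: int = 7500
    brt_step_size: int = 50
    pa_weight: float = 1.0 / 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.pa_weight <= 1):
            raise ValueError("pa_weight must be in (0, 1]")
        for name in ("rf_trees", "brt_tree_complexity", "brt_learning_rate",
                     "brt_bag_fraction", "brt_cv_folds", "brt_max_trees",
                     "brt_step_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def fast(cls, **overrides) -> "TrainConfig":
        base = dict(rf_trees=400, brt_learning_rate=0.02, brt_max_trees=1200,
                    brt_step_size=40)
        base.update(overrides)
        return cls(**base)

    def config_hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


class BalancedRandomForest:
    """Random forest with a class-balanced bootstrap per tree.

    Each tree trains on n1 presences and n1 pseudoabsences drawn with
    replacement within class (n1 = number of presences); the score is the
    fraction of trees voting presence.
    """

    def __init__(self, n_trees: int = 2000, max_features: str = "sqrt", seed: int = 0):
        self.n_trees = n_trees
        self.max_features = max_features
        self.seed = seed
        self.trees_: list[DecisionTreeClassifier] = []
        self.feature_names_: list[str] | None = None

    def fit(self, X, y) -> "BalancedRandomForest":
        if isinstance(X, pd.DataFrame):
            self.feature_names_ = list(X.columns)
            X = X.to_numpy()
        X = np.asarray(X, np.float32)
        y = np.asarray(y)
        pos = np.nonzero(y == 1)[0]
        neg = np.nonzero(y == 0)[0]
        if len(pos) == 0 or len(neg) == 0:
            raise ValueError("both classes must be present")
        n1 = len(pos)
        rng = np.random.default_rng(self.seed)
        tree_seeds = rng.integers(0, 2**31 - 1, size=self.n_trees)
        self.trees_ = []
        for s in tree_seeds:
            r = np.random.default_rng(s)
            idx = np.concatenate(
                [pos[r.integers(0, len(pos), n1)], neg[r.integers(0, len(neg), n1)]]
            )
            tree = DecisionTreeClassifier(
                max_features=self.max_features, random_state=int(s % (2**31))
            )
            tree.fit(X[idx], y[idx])
            self.trees_.append(tree)
        return self

    def predict_proba(self, X) -> np.ndarray:
        if not self.trees_:
            raise RuntimeError("forest not fitted")
        if isinstance(X, pd.DataFrame):
            if self.feature_names_:
                X = X[self.feature_names_]
            X = X.to_numpy()
        X = np.asarray(X, np.float32)
        votes = np.zeros(len(X))
        for tree in self.trees_:
            votes += tree.predict(X)
        return votes / len(self.trees_)


@dataclass
class WeightedBRT:
    """Fitted boosted-trees member with its CV-selected tree count."""

    booster: lgb.Booster
    selected_trees: int
    feature_names: list[str]
    cv_deviance: list[float] = field(default_factory=list, repr=False)

    def predict_proba(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.feature_names].to_numpy()
        return self.booster.predict(
            np.asarray(X, float), num_iteration=self.selected_trees
        )


def _lgb_params(cfg: TrainConfig, seed: int) -> dict:
    return {
        "objective": "binary",
        "learning_rate": cfg.brt_learning_rate,
        "max_depth": cfg.brt_tree_complexity,
        "num_leaves": 2**cfg.brt_tree_complexity,
        "bagging_fraction": cfg.brt_bag_fraction,
        "bagging_freq": 1,
        "feature_fraction": 1.0,
        "min_child_samples": 10,
        "metric": "binary_logloss",
        "verbosity": -1,
        "num_threads": 1,
        "deterministic": True,
        "force_row_wise": True,
        "seed": seed,
    }


def train_weighted_brt(
    fm: FeatureMatrix, cfg: TrainConfig, feature_names: Sequence[str] | None = None
) -> WeightedBRT:
    """Fit weighted boosted trees with CV-selected tree count.

    Pseudoabsences carry weight ``cfg.pa_weight`` relative to presences.  The
    tree count is chosen by minimising the mean weighted binomial deviance
    over ``brt_cv_folds`` stratified folds, with growth stopped once the
    deviance has not improved for ``brt_step_size`` consecutive trees.
    """
    names = list(feature_names) if feature_names is not None else fm.feature_names
    X = fm.X[names].to_numpy(float)
    y = fm.labels
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    w = np.where(y == 1, 1.0, cfg.pa_weight)
    params = _lgb_params(cfg, cfg.seed)
    dset = lgb.Dataset(X, label=y, weight=w, params=params, free_raw_data=False)
    skf = StratifiedKFold(n_splits=cfg.brt_cv_folds, shuffle=True, random_state=cfg.seed)
    folds = list(skf.split(X, y))
    cv = lgb.cv(
        params,
        dset,
        num_boost_round=cfg.brt_max_trees,
        folds=folds,
        callbacks=[lgb.early_stopping(stopping_rounds=cfg.brt_step_size, verbose=False)],
    )
    curve = list(cv["valid binary_logloss-mean"])
    selected = int(np.argmin(curve)) + 1
    if selected >= cfg.brt_max_trees:
        warnings.warn(
            "boosted trees hit the tree cap; consider a smaller learning rate "
            "or a larger brt_max_trees",
            stacklevel=2,
        )
    booster = lgb.train(params, dset, num_boost_round=selected)
    return WeightedBRT(booster, selected, names, cv_deviance=curve)


def train_balanced_forest(
    fm: FeatureMatrix, cfg: TrainConfig, feature_names: Sequence[str] | None = None
) -> BalancedRandomForest:
    names = list(feature_names) if feature_names is not None else fm.feature_names
    forest = BalancedRandomForest(n_trees=cfg.rf_trees, seed=cfg.seed)
    forest.fit(fm.X[names], fm.labels)
    return forest


@dataclass
class EnsembleModel:
    """Balanced forest + weighted boosted trees; score = mean of the two."""

    forest: BalancedRandomForest
    brt: WeightedBRT
    kept_features: list[str]
    train_meta: dict = field(default_factory=dict)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return predict_scores(self, X)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "wb") as fh:
            pickle.dump(self, fh)
        manifest = {
            "format_version": 1,
            "kept_features": self.kept_features,
            "train_meta": self.train_meta,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "EnsembleModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, cls):
            raise TypeError(f"{path} does not contain an EnsembleModel")
        return model


def train_ensemble(fm: FeatureMatrix, cfg: TrainConfig, corr_cutoff: float = 0.8) -> EnsembleModel:
    """Correlation pre-filter, then fit both members on the surviving features."""
    kept, dropped = correlation_prefilter(fm.X, cutoff=corr_cutoff)
    forest = train_balanced_forest(fm, cfg, kept)
    brt = train_weighted_brt(fm, cfg, kept)
    years = sorted(set(pd.DatetimeIndex(fm.meta["date"]).year))
    return EnsembleModel(
        forest,
        brt,
        kept,
        train_meta={
            "years": [int(y) for y in years],
            "seed": cfg.seed,
            "config_hash": cfg.config_hash(),
            "dropped_features": dropped,
            "n_presences": int((fm.labels == 1).sum()),
            "n_pseudoabsences": int((fm.labels == 0).sum()),
        },
    )


def predict_scores(model, X: pd.DataFrame) -> np.ndarray:
    """Score rows with a forest, a BRT, or the ensemble (mean of members)."""
    if isinstance(model, EnsembleModel):
        missing = [c for c in model.kept_features if c not in X.columns]
        if missing:
            raise ValueError(f"input lacks model features: {missing}")
        Xs = X[model.kept_features]
        return 0.5 * (model.forest.predict_proba(Xs) + model.brt.predict_proba(Xs))
    if isinstance(model, WeightedBRT):
        missing = [c for c in model.feature_names if c not in X.columns]
        if missing:
            raise ValueError(f"input lacks model features: {missing}")
        return model.predict_proba(X)
    if isinstance(model, BalancedRandomForest):
        if model.feature_names_:
            missing = [c for c in model.feature_names_ if c not in X.columns]
            if missing:
                raise ValueError(f"input lacks model features: {missing}")
        return model.predict_proba(X)
    raise TypeError(f"unsupported model type {type(model).__name__}")
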