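"""Random-forest permutation ranking of vegetation indices per growth stage.

The forest is a ranker, not a yield model: at each flight a random-forest
regressor of yield on all VIs is tuned by randomized-search cross-validation
(100 candidate hyperparameter sets, 5-fold CV, R^2 scoring, bootstrap
sampling), refit on all rows, and the VIs are ranked by permutation
importance — the mean drop in the model's R^2 when one column is shuffled,
over seeded repeats.  The top-ranked VI is then handed to a simple linear
yield model whose R^2/MAPE are reported alongside the ranking.

The tuned hyperparameters are the number of trees, the minimum samples to
split an internal node, the minimum samples per leaf, and the number of
features considered per split (all features or their square root).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.model_selection import KFold, RandomizedSearchCV

from .vi_registry import VIMatrix
from .yield_model import RegressionFit, fit_simple_lm

__all__ = ["RFTuningSpec", "TunedForest", "RFResult", "tune_forest",
           "permutation_ranking", "rank_per_stage"]


@dataclass(frozen=True)
class RFTuningSpec:
    """Randomized-search protocol for the forest ranker.

    The search space covers trees in [100, 1000], min-split in [2, 10],
    min-leaf in [1, 5] and max_features in {all, sqrt}; bootstrap sampling
    is always on.  ``n_candidates`` hyperparameter sets are drawn and scored
    by ``cv_folds``-fold cross-validated R^2.
    """

    n_candidates: int = 100
    cv_folds: int = 5
    n_trees: tuple[int, int] = (100, 1000)
    min_samples_split: tuple[int, int] = (2, 10)
    min_samples_leaf: tuple[int, int] = (1, 5)
    max_features: tuple = (1.0, "sqrt")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_candidates < 1:
            raise ValueError("n_candidates must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")

    def parameter_space(self) -> dict:
        from scipy.stats import randint

        return {
            "n_estimators": randint(self.n_trees[0], self.n_trees[1] + 1),
            "min_samples_split": randint(self.min_samples_split[0],
                                         self.min_samples_split[1] + 1),
            "min_samples_leaf": randint(self.min_samples_leaf[0],
                                        self.min_samples_leaf[1] + 1),
            "max_features": list(self.max_features),
        }

    def contains(self, params: dict) -> bool:
        return (self.n_trees[0] <= params["n_estimators"] <= self.n_trees[1]
                and self.min_samples_split[0] <= params["min_samples_split"]
                <= self.min_samples_split[1]
                and self.min_samples_leaf[0] <= params["min_samples_leaf"]
                <= self.min_samples_leaf[1]
                and params["max_features"] in self.max_features)


@dataclass
class TunedForest:
    model: RandomForestRegressor
    params: dict
    cv_score: float
    feature_names: tuple[str, ...]
    fitted: bool = True


@dataclass
class RFResult:
    """Permutation-importance ranking of VIs at one flight."""

    year: int
    stage: str
    params: dict
    ranking: pd.DataFrame  # vi_name, importance_mean, importance_sd (desc.)
    top_vi: str = field(init=False)

    def __post_init__(self) -> None:
        self.top_vi = str(self.ranking["vi_name"].iloc[0])


def _complete_rows(X: pd.DataFrame, y: Sequence[float]) -> tuple[pd.DataFrame, np.ndarray]:
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(X.to_numpy(dtype=float)).all(axis=1) & np.isfinite(y)
    return X.loc[keep], y[keep]


def tune_forest(X: pd.DataFrame, y: Sequence[float], spec: RFTuningSpec) -> TunedForest:
    """Randomized-search CV over the spec's space; refit best on all rows.

    Rows containing any missing value are dropped first; at least
    ``cv_folds`` complete rows are required.  Fully reproducible given
    ``spec.seed``.
    """
    X, y = _complete_rows(X, np.asarray(y, dtype=float))
    if len(X) < spec.cv_folds:
        raise ValueError(
            f"{len(X)} complete rows but {spec.cv_folds}-fold CV requested")
    base = RandomForestRegressor(bootstrap=True, random_state=spec.seed)
    search = RandomizedSearchCV(
        base, spec.parameter_space(), n_iter=spec.n_candidates,
        cv=KFold(spec.cv_folds, shuffle=True, random_state=spec.seed),
        scoring="r2", random_state=spec.seed, refit=True, n_jobs=1,
        error_score="raise")
    with warnings.catch_warnings():
        # tiny folds can yield undefined fold-level R^2; the mean still ranks
        warnings.simplefilter("ignore")
        search.fit(X.to_numpy(dtype=float), y)
    return TunedForest(model=search.best_estimator_, params=dict(search.best_params_),
                       cv_score=float(search.best_score_),
                       feature_names=tuple(X.columns))


def permutation_ranking(forest: TunedForest, X: pd.DataFrame, y: Sequence[float],
                        n_repeats: int = 10, seed: int = 0, *,
                        year: int = 0, stage: str = "") -> RFResult:
    """Rank columns by mean permutation importance (R^2 drop), descending.

    Ties break alphabetically for determinism.  The forest must be fitted
    and ``X`` must carry the columns it was fitted on.
    """
    if not getattr(forest, "fitted", False):
        raise ValueError("forest is not fitted; run tune_forest first")
    if tuple(X.columns) != forest.feature_names:
        raise ValueError("X columns differ from the columns the forest was fitted on")
    X, y = _complete_rows(X, np.asarray(y, dtype=float))
    result = permutation_importance(
        forest.model, X.to_numpy(dtype=float), y, scoring="r2",
        n_repeats=n_repeats, random_state=seed, n_jobs=1)
    ranking = pd.DataFrame({
        "vi_name": list(X.columns),
        "importance_mean": result.importances_mean,
        "importance_sd": result.importances_std,
    }).sort_values(["importance_mean", "vi_name"],
                   ascending=[False, True]).reset_index(drop=True)
    return RFResult(year=year, stage=stage, params=forest.params, ranking=ranking)


def rank_per_stage(panels: Iterable[VIMatrix], yields: pd.DataFrame,
                   spec: RFTuningSpec, n_repeats: int = 10
                   ) -> list[tuple[RFResult, RegressionFit]]:
    """Per flight: tuned-forest permutation ranking + simple-LM fit of the top VI.

    Flights with fewer complete rows than CV folds are skipped with a
    warning.  Returns one (RFResult, RegressionFit) pair per ranked flight.
    """
    panels = list(panels)
    if not panels:
        raise ValueError("no flights supplied")
    out: list[tuple[RFResult, RegressionFit]] = []
    for panel in panels:
        year_yields = yields.loc[yields["year"] == panel.year].set_index("plot_id")
        shared = panel.values.index.intersection(year_yields.index)
        X = panel.values.loc[shared]
        y = year_yields.loc[shared, "yield_mg_ha"].to_numpy(dtype=float)
        X_complete, y_complete = _complete_rows(X, y)
        if len(X_complete) < spec.cv_folds:
            warnings.warn(
                f"year {panel.year} {panel.flight.stage}: {len(X_complete)} complete "
                f"rows < {spec.cv_folds} folds; flight skipped", stacklevel=2)
            continue
        forest = tune_forest(X_complete, y_complete, spec)
        ranking = permutation_ranking(forest, X_complete, y_complete,
                                      n_repeats=n_repeats, seed=spec.seed,
                                      year=panel.year, stage=panel.flight.stage)
        companion = fit_simple_lm(
            X_complete[ranking.top_vi].to_numpy(dtype=float), y_complete,
            vi_name=ranking.top_vi, year=panel.year, stage=panel.flight.stage)
        out.append((ranking, companion))
    return out
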