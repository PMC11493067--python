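"""Grid-search-tuned random forest regression with MDI importance aggregation.

Hyperparameters (n_estimators, max_depth, min_samples_split,
min_samples_leaf and the cost-complexity pruning strength ccp_alpha) are
tuned by k-fold cross-validated MAPE over a cartesian grid; ties break
toward the smaller forest, then the shallower one.  MDI (mean decrease in
impurity) importances of the 8 codes belonging to one climate variable are
summed into a single per-variable row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold, ParameterGrid

from .features import FEATURE_ORDER, VARIABLE_OF_FEATURE
from .metrics import gamma_deviance, mape

#: aggregated-importance row order (economic block then climate block)
IMPORTANCE_ROWS = ["SownArea", "dt", "PrimInd", "MechPower", "tas", "pr", "hw_freq", "cw_freq"]

DEFAULT_PARAM_GRID = {
    "n_estimators": [100, 200, 400],
    "max_depth": [4, 8, 16, None],
    "min_samples_split": [2, 5, 10],
    "min_samples_leaf": [1, 2, 5],
    "ccp_alpha": [0.0, 1e-4, 1e-3],
}


@dataclass
class RFConfig:
    """Search grid and protocol shared by the primary model and benchmarks."""

    param_grid: dict = field(default_factory=lambda: dict(DEFAULT_PARAM_GRID))
    cv_folds: int = 5
    split_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must be in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


def _depth_key(d):
    return np.inf if d is None else d


class TunedForestRegressor(BaseEstimator, RegressorMixin):
    """RandomForestRegressor wrapped in a cross-validated grid search.

    Parameters
    ----------
    param_grid : dict
        Cartesian hyperparameter grid (RandomForestRegressor keywords).
    cv : int
        Number of folds for cross-validated MAPE.
    random_state : int
        Seeds the fold shuffling and every forest.

    Attributes
    ----------
    best_params_ : selected hyperparameter combination.
    cv_results_ : DataFrame with per-combination mean CV MAPE and Gamma
        deviance (the grid-search surface).
    best_estimator_ : refitted RandomForestRegressor.
    feature_importances_ : MDI importances in training-column order.
    """

    def __init__(self, param_grid=None, cv=5, random_state=0):
        self.param_grid = param_grid
        self.cv = cv
        self.random_state = random_state

    def fit(self, X, y):
        Xa, ya, names = _as_matrix(X, y)
        pg = DEFAULT_PARAM_GRID if self.param_grid is None else self.param_grid
        grid = list(ParameterGrid(pg))
        if not grid or all(len(g) == 0 for g in grid):
            raise ValueError("empty hyperparameter grid")
        n = len(ya)
        folds = list(
            KFold(n_splits=self.cv, shuffle=True, random_state=self.random_state).split(Xa)
        )
        for _, val in folds:
            if len(val) == 0:
                raise ValueError("fold with empty validation slice")
        records = []
        for params in grid:
            fold_mape, fold_dev = [], []
            for tr, val in folds:
                rf = RandomForestRegressor(random_state=self.random_state, **params)
                rf.fit(Xa[tr], ya[tr])
                pred = rf.predict(Xa[val])
                fold_mape.append(mape(ya[val], pred))
                fold_dev.append(gamma_deviance(ya[val], np.maximum(pred, 1e-12)))
            records.append(
                {**params, "cv_mape": float(np.mean(fold_mape)), "cv_gamma_deviance": float(np.mean(fold_dev))}
            )
        table = pd.DataFrame(records)
        order = sorted(
            range(len(grid)),
            key=lambda i: (
                table.loc[i, "cv_mape"],
                grid[i].get("n_estimators", 0),
                _depth_key(grid[i].get("max_depth")),
            ),
        )
        best = order[0]
        self.cv_results_ = table
        self.best_params_ = dict(grid[best])
        self.best_cv_mape_ = float(table.loc[best, "cv_mape"])
        self.best_estimator_ = RandomForestRegressor(
            random_state=self.random_state, **self.best_params_
        ).fit(Xa, ya)
        self.feature_names_in_ = names
        self.feature_importances_ = self.best_estimator_.feature_importances_
        self.n_features_in_ = Xa.shape[1]
        return self

    def predict(self, X):
        Xa, _, _ = _as_matrix(X, None, expected=self.feature_names_in_)
        return self.best_estimator_.predict(Xa)


def _as_matrix(X, y, expected=None):
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        if expected is not None:
            if list(expected) != names:
                X = X[list(expected)]
                names = list(expected)
        Xa = X.values.astype(float)
    else:
        Xa = np.asarray(X, dtype=float)
        names = list(expected) if expected is not None else [f"x{i}" for i in range(Xa.shape[1])]
    ya = None if y is None else np.asarray(y, dtype=float)
    return Xa, ya, names


def aggregate_importance(model: TunedForestRegressor) -> pd.Series:
    """Sum the 8 code importances of each climate variable into one row.

    Economic features pass through; the result preserves the total (sums to
    the same value as the raw MDI vector, i.e. 1 within float tolerance).
    """
    names = getattr(model, "feature_names_in_", None)
    if names is None or any(n not in VARIABLE_OF_FEATURE and n not in IMPORTANCE_ROWS for n in names):
        unknown = [n for n in (names or []) if n not in VARIABLE_OF_FEATURE]
        raise ValueError(f"cannot map features to variables: {unknown or 'no feature names'}")
    agg = {row: 0.0 for row in IMPORTANCE_ROWS}
    for name, imp in zip(names, model.feature_importances_):
        agg[VARIABLE_OF_FEATURE.get(name, name)] += float(imp)
    return pd.Series(agg, name="importance").reindex(IMPORTANCE_ROWS)


def fit_primary_rf(train_cases: pd.DataFrame, cfg: RFConfig) -> TunedForestRegressor:
    """Fit the 36-feature ConvAE-RF regressor on assembled cases."""
    model = TunedForestRegressor(
        param_grid=cfg.param_grid, cv=cfg.cv_folds, random_state=cfg.seed
    )
    return model.fit(train_cases[FEATURE_ORDER], train_cases["production_t"])
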