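"""Benchmark models: B1 (log-log FGLS regression) and B2 (spatial-mean RF).

B1 treats grain production as an economic activity: ln(production) is
regressed on the logs of the positive economic inputs, the time dummy, and
province-mean climate levels, with feasible generalized least squares
correcting for heteroskedasticity (log squared OLS residuals modeled on the
fitted values, weights = inverse fitted variance, one weighted refit).

B2 is the spatial ablation: the same tuned-forest protocol as the primary
model but with each climate variable reduced to its province spatial mean
(8 features instead of 36).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin

from .config import CLIMATE_VARS
from .features import ECON_FEATURES
from .regression import RFConfig, TunedForestRegressor

#: B2-RF design columns: normalized econ trio + dt + spatial-mean climate
BENCH_FEATURES = list(ECON_FEATURES) + list(CLIMATE_VARS)
#: B1-FGLS design columns: raw positive econ levels + dt + climate means
B1_FEATURES = ["sown_area_kha", "prim_ind_k", "mech_power_gw", "dt"] + list(CLIMATE_VARS)


class DesignError(ValueError):
    """Rank-deficient or otherwise unusable regression design."""


class FGLSRegressor(BaseEstimator, RegressorMixin):
    """Two-step FGLS on a log-log production design.

    fit expects a DataFrame carrying the raw positive economic levels
    (sown_area_kha, prim_ind_k, mech_power_gw), the time dummy dt, and the
    spatial-mean climate columns (tas, pr, hw_freq, cw_freq).  The logs are
    taken of the target and the economic trio only; climate enters in levels
    because temperatures and frequencies may be <= 0.  Predictions are
    exponentiated back to tons.

    Attributes
    ----------
    coef_ : fitted FGLS coefficient vector (const first).
    ols_coef_ : first-stage OLS coefficients.
    weights_ : strictly positive FGLS case weights.
    """

    LOG_COLS = ("sown_area_kha", "prim_ind_k", "mech_power_gw")
    LEVEL_COLS = ("dt", "tas", "pr", "hw_freq", "cw_freq")

    def __init__(self):
        pass

    def _design(self, X: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.LOG_COLS + self.LEVEL_COLS if c not in X.columns]
        if missing:
            raise DesignError(f"missing design columns: {missing}")
        logs = X[list(self.LOG_COLS)].values.astype(float)
        if np.any(logs <= 0):
            raise DesignError("economic inputs must be strictly positive for the log-log design")
        mat = np.column_stack(
            [np.ones(len(X)), np.log(logs), X[list(self.LEVEL_COLS)].values.astype(float)]
        )
        return mat

    def _check_rank(self, design: np.ndarray) -> None:
        names = ["const"] + [f"ln_{c}" for c in self.LOG_COLS] + list(self.LEVEL_COLS)
        rank = np.linalg.matrix_rank(design)
        if rank < design.shape[1]:
            _, s, vt = np.linalg.svd(design - design.mean(0), full_matrices=False)
            null = vt[-1]
            involved = [n for n, v in zip(names, null) if abs(v) > 0.1]
            raise DesignError(f"rank-deficient design; collinear columns: {involved}")

    def fit(self, X: pd.DataFrame, y):
        y = np.asarray(y, dtype=float)
        if np.any(y <= 0):
            raise DesignError("target must be strictly positive (log-log model)")
        design = self._design(X)
        self._check_rank(design)
        ols = sm.OLS(np.log(y), design).fit()
        self.ols_coef_ = ols.params.copy()
        # variance model: log squared residuals on the fitted values
        log_r2 = np.log(np.maximum(ols.resid**2, 1e-300))
        aux = sm.OLS(log_r2, sm.add_constant(ols.fittedvalues)).fit()
        var_hat = np.exp(aux.fittedvalues)
        self.weights_ = 1.0 / np.maximum(var_hat, 1e-300)
        wls = sm.WLS(np.log(y), design, weights=self.weights_).fit()
        self.coef_ = wls.params.copy()
        self.results_ = wls
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return np.exp(self._design(X) @ self.coef_)


def fit_fgls_loglog(cases8: pd.DataFrame, target="production_t") -> FGLSRegressor:
    """B1-FGLS on the spatial-mean case table (raw economic levels)."""
    return FGLSRegressor().fit(cases8[B1_FEATURES], cases8[target])


def fit_b2rf_ablation(train_cases8: pd.DataFrame, cfg: RFConfig) -> TunedForestRegressor:
    """B2-RF: identical search grid, folds and seed, spatial-mean features."""
    model = TunedForestRegressor(
        param_grid=cfg.param_grid, cv=cfg.cv_folds, random_state=cfg.seed
    )
    return model.fit(train_cases8[BENCH_FEATURES], train_cases8["production_t"])
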