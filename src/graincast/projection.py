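"""Scenario projection utilities: ensemble aggregation, trend diagnostics.

The projection driver itself (which chains detector -> encoders -> forest
with economics frozen at the last observed year) lives in
:mod:`graincast.pipeline`; this module holds the analysis primitives it and
the reporting layer share.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import xarray as xr

from .grids import AlignmentError


class DegenerateRegressionError(ValueError):
    pass


class InsufficientDataError(ValueError):
    pass


def smooth_4yr(series: pd.Series, window: int = 4) -> pd.Series:
    """Non-overlapping block means of an annual series (2021-2024, ...).

    The index must be consecutive calendar years; a partial trailing block is
    dropped with a warning.
    """
    years = np.asarray(series.index, dtype=int)
    if len(years) == 0 or np.any(np.diff(years) != 1):
        raise InsufficientDataError("series must cover consecutive years")
    n_full = len(years) // window
    if n_full * window != len(years):
        warnings.warn(
            f"dropping partial trailing {len(years) - n_full * window}-year group",
            UserWarning,
        )
    vals = series.values[: n_full * window].reshape(n_full, window).mean(axis=1)
    return pd.Series(vals, index=years[::window][:n_full], name=series.name)


def ensemble_median_iqr(members: pd.DataFrame) -> pd.DataFrame:
    """Across-member median and interquartile band per year.

    ``members``: index = year, one column per GCM.
    """
    if members.shape[1] < 2:
        raise InsufficientDataError("need >= 2 ensemble members")
    return pd.DataFrame(
        {
            "median": members.median(axis=1),
            "q25": members.quantile(0.25, axis=1),
            "q75": members.quantile(0.75, axis=1),
        }
    )


def rank_and_split_gcms(hw_projections: dict[str, xr.DataArray]) -> pd.DataFrame:
    """Rank members by summed projected HW frequency and split into halves.

    The ranking score is the plain sum of projected heatwave frequency over
    all cells and years.  Members in the top half are labeled "higher", the
    rest "lower"; with an odd count the "higher" half gets the extra member.
    Ties break deterministically by member id.
    """
    grids = list(hw_projections.values())
    ref = grids[0]
    for g in grids[1:]:
        if g.shape != ref.shape or not np.array_equal(g["year"].values, ref["year"].values):
            raise AlignmentError("ensemble members must share grid and year range")
    scores = {gcm: float(da.sum()) for gcm, da in hw_projections.items()}
    order = sorted(scores, key=lambda g: (-scores[g], g))
    n_high = (len(order) + 1) // 2
    rows = [
        {"gcm": g, "score": scores[g], "membership": "higher" if i < n_high else "lower"}
        for i, g in enumerate(order)
    ]
    return pd.DataFrame(rows).set_index("gcm")


def hw_cw_tradeoff(hw, cw) -> tuple[float, float]:
    """Least-squares slopes (HW on CW, CW on HW) over pooled cell-years."""
    hw = np.asarray(hw, dtype=float).ravel()
    cw = np.asarray(cw, dtype=float).ravel()
    if hw.shape != cw.shape:
        raise AlignmentError("hw and cw samples must pair up")
    if np.var(cw) == 0 or np.var(hw) == 0:
        raise DegenerateRegressionError("zero variance in a regressor")
    slope_hw_on_cw = float(np.polyfit(cw, hw, 1)[0])
    slope_cw_on_hw = float(np.polyfit(hw, cw, 1)[0])
    return slope_hw_on_cw, slope_cw_on_hw


def tas_anomaly_regression(
    tas_anomaly, production_anomaly, mad_threshold: float = 3.0
) -> dict:
    """Production-anomaly vs temperature-anomaly slope with outlier handling.

    One (anomaly, production-anomaly) point per GCM-scenario, period-averaged
    by the caller.  An initial least-squares line is fitted; points whose
    residuals exceed ``mad_threshold`` robust (MAD-based) standard deviations
    are dropped once and the line refitted.

    Returns {"slope", "intercept", "n_used", "n_dropped"} with slope in
    target units per degC.
    """
    x = np.asarray(tas_anomaly, dtype=float).ravel()
    y = np.asarray(production_anomaly, dtype=float).ravel()
    if x.shape != y.shape:
        raise AlignmentError("anomaly vectors must pair up")
    if x.size < 3:
        raise InsufficientDataError("need >= 3 points")
    if np.var(x) == 0:
        raise DegenerateRegressionError("zero variance in tas anomaly")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    mad = np.median(np.abs(resid - np.median(resid)))
    keep = np.ones_like(x, dtype=bool)
    if mad > 0:
        robust_sd = 1.4826 * mad
        keep = np.abs(resid - np.median(resid)) <= mad_threshold * robust_sd
    if keep.sum() < 3:
        raise InsufficientDataError("fewer than 3 points after outlier removal")
    slope, intercept = np.polyfit(x[keep], y[keep], 1)
    return {
        "slope": float(slope),
        "intercept": float(intercept),
        "n_used": int(keep.sum()),
        "n_dropped": int((~keep).sum()),
    }


def temporal_pearson_map(freq: xr.DataArray) -> xr.DataArray:
    """Per-cell Pearson correlation of annual frequency with the year.

    Cells with zero temporal variance get NaN (undefined flag).
    """
    years = freq["year"].values.astype(float)
    if len(years) < 3:
        raise InsufficientDataError("need >= 3 years per cell")
    vals = freq.values.astype(float)
    yc = years - years.mean()
    vc = vals - vals.mean(axis=0)
    cov = np.tensordot(yc, vc, axes=(0, 0)) / len(years)
    sy = yc.std()
    sv = vals.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / (sy * sv)
    r[sv == 0] = np.nan
    return xr.DataArray(
        r,
        dims=("lat", "lon"),
        coords={"lat": freq["lat"].values, "lon": freq["lon"].values},
        name="pearson_r",
        attrs={"description": "temporal Pearson correlation of frequency with year"},
    )


def baseline_production(econ: pd.DataFrame, years: tuple[int, int] = (2001, 2020)) -> float:
    """Mean observed region-total annual production over a reference window."""
    sub = econ[(econ["year"] >= years[0]) & (econ["year"] <= years[1])]
    if sub.empty:
        raise InsufficientDataError(f"no observations in {years}")
    return float(sub.groupby("year")["production_t"].sum().mean())
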