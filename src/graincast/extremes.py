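"""Percentile-threshold extreme temperature event (ETE) climatology.

A heatwave (HW) is >= ``min_run`` consecutive days with daily maximum
temperature strictly above the cell's 90th-percentile threshold; a coldwave
(CW) is >= ``min_run`` consecutive days with daily minimum temperature
strictly below the 10th-percentile threshold.  Thresholds are empirical
quantiles of all base-period days pooled per cell (linear interpolation
between order statistics).  Events never span calendar years: a run is
counted in the year containing it, and a run truncated by Dec 31 counts only
if its within-year length still reaches ``min_run``.
"""

from __future__ import annotations

import numpy as np
import xarray as xr
from sklearn.base import BaseEstimator

from .config import DAYS_PER_YEAR, ConfigurationError
from .grids import AlignmentError, annual_grid, check_same_grid, interp_to_axes

HW, CW = "HW", "CW"
DEFAULT_PERCENTILE = {HW: 0.90, CW: 0.10}
DEFAULT_MIN_RUN = 3


class InsufficientDataError(ValueError):
    """Input does not cover the configured base period or year span."""


def compute_threshold_grid(
    base: xr.DataArray,
    percentile: float | None = None,
    kind: str = HW,
    base_period: tuple[int, int] | None = None,
) -> xr.DataArray:
    """Per-cell qualifying temperature from pooled base-period daily values.

    Parameters
    ----------
    base
        Daily temperature grid covering (at least) the base period.
    percentile
        Quantile level in (0, 1); defaults to 0.90 for HW and 0.10 for CW.
    kind
        "HW" (thresholds from tasmax) or "CW" (from tasmin).
    base_period
        Inclusive year range to pool; defaults to all years present.
    """
    if kind not in (HW, CW):
        raise ConfigurationError(f"kind must be HW or CW, got {kind!r}")
    if percentile is None:
        percentile = DEFAULT_PERCENTILE[kind]
    if not 0.0 < percentile < 1.0:
        raise ConfigurationError("percentile must lie in (0, 1)")
    years = base["year"].values
    if base_period is not None:
        y0, y1 = base_period
        present = np.unique(years)
        wanted = np.arange(y0, y1 + 1)
        missing = np.setdiff1d(wanted, present)
        if missing.size:
            raise InsufficientDataError(
                f"base period {base_period} not covered; missing years {missing.tolist()}"
            )
        base = base.isel(time=(years >= y0) & (years <= y1))
    else:
        y0, y1 = int(years.min()), int(years.max())
    q = np.quantile(base.values, percentile, axis=0, method="linear")
    out = xr.DataArray(
        q,
        dims=("lat", "lon"),
        coords={"lat": base["lat"].values, "lon": base["lon"].values},
        name=f"q_{kind.lower()}",
        attrs={
            "kind": kind,
            "percentile": float(percentile),
            "base_period": (int(y0), int(y1)),
            "quantile_interpolation": "linear",
        },
    )
    return out


def label_exceedance_days(
    daily: xr.DataArray, thresholds: xr.DataArray, kind: str
) -> xr.DataArray:
    """Boolean day grid: strict exceedance above (HW) / below (CW) threshold."""
    check_same_grid(daily, thresholds)
    if kind == HW:
        flags = daily.values > thresholds.values[None, :, :]
    elif kind == CW:
        flags = daily.values < thresholds.values[None, :, :]
    else:
        raise ConfigurationError(f"kind must be HW or CW, got {kind!r}")
    out = daily.copy(data=flags)
    out.name = f"{kind.lower()}_day"
    out.attrs = {"kind": kind}
    return out


def count_events(flags: np.ndarray, min_run: int = DEFAULT_MIN_RUN) -> int:
    """Number of maximal runs of consecutive True values with length >= min_run.

    ``flags`` is a single cell-year boolean series.
    """
    counts = count_events_columns(np.asarray(flags, bool).reshape(-1, 1), min_run)
    return int(counts[0])


def count_events_columns(flags: np.ndarray, min_run: int = DEFAULT_MIN_RUN) -> np.ndarray:
    """Vectorized run counting over (time, n_series) boolean columns."""
    if min_run < 1:
        raise ConfigurationError("min_run must be >= 1")
    f = np.asarray(flags, bool)
    t, n = f.shape
    padded = np.zeros((n, t + 2), dtype=np.int8)
    padded[:, 1:-1] = f.T
    d = np.diff(padded, axis=1)
    scol, spos = np.nonzero(d == 1)
    ecol, epos = np.nonzero(d == -1)
    lengths = epos - spos  # starts/ends pair up in order within each column
    good = lengths >= min_run
    return np.bincount(scol[good], minlength=n)


def count_event_days_columns(flags: np.ndarray, min_run: int = DEFAULT_MIN_RUN) -> np.ndarray:
    """Days belonging to qualifying runs, per (time, n_series) column.

    Unlike the event count, this quantity is monotone under uniform warming
    (with thresholds fixed): adding exceedance days can merge two qualifying
    runs into one — reducing the *count* — but never removes a day from a
    qualifying run.
    """
    if min_run < 1:
        raise ConfigurationError("min_run must be >= 1")
    f = np.asarray(flags, bool)
    t, n = f.shape
    padded = np.zeros((n, t + 2), dtype=np.int8)
    padded[:, 1:-1] = f.T
    d = np.diff(padded, axis=1)
    scol, spos = np.nonzero(d == 1)
    _, epos = np.nonzero(d == -1)
    lengths = epos - spos
    good = lengths >= min_run
    return np.bincount(scol[good], weights=lengths[good], minlength=n).astype(np.int64)


def annual_event_frequency_grid(
    daily: xr.DataArray,
    thresholds: xr.DataArray,
    kind: str,
    min_run: int = DEFAULT_MIN_RUN,
) -> xr.DataArray:
    """Events per cell-year; runs are truncated at calendar-year boundaries."""
    flags = label_exceedance_days(daily, thresholds, kind)
    years = flags["year"].values
    uniq, counts_per_year = np.unique(years, return_counts=True)
    if np.any(counts_per_year != DAYS_PER_YEAR):
        bad = uniq[counts_per_year != DAYS_PER_YEAR].tolist()
        raise InsufficientDataError(
            f"partial calendar years not allowed: {bad} "
            f"(need {DAYS_PER_YEAR} days per year)"
        )
    nlat, nlon = flags.sizes["lat"], flags.sizes["lon"]
    out = np.empty((len(uniq), nlat, nlon), dtype=np.int64)
    fvals = flags.values
    for i, y in enumerate(uniq):
        block = fvals[years == y].reshape(DAYS_PER_YEAR, nlat * nlon)
        out[i] = count_events_columns(block, min_run).reshape(nlat, nlon)
    return annual_grid(
        out,
        uniq,
        flags["lat"].values,
        flags["lon"].values,
        "hw_freq" if kind == HW else "cw_freq",
        event_kind=kind,
        min_run=int(min_run),
        units="year-1",
    )


def regrid_thresholds(
    thresholds: xr.DataArray, target_lat: np.ndarray, target_lon: np.ndarray
) -> xr.DataArray:
    """Bilinear downscaling of a threshold field onto finer target axes.

    Raises AlignmentError if any target node lies outside the source
    cell-center hull (no extrapolation).
    """
    out = interp_to_axes(thresholds, np.asarray(target_lat), np.asarray(target_lon))
    out.name = thresholds.name
    return out


class ExtremeEventDetector(BaseEstimator):
    """Percentile-threshold run-length event detector, estimator-style.

    ``fit`` learns per-cell thresholds from base-period daily data;
    ``transform`` turns any daily grid on the same (or a regridded) grid into
    an annual event-frequency grid.

    Parameters
    ----------
    kind : {"HW", "CW"}
    percentile : float or None
        Defaults to 0.90 (HW) / 0.10 (CW).
    min_run : int, default 3
    base_period : (int, int) or None
        Years pooled for the threshold; None pools everything passed to fit.
    """

    def __init__(self, kind=HW, percentile=None, min_run=DEFAULT_MIN_RUN, base_period=None):
        self.kind = kind
        self.percentile = percentile
        self.min_run = min_run
        self.base_period = base_period

    def fit(self, X: xr.DataArray, y=None):
        self.threshold_ = compute_threshold_grid(
            X, self.percentile, self.kind, self.base_period
        )
        return self

    def transform(self, X: xr.DataArray) -> xr.DataArray:
        if not hasattr(self, "threshold_"):
            raise AlignmentError("detector is not fitted")
        thr = self.threshold_
        if (
            thr.sizes["lat"] != X.sizes["lat"]
            or thr.sizes["lon"] != X.sizes["lon"]
            or not np.allclose(thr["lat"].values, X["lat"].values)
            or not np.allclose(thr["lon"].values, X["lon"].values)
        ):
            thr = regrid_thresholds(thr, X["lat"].values, X["lon"].values)
        return annual_event_frequency_grid(X, thr, self.kind, self.min_run)

    def fit_transform(self, X: xr.DataArray, y=None) -> xr.DataArray:
        return self.fit(X).transform(X)
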