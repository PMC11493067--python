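"""Event detection: thresholds, exceedance labeling, run counting, regridding."""

import numpy as np
import pytest
import xarray as xr

from graincast.config import DAYS_PER_YEAR, ConfigurationError
from graincast.extremes import (
    CW,
    HW,
    DEFAULT_PERCENTILE,
    ExtremeEventDetector,
    InsufficientDataError,
    annual_event_frequency_grid,
    compute_threshold_grid,
    count_event_days_columns,
    count_events,
    count_events_columns,
    label_exceedance_days,
    regrid_thresholds,
)
from graincast.grids import AlignmentError, daily_grid
from graincast.synth import gen_daily_temperature_grid


def _toy_daily(values, years, nlat=2, nlon=2):
    lat = np.array([30.0 + 0.5 * i for i in range(nlat)])
    lon = np.array([110.0 + 0.5 * j for j in range(nlon)])
    return daily_grid(values, years, lat, lon, "tasmax")


def rle_event_count(flags, min_run):
    """Independent oracle: explicit run-length encoding of a boolean series."""
    count = run = 0
    for f in flags:
        run = run + 1 if f else 0
        if f and run == min_run:
            count += 1
    return count


# --- thresholds -----------------------------------------------------------


def test_threshold_of_constant_series_is_constant():
    v = np.full((DAYS_PER_YEAR, 2, 2), 21.5)
    thr = compute_threshold_grid(_toy_daily(v, [1981]), kind=HW)
    np.testing.assert_allclose(thr.values, 21.5)


def test_threshold_matches_sorted_order_oracle():
    # one year of distinct values 1..365 in one cell: compare to the linear
    # interpolation between order statistics done by hand
    vals = np.arange(1, DAYS_PER_YEAR + 1, dtype=float)
    v = np.zeros((DAYS_PER_YEAR, 2, 2))
    v[:, 0, 0] = vals
    thr = compute_threshold_grid(_toy_daily(v, [1981]), percentile=0.90, kind=HW)
    srt = np.sort(vals)
    h = 0.90 * (len(srt) - 1)
    expected = srt[int(h)] + (h - int(h)) * (srt[int(h) + 1] - srt[int(h)])
    assert thr.values[0, 0] == pytest.approx(expected, abs=1e-12)


def test_default_percentiles():
    assert DEFAULT_PERCENTILE[HW] == 0.90
    assert DEFAULT_PERCENTILE[CW] == 0.10


def test_threshold_requires_full_base_period():
    v = np.zeros((DAYS_PER_YEAR, 2, 2))
    with pytest.raises(InsufficientDataError):
        compute_threshold_grid(_toy_daily(v, [1981]), kind=HW, base_period=(1981, 1990))


def test_threshold_calibration_on_base_data(tiny_cfg):
    """Fraction of base days strictly above q_hw is <= p-complement + one step."""
    tasmax = gen_daily_temperature_grid(tiny_cfg, "tasmax")
    det = ExtremeEventDetector(kind=HW, base_period=tiny_cfg.years_base).fit(tasmax)
    years = tasmax["year"].values
    base = tasmax.isel(time=(years >= 1981) & (years <= 1990))
    frac = (base.values > det.threshold_.values[None]).mean(axis=0)
    n_days = base.sizes["time"]
    assert frac.max() <= 0.10 + 1.0 / n_days


# --- exceedance labeling --------------------------------------------------


def test_equal_to_threshold_not_flagged():
    v = np.full((DAYS_PER_YEAR, 2, 2), 20.0)
    da = _toy_daily(v, [1990])
    thr = compute_threshold_grid(da, kind=HW).copy(data=np.full((2, 2), 20.0))
    flags = label_exceedance_days(da, thr, HW)
    assert not flags.values.any()


def test_above_threshold_all_flagged_and_cw_mirror():
    v = np.full((DAYS_PER_YEAR, 2, 2), 21.0)
    da = _toy_daily(v, [1990])
    thr = da.isel(time=0).drop_vars(["year", "doy", "time"]).copy(data=np.full((2, 2), 20.0))
    assert label_exceedance_days(da, thr, HW).values.all()
    assert not label_exceedance_days(da, thr, CW).values.any()


def test_flags_equal_elementwise_oracle():
    rng = np.random.default_rng(0)
    v = rng.normal(20, 5, size=(DAYS_PER_YEAR, 2, 2))
    da = _toy_daily(v, [1990])
    thr = da.isel(time=0).drop_vars(["year", "doy", "time"]).copy(
        data=rng.normal(20, 1, size=(2, 2))
    )
    flags = label_exceedance_days(da, thr, HW)
    np.testing.assert_array_equal(flags.values, v > thr.values[None])


def test_grid_mismatch_rejected():
    v = np.zeros((DAYS_PER_YEAR, 2, 2))
    da = _toy_daily(v, [1990])
    thr = xr.DataArray(
        np.zeros((3, 3)),
        dims=("lat", "lon"),
        coords={"lat": [30, 30.5, 31.0], "lon": [110, 110.5, 111.0]},
    )
    with pytest.raises(AlignmentError):
        label_exceedance_days(da, thr, HW)


# --- run counting ---------------------------------------------------------


@pytest.mark.parametrize(
    "flags,min_run,expected",
    [
        ([0, 1, 1, 1, 0, 1, 1, 0], 3, 1),
        ([1] * 365, 3, 1),
        ([0] * 10, 3, 0),
        ([1, 1, 1, 0, 1, 1, 1], 3, 2),
        ([1, 1], 3, 0),
        ([1], 1, 1),
    ],
)
def test_count_events_examples(flags, min_run, expected):
    assert count_events(np.array(flags, bool), min_run) == expected


def test_count_events_invalid_min_run():
    with pytest.raises(ConfigurationError):
        count_events(np.array([True]), 0)


def test_count_events_matches_rle_oracle_500_series():
    rng = np.random.default_rng(42)
    flags = rng.random((DAYS_PER_YEAR, 500)) < rng.uniform(0.02, 0.5, 500)
    counts = count_events_columns(flags, 3)
    for j in range(500):
        assert counts[j] == rle_event_count(flags[:, j], 3), f"series {j}"


# --- annual frequency grids ----------------------------------------------


def test_flag_free_year_counts_zero():
    v = np.full((2 * DAYS_PER_YEAR, 2, 2), 10.0)
    da = _toy_daily(v, [1990, 1991])
    thr = da.isel(time=0).drop_vars(["year", "doy", "time"]).copy(data=np.full((2, 2), 20.0))
    freq = annual_event_frequency_grid(da, thr, HW)
    assert freq.shape == (2, 2, 2)
    assert (freq.values == 0).all()


def test_single_injected_run_counts_once():
    v = np.full((DAYS_PER_YEAR, 2, 2), 10.0)
    v[100:105, 1, 0] = 30.0
    da = _toy_daily(v, [1990])
    thr = da.isel(time=0).drop_vars(["year", "doy", "time"]).copy(data=np.full((2, 2), 20.0))
    freq = annual_event_frequency_grid(da, thr, HW)
    expected = np.zeros((2, 2))
    expected[1, 0] = 1
    np.testing.assert_array_equal(freq.values[0], expected)


def test_partial_year_rejected():
    v = np.zeros((DAYS_PER_YEAR, 2, 2))
    da = _toy_daily(v, [1990]).isel(time=slice(0, 300))
    thr = _toy_daily(v, [1990]).isel(time=0).drop_vars(["year", "doy", "time"]) * 0
    with pytest.raises(InsufficientDataError):
        annual_event_frequency_grid(da, thr, HW)


def test_translation_invariance(tiny_cfg):
    tasmax = gen_daily_temperature_grid(tiny_cfg, "tasmax")
    thr = compute_threshold_grid(tasmax, kind=HW)
    f1 = annual_event_frequency_grid(tasmax, thr, HW)
    f2 = annual_event_frequency_grid(tasmax + 5.0, thr + 5.0, HW)
    np.testing.assert_array_equal(f1.values, f2.values)


def test_warming_monotonicity_of_event_days(tiny_cfg):
    """+delta warming never removes HW event days, never adds CW event days.

    Event *days* (days inside qualifying runs) are the monotone quantity;
    event *counts* are not, because warming can merge two adjacent
    qualifying runs into one (the all-flagged year counts a single event).
    """
    tasmax = gen_daily_temperature_grid(tiny_cfg, "tasmax")
    tasmin = gen_daily_temperature_grid(tiny_cfg, "tasmin")
    qh = compute_threshold_grid(tasmax, kind=HW)
    qc = compute_threshold_grid(tasmin, kind=CW)

    def event_days(daily, thr, kind):
        flags = label_exceedance_days(daily, thr, kind)
        t, nlat, nlon = flags.shape
        return count_event_days_columns(flags.values.reshape(t, nlat * nlon), 3)

    assert (event_days(tasmax + 1.5, qh, HW) >= event_days(tasmax, qh, HW)).all()
    assert (event_days(tasmin + 1.5, qc, CW) <= event_days(tasmin, qc, CW)).all()
    hw0 = annual_event_frequency_grid(tasmax, qh, HW)
    assert hw0.values.max() <= DAYS_PER_YEAR // 3


def test_count_merging_counterexample():
    """Warming can merge runs: flags [T,T,T,F,T,T,T] has 2 events, filling
    the gap leaves 1 — the documented reason counts are not monotone."""
    assert count_events(np.array([1, 1, 1, 0, 1, 1, 1], bool), 3) == 2
    assert count_events(np.ones(7, bool), 3) == 1


# --- regridding -----------------------------------------------------------


def _plane_thresholds():
    lat = np.array([30.0, 30.5, 31.0])
    lon = np.array([110.0, 110.5, 111.0])
    field = 2.0 * lat[:, None] + 3.0 * lon[None, :] + 1.0
    return xr.DataArray(field, dims=("lat", "lon"), coords={"lat": lat, "lon": lon})


def test_regrid_identity():
    thr = _plane_thresholds()
    out = regrid_thresholds(thr, thr["lat"].values, thr["lon"].values)
    np.testing.assert_allclose(out.values, thr.values)


def test_regrid_exact_on_planes():
    thr = _plane_thresholds()
    tlat = np.array([30.1, 30.7])
    tlon = np.array([110.2, 110.9])
    out = regrid_thresholds(thr, tlat, tlon)
    expected = 2.0 * tlat[:, None] + 3.0 * tlon[None, :] + 1.0
    np.testing.assert_allclose(out.values, expected, atol=1e-12)


def test_regrid_midpoint_is_corner_mean():
    lat = np.array([30.0, 31.0])
    lon = np.array([110.0, 111.0])
    corners = np.array([[1.0, 3.0], [5.0, 9.0]])
    thr = xr.DataArray(corners, dims=("lat", "lon"), coords={"lat": lat, "lon": lon})
    out = regrid_thresholds(thr, np.array([30.5]), np.array([110.5]))
    assert out.values[0, 0] == pytest.approx(corners.mean())


def test_regrid_refuses_extrapolation():
    thr = _plane_thresholds()
    with pytest.raises(AlignmentError):
        regrid_thresholds(thr, np.array([29.0]), np.array([110.5]))
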