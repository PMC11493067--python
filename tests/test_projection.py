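"""Projection analytics and the frozen-economy scenario driver."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from graincast.config import ResponseSpec, SynthConfig
from graincast.grids import AlignmentError, annual_grid
from graincast.pipeline import (
    EncoderParams,
    fit_observation_model,
    project_scenario,
    region_total,
)
from graincast.projection import (
    DegenerateRegressionError,
    InsufficientDataError,
    baseline_production,
    ensemble_median_iqr,
    hw_cw_tradeoff,
    rank_and_split_gcms,
    smooth_4yr,
    tas_anomaly_regression,
    temporal_pearson_map,
)
from graincast.regression import RFConfig
from graincast.synth import gen_scenario_ensemble


# --- 4-year smoothing -----------------------------------------------------


def test_smooth_4yr_hand_values():
    s = pd.Series([1, 2, 3, 4, 5, 6, 7, 8], index=range(2021, 2029), dtype=float)
    out = smooth_4yr(s)
    assert list(out.index) == [2021, 2025]
    np.testing.assert_allclose(out.values, [2.5, 6.5])


def test_smooth_4yr_constant_and_group_count():
    s = pd.Series(3.0, index=range(2021, 2101))
    out = smooth_4yr(s)
    assert len(out) == 20 and (out == 3.0).all()


def test_smooth_4yr_conserves_mean():
    rng = np.random.default_rng(0)
    s = pd.Series(rng.normal(size=8), index=range(2021, 2029))
    assert smooth_4yr(s).mean() == pytest.approx(s.mean())


def test_smooth_4yr_partial_group_warns():
    s = pd.Series(1.0, index=range(2021, 2027))
    with pytest.warns(UserWarning, match="partial"):
        out = smooth_4yr(s)
    assert list(out.index) == [2021]


# --- ensemble aggregation -------------------------------------------------


def test_median_iqr_identical_members_zero_band():
    df = pd.DataFrame({"a": [5.0, 6.0], "b": [5.0, 6.0]}, index=[2021, 2022])
    out = ensemble_median_iqr(df)
    assert (out["q75"] - out["q25"]).max() == 0.0
    np.testing.assert_allclose(out["median"], [5.0, 6.0])


def test_median_of_three():
    df = pd.DataFrame({"a": [1.0], "b": [2.0], "c": [3.0]}, index=[2021])
    assert ensemble_median_iqr(df)["median"].iloc[0] == 2.0


def test_median_iqr_matches_sort_oracle():
    rng = np.random.default_rng(1)
    df = pd.DataFrame(rng.normal(size=(5, 25)), index=range(2021, 2026))
    out = ensemble_median_iqr(df)
    for year in df.index:
        srt = np.sort(df.loc[year].values)
        assert out.loc[year, "median"] == pytest.approx(np.median(srt))
        assert out.loc[year, "q25"] == pytest.approx(np.quantile(srt, 0.25))
        assert out.loc[year, "q75"] == pytest.approx(np.quantile(srt, 0.75))


# --- ensemble split -------------------------------------------------------


def _freq_stack(offset, seed=0, n_years=3):
    rng = np.random.default_rng(seed)
    vals = rng.poisson(3 + offset, size=(n_years, 4, 4))
    return annual_grid(vals, range(2021, 2021 + n_years), np.arange(4.0), np.arange(4.0), "hw_freq")


def test_split_matches_constructed_propensity():
    stacks = {f"G{i}": _freq_stack(offset=2 * i, seed=i) for i in range(4)}
    out = rank_and_split_gcms(stacks)
    assert out.loc["G3", "membership"] == "higher"
    assert out.loc["G2", "membership"] == "higher"
    assert out.loc["G1", "membership"] == "lower"
    assert out.loc["G0", "membership"] == "lower"


def test_split_rank_invariant_under_constant_shift():
    stacks = {f"G{i}": _freq_stack(offset=2 * i, seed=i) for i in range(4)}
    shifted = {k: v + 7 for k, v in stacks.items()}
    a = rank_and_split_gcms(stacks)["membership"]
    b = rank_and_split_gcms(shifted)["membership"]
    pd.testing.assert_series_equal(a, b)


def test_split_odd_count_differs_by_one():
    stacks = {f"G{i}": _freq_stack(offset=i, seed=i) for i in range(5)}
    out = rank_and_split_gcms(stacks)["membership"].value_counts()
    assert abs(out["higher"] - out["lower"]) == 1


def test_split_mismatched_grids_rejected():
    a = _freq_stack(0)
    b = _freq_stack(0, n_years=4)
    with pytest.raises(AlignmentError):
        rank_and_split_gcms({"a": a, "b": b})


# --- trade-off and anomaly regressions -----------------------------------


def test_tradeoff_exact_reciprocal_pair():
    hw = np.linspace(0, 10, 200)
    cw = -4.0 * hw + 30.0
    s_hw_on_cw, s_cw_on_hw = hw_cw_tradeoff(hw, cw)
    assert s_hw_on_cw == pytest.approx(-0.25)
    assert s_cw_on_hw == pytest.approx(-4.0)


def test_tradeoff_null_case_near_zero():
    rng = np.random.default_rng(2)
    hw, cw = rng.normal(size=4000), rng.normal(size=4000)
    s1, s2 = hw_cw_tradeoff(hw, cw)
    se = 1.0 / np.sqrt(4000)
    assert abs(s1) < 3 * se and abs(s2) < 3 * se


def test_tradeoff_slope_product_is_r_squared():
    rng = np.random.default_rng(3)
    hw = rng.normal(size=500)
    cw = -0.5 * hw + rng.normal(scale=0.5, size=500)
    s1, s2 = hw_cw_tradeoff(hw, cw)
    r2 = np.corrcoef(hw, cw)[0, 1] ** 2
    assert s1 * s2 == pytest.approx(r2, rel=1e-9)
    assert s1 * s2 <= 1.0


def test_tradeoff_degenerate_rejected():
    with pytest.raises(DegenerateRegressionError):
        hw_cw_tradeoff(np.ones(10), np.arange(10.0))


def test_anomaly_regression_exact_line():
    x = np.linspace(0.5, 4.0, 12)
    y = -150.0 * x + 20.0
    out = tas_anomaly_regression(x, y)
    assert out["slope"] == pytest.approx(-150.0)
    assert out["n_dropped"] == 0


def test_anomaly_regression_drops_outlier():
    rng = np.random.default_rng(4)
    x = np.linspace(0.5, 4.0, 25)
    y = -150.0 * x + rng.normal(0, 5, 25)
    y[10] += 4000.0  # gross outlier
    out = tas_anomaly_regression(x, y)
    assert out["n_dropped"] >= 1
    assert out["slope"] == pytest.approx(-150.0, rel=0.1)


def test_anomaly_regression_degenerate_inputs():
    with pytest.raises(DegenerateRegressionError):
        tas_anomaly_regression(np.zeros(5), np.arange(5.0))
    with pytest.raises(InsufficientDataError):
        tas_anomaly_regression([1.0, 2.0], [1.0, 2.0])


# --- temporal Pearson map -------------------------------------------------


def test_pearson_map_increasing_counts():
    vals = np.arange(5)[:, None, None] * np.ones((1, 2, 2))
    freq = annual_grid(vals, range(2021, 2026), np.arange(2.0), np.arange(2.0), "hw_freq")
    r = temporal_pearson_map(freq)
    np.testing.assert_allclose(r.values, 1.0)


def test_pearson_map_constant_cell_flagged():
    vals = np.ones((5, 2, 2))
    vals[:, 0, 0] = np.arange(5)
    freq = annual_grid(vals, range(2021, 2026), np.arange(2.0), np.arange(2.0), "hw_freq")
    r = temporal_pearson_map(freq)
    assert r.values[0, 0] == pytest.approx(1.0)
    assert np.isnan(r.values[1, 1])


def test_pearson_map_matches_direct_formula():
    rng = np.random.default_rng(5)
    vals = rng.poisson(3, size=(8, 3, 3)).astype(float)
    years = np.arange(2021, 2029)
    freq = annual_grid(vals, years, np.arange(3.0), np.arange(3.0), "hw_freq")
    r = temporal_pearson_map(freq)
    for i in range(3):
        for j in range(3):
            expected = np.corrcoef(years, vals[:, i, j])[0, 1]
            assert r.values[i, j] == pytest.approx(expected, abs=1e-12)


# --- scenario driver ------------------------------------------------------


@pytest.fixture(scope="module")
def proj_model():
    cfg = SynthConfig(
        seed=13, grid_shape=(8, 8), years_obs=(1990, 2001), years_base=(1981, 1990),
        years_proj=(2021, 2026),
    )
    rfc = RFConfig(param_grid={"n_estimators": [100]}, seed=13)
    model = fit_observation_model(
        cfg, ResponseSpec(), rfc, EncoderParams(epochs=8), with_benchmarks=False
    )
    ens = gen_scenario_ensemble(cfg, 3, {"SSP126": 0.1, "SSP585": 0.6})
    return model, ens


def test_projection_shape_and_determinism(proj_model):
    model, ens = proj_model
    a = project_scenario(model, ens["SSP585"], "SSP585")
    b = project_scenario(model, ens["SSP585"], "SSP585")
    pd.testing.assert_frame_equal(a, b)
    n_prov = model.cfg.n_provinces
    n_years = len(model.cfg.proj_years)
    assert len(a) == 3 * n_prov * n_years
    assert set(a["scenario"]) == {"SSP585"}


def test_identical_members_identical_projections(proj_model):
    model, ens = proj_model
    g0 = ens["SSP126"]["GCM00"]
    twin = {"A": g0, "B": {k: v.copy() for k, v in g0.items()}}
    out = project_scenario(model, twin, "SSP126")
    a = out[out["gcm"] == "A"]["prediction_t"].values
    b = out[out["gcm"] == "B"]["prediction_t"].values
    np.testing.assert_allclose(a, b)


def test_frozen_climate_gives_constant_projection(proj_model):
    """Repeating one year's climate for every projection year freezes output."""
    model, ens = proj_model
    g = ens["SSP126"]["GCM00"]
    frozen = {}
    years = model.cfg.proj_years
    for var, da in g.items():
        steps = (da["year"].values == years[0]).sum()
        block = da.isel(time=slice(0, steps)).values
        tiled = np.tile(block, (len(years), 1, 1))
        frozen[var] = da.copy(data=tiled)
    out = project_scenario(model, {"F": frozen}, "SSP126")
    per_year = out.groupby("year")["prediction_t"].sum()
    assert per_year.std() == pytest.approx(0.0, abs=1e-9)


def test_frozen_economy_ignores_pre_freeze_history(proj_model):
    """Permuting economic history before the freeze year leaves projections unchanged."""
    model, ens = proj_model
    out1 = project_scenario(model, ens["SSP126"], "SSP126")
    shuffled = model.cases.copy()
    years = shuffled.index.get_level_values("year")
    pre = shuffled[years < years.max()].sample(frac=1.0, random_state=1)
    post = shuffled[years == years.max()]
    model.cases = pd.concat([pre, post])
    out2 = project_scenario(model, ens["SSP126"], "SSP126")
    pd.testing.assert_frame_equal(
        out1.sort_values(["gcm", "province", "year"]).reset_index(drop=True),
        out2.sort_values(["gcm", "province", "year"]).reset_index(drop=True),
    )


def test_warming_scenario_declines_when_ground_truth_penalizes_heatwaves():
    """With production built to suffer from HW frequency (all other climate
    coefficients zero), the strongly warming scenario's ensemble-median
    projection trends downward (negative Spearman correlation with time)."""
    from scipy.stats import spearmanr

    cfg = SynthConfig(
        seed=2, grid_shape=(8, 8), years_obs=(1990, 2009), years_base=(1981, 1990),
        years_proj=(2021, 2050),
    )
    resp = ResponseSpec(
        coef_hw=-0.08, coef_cw=0.0, coef_tas=0.0, coef_pr=0.0,
        trend_per_year=0.0, noise_sd=10.0,
    )
    rfc = RFConfig(param_grid={"n_estimators": [200], "min_samples_leaf": [1, 2]}, seed=2)
    model = fit_observation_model(
        cfg, resp, rfc, EncoderParams(epochs=25), with_benchmarks=False
    )
    ens = gen_scenario_ensemble(cfg, 3, {"SSP585": 0.8})
    proj = project_scenario(model, ens["SSP585"], "SSP585")
    med = ensemble_median_iqr(region_total(proj))["median"]
    rho = spearmanr(med.index, med.values).statistic
    assert rho < 0, f"median projection does not decline (rho={rho:.3f})"


def test_baseline_from_observations():
    econ = pd.DataFrame(
        {
            "province": ["A", "A", "B", "B"],
            "year": [2001, 2002, 2001, 2002],
            "production_t": [10.0, 20.0, 30.0, 40.0],
        }
    )
    assert baseline_production(econ, (2001, 2002)) == pytest.approx(50.0)
    with pytest.raises(InsufficientDataError):
        baseline_production(econ, (1990, 1995))


def test_region_total_pivots(proj_model):
    model, ens = proj_model
    out = project_scenario(model, ens["SSP126"], "SSP126")
    tot = region_total(out)
    assert tot.shape == (len(model.cfg.proj_years), 3)
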