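import numpy as np
import pandas as pd
import pytest

from graincast.config import ResponseSpec, SynthConfig
from graincast.pipeline import EncoderParams, fit_observation_model, synthesize_observations
from graincast.regression import RFConfig


@pytest.fixture(scope="session")
def tiny_cfg():
    """Desk-scale world: 6x6 grid, 6 observation years, 10 base years."""
    return SynthConfig(
        seed=7, grid_shape=(6, 6), years_obs=(1991, 1996), years_base=(1981, 1990)
    )


@pytest.fixture(scope="session")
def tiny_world(tiny_cfg):
    grids, econ = synthesize_observations(tiny_cfg, ResponseSpec())
    return grids, econ


@pytest.fixture(scope="session")
def small_rf_cfg():
    return RFConfig(param_grid={"n_estimators": [100], "max_depth": [8, None]}, seed=7)


@pytest.fixture(scope="session")
def fitted_model(tiny_cfg, small_rf_cfg):
    """One full observation-pipeline fit shared across tests."""
    cfg = tiny_cfg.replace(years_obs=(1990, 2001))
    return fit_observation_model(
        cfg, ResponseSpec(), small_rf_cfg, EncoderParams(epochs=8), with_benchmarks=True
    )


def north_south_gradient_production(grids, econ, provinces, amplitude=400.0, base=5000.0):
    """Production driven by the within-province north-south heatwave gradient.

    The gradient is (mean of the northern half) - (mean of the southern half)
    of each province's annual hw_freq field: a spatial-pattern signal that is
    invisible to a spatial-mean model by construction.
    """
    hw = grids["hw_freq"]
    lat, lon = hw["lat"].values, hw["lon"].values
    rows = {}
    for box in provinces:
        ilat = np.where((lat >= box.lat_min) & (lat <= box.lat_max))[0]
        ilon = np.where((lon >= box.lon_min) & (lon <= box.lon_max))[0]
        sub = hw.values[:, ilat[:, None], ilon[None, :]]
        half = len(ilat) // 2
        g = sub[:, half:, :].mean(axis=(1, 2)) - sub[:, :half, :].mean(axis=(1, 2))
        for y, gv in zip(hw["year"].values, g):
            rows[(box.name, int(y))] = gv
    econ = econ.set_index(["province", "year"])
    g = pd.Series(rows).reindex(econ.index)
    econ["production_t"] = base + amplitude * g.values
    return econ.reset_index()


def run_pattern_ablation(seed):
    """One seed of the spatial-signal experiment: returns (primary, B2) MAPE."""
    cfg = SynthConfig(
        seed=seed, grid_shape=(8, 8), years_obs=(1990, 2009), years_base=(1981, 1990)
    )
    grids, econ = synthesize_observations(cfg, ResponseSpec(noise_sd=0))
    econ = north_south_gradient_production(grids, econ, cfg.provinces())
    rfc = RFConfig(
        param_grid={"n_estimators": [200], "max_depth": [None], "min_samples_leaf": [1, 2]},
        seed=seed,
    )
    m = fit_observation_model(
        cfg, ResponseSpec(), rfc, EncoderParams(epochs=40), grids=grids, econ=econ
    )
    return m.reports["ConvAE-RF"].mape, m.reports["B2-RF"].mape


def run_sown_area_recovery(seed):
    """One seed of the dominant-SownArea recovery: returns the top variable."""
    cfg = SynthConfig(
        seed=seed, grid_shape=(8, 8), years_obs=(1990, 2001), years_base=(1981, 1990)
    )
    rfc = RFConfig(param_grid={"n_estimators": [100], "max_depth": [8, None]}, seed=seed)
    m = fit_observation_model(
        cfg, ResponseSpec(), rfc, EncoderParams(epochs=8), with_benchmarks=False
    )
    return m.importance.idxmax()
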