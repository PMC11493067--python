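"""Synthetic climate and economic data with known ground truth.

Daily temperature grids combine a latitude-dependent seasonal cycle, a slow
warming trend, and AR(1) day-to-day noise; warm or cold runs of known length
and magnitude can be stamped into chosen cells so the event detector can be
validated against construction.  Economic series follow the stylized facts of
provincial yearbooks: shrinking primary-industry employment, machinery power
that roughly triples over three decades, slowly varying sown area.  The
production generator applies a known response function so that downstream
feature-importance and skill claims can be tested as recovery experiments.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr
from scipy.signal import lfilter

from .config import (
    DAYS_PER_YEAR,
    MONTHS_PER_YEAR,
    SCENARIOS,
    ConfigurationError,
    ResponseSpec,
    SynthConfig,
)
from .grids import AlignmentError, daily_grid, monthly_grid

# stable RNG stream ids per generated product
_STREAMS = {
    "tasmax": 1,
    "tasmin": 2,
    "tas": 3,
    "pr": 4,
    "econ": 5,
    "production": 6,
    "gcm": 7,
}

#: default scenario warming rates, degC per decade (ordered by forcing)
DEFAULT_SCENARIO_TRENDS = {
    "SSP126": 0.10,
    "SSP245": 0.25,
    "SSP370": 0.45,
    "SSP585": 0.60,
}


def _seasonal_cycle(doy: np.ndarray, amplitude: float) -> np.ndarray:
    """Annual harmonic peaking in mid-July (doy ~196) on a no-leap calendar."""
    return amplitude * np.cos(2 * np.pi * (doy - 196) / DAYS_PER_YEAR)


def _base_field(cfg: SynthConfig, years: np.ndarray, rng, daily: bool = True):
    """Deterministic seasonal + latitudinal + trend component and AR(1) noise."""
    steps = DAYS_PER_YEAR if daily else MONTHS_PER_YEAR
    n_years = len(years)
    nlat, nlon = cfg.grid_shape
    if daily:
        tix = np.tile(np.arange(1, steps + 1), n_years)
        season = _seasonal_cycle(tix, cfg.seasonal_amplitude)
    else:
        months = np.tile(np.arange(1, 13), n_years)
        season = _seasonal_cycle((months - 0.5) * DAYS_PER_YEAR / 12, cfg.seasonal_amplitude)
    frac_year = np.repeat(years - years[0], steps) + np.tile(
        np.arange(steps) / steps, n_years
    )
    trend = cfg.trend_degc_per_decade / 10.0 * frac_year
    latg = cfg.lat_gradient_degc_per_deg * (cfg.lat - cfg.lat[0])
    det = (
        cfg.mean_tas
        + season[:, None, None]
        + trend[:, None, None]
        + latg[None, :, None]
        + np.zeros((1, 1, nlon))
    )
    if cfg.noise_sd > 0:
        eps = rng.normal(0.0, cfg.noise_sd, size=(steps * n_years, nlat, nlon))
        # stationary AR(1): innovations scaled so marginal sd == noise_sd
        eps *= np.sqrt(1.0 - cfg.ar1_coeff**2)
        noise = lfilter([1.0], [1.0, -cfg.ar1_coeff], eps, axis=0)
    else:
        noise = np.zeros((steps * n_years, nlat, nlon))
    return det + noise


def gen_daily_temperature_grid(cfg: SynthConfig, variable: str) -> xr.DataArray:
    """Daily tasmax or tasmin over the base-through-observation period.

    tasmax sits ``diurnal_half_range`` above the daily-mean cycle and tasmin
    the same amount below.  Injected events shift the field by their stated
    magnitude over their stated run.
    """
    if variable not in ("tasmax", "tasmin"):
        raise ConfigurationError(f"unknown daily variable {variable!r}")
    years = cfg.all_obs_years
    rng = cfg.child_seed(_STREAMS[variable])
    values = _base_field(cfg, years, rng, daily=True)
    offset = cfg.diurnal_half_range if variable == "tasmax" else -cfg.diurnal_half_range
    values = values + offset
    for ev in cfg.event_injections:
        if ev.year not in years:
            continue
        t0 = (np.searchsorted(years, ev.year)) * DAYS_PER_YEAR + (ev.start_doy - 1)
        t1 = min(t0 + ev.length_days, values.shape[0])
        for (ilat, ilon) in ev.cells:
            values[t0:t1, ilat, ilon] += ev.magnitude_degc
    return daily_grid(values, years, cfg.lat, cfg.lon, variable)


def gen_monthly_climate_grid(cfg: SynthConfig, variable: str) -> xr.DataArray:
    """Monthly mean temperature (tas, degC) or monthly total precipitation (pr, mm)."""
    years = cfg.obs_years
    rng = cfg.child_seed(_STREAMS[variable])
    if variable == "tas":
        values = _base_field(cfg, years, rng, daily=False)
        return monthly_grid(values, years, cfg.lat, cfg.lon, "tas", units="degC")
    if variable == "pr":
        months = np.tile(np.arange(1, 13), len(years))
        # monsoon-like profile peaking in June-July, mm per month
        profile = 60.0 + 120.0 * np.exp(-0.5 * ((months - 6.5) / 1.8) ** 2)
        nlat, nlon = cfg.grid_shape
        base = np.broadcast_to(profile[:, None, None], (len(months), nlat, nlon))
        if cfg.noise_sd > 0:
            lognoise = rng.lognormal(
                mean=0.0, sigma=cfg.noise_sd / 10.0, size=base.shape
            )
        else:
            lognoise = 1.0
        return monthly_grid(base * lognoise, years, cfg.lat, cfg.lon, "pr", units="mm")
    raise ConfigurationError(f"unknown monthly variable {variable!r}")


def gen_economic_table(cfg: SynthConfig) -> pd.DataFrame:
    """Province-year economic indicators, one row per (province, year).

    PrimInd declines, MechPower roughly triples over the observation window,
    SownArea varies slowly; noise is multiplicative log-normal so every
    series stays strictly positive.
    """
    rng = cfg.child_seed(_STREAMS["econ"])
    years = cfg.obs_years
    n_years = len(years)
    frac = (years - years[0]) / max(n_years - 1, 1)
    rows = []
    for p in range(cfg.n_provinces):
        prng = np.random.default_rng(
            np.random.SeedSequence((int(cfg.seed), _STREAMS["econ"], p))
        )
        sown0 = 2000.0 + 400.0 * p
        prim0 = 3000.0 - 150.0 * p
        mech0 = 10.0 + 2.0 * p
        sown = sown0 * (1.0 + 0.05 * np.sin(2 * np.pi * frac))
        prim = prim0 * (1.0 - 0.65 * frac)
        mech = mech0 * (1.0 + 2.2 * frac)  # ~3.2x over the window
        if cfg.noise_sd > 0:
            s = cfg.noise_sd / 100.0
            sown = sown * prng.lognormal(0.0, s, n_years)
            prim = prim * prng.lognormal(0.0, s, n_years)
            mech = mech * prng.lognormal(0.0, s, n_years)
        for i, y in enumerate(years):
            rows.append(
                {
                    "province": f"P{p:02d}",
                    "year": int(y),
                    "sown_area_kha": sown[i],
                    "prim_ind_k": prim[i],
                    "mech_power_gw": mech[i],
                }
            )
    return pd.DataFrame(rows)


def gen_production(
    econ: pd.DataFrame,
    climate_summaries: pd.DataFrame,
    spec: ResponseSpec,
    seed: int,
) -> pd.Series:
    """Ground-truth grain production (tons) for aligned province-year cases.

    ``climate_summaries`` must carry per (province, year) columns
    tas (degC), pr (mm/yr), hw_freq and cw_freq (events/yr).
    """
    e = econ.set_index(["province", "year"]).sort_index()
    c = climate_summaries.set_index(["province", "year"]).sort_index()
    if not e.index.equals(c.index):
        missing = e.index.symmetric_difference(c.index).tolist()
        raise AlignmentError(f"econ and climate summaries misaligned on keys: {missing[:10]}")
    dt = e.index.get_level_values("year") - e.index.get_level_values("year").min()
    core = (
        spec.scale
        * e["sown_area_kha"] ** spec.elasticity_sown_area
        * e["prim_ind_k"] ** spec.elasticity_prim_ind
        * e["mech_power_gw"] ** spec.elasticity_mech_power
        * np.exp(spec.trend_per_year * dt)
    )
    modifier = (
        1.0
        + spec.coef_tas * (c["tas"] - spec.tas_ref)
        + spec.coef_pr * (c["pr"] - spec.pr_ref)
        + spec.coef_hw * c["hw_freq"]
        + spec.coef_cw * c["cw_freq"]
    ).clip(lower=spec.climate_floor)
    y = core * modifier
    if spec.noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence((int(seed), _STREAMS["production"])))
        y = y + rng.normal(0.0, spec.noise_sd, size=len(y))
    y = y.clip(lower=1.0)  # production is strictly positive by construction
    y.name = "production_t"
    return y


def gen_scenario_ensemble(
    cfg: SynthConfig,
    n_gcms: int,
    scenario_trends: dict[str, float] | None = None,
    member_offset_spread: float = 1.0,
) -> dict[str, dict[str, dict[str, xr.DataArray]]]:
    """Pseudo-GCM scenario climate bundles on the finer scenario grid.

    Returns ``{scenario: {gcm: {"tasmax": ..., "tasmin": ..., "tas": ...,
    "pr": ...}}}`` over the projection years.  Member m carries a fixed
    temperature offset (evenly spaced in ±member_offset_spread/2, ordered by
    member index) so that heatwave propensity orderings are known by
    construction; each scenario adds its stated linear warming from the first
    projection year.
    """
    if n_gcms < 2:
        raise ConfigurationError("n_gcms must be >= 2")
    trends = dict(DEFAULT_SCENARIO_TRENDS if scenario_trends is None else scenario_trends)
    years = cfg.proj_years
    lat, lon = cfg.scenario_lat, cfg.scenario_lon
    scen_cfg = cfg.replace(
        grid_shape=(len(lat), len(lon)),
        resolution_deg=cfg.scenario_resolution_deg,
        lat_start=float(lat[0]),
        lon_start=float(lon[0]),
        trend_degc_per_decade=0.0,
    )
    if n_gcms == 1:
        offsets = np.zeros(1)
    else:
        offsets = np.linspace(-0.5, 0.5, n_gcms) * member_offset_spread
    out: dict[str, dict[str, dict[str, xr.DataArray]]] = {}
    for scenario, rate in trends.items():
        if scenario not in SCENARIOS:
            raise ConfigurationError(f"unknown scenario {scenario!r}")
        out[scenario] = {}
        for m in range(n_gcms):
            member = f"GCM{m:02d}"
            mseed = np.random.SeedSequence(
                (int(cfg.seed), _STREAMS["gcm"], SCENARIOS.index(scenario), m)
            )
            rngs = np.random.default_rng(mseed).spawn(3)
            bundle: dict[str, xr.DataArray] = {}
            frac_daily = np.repeat(years - years[0], DAYS_PER_YEAR) + np.tile(
                np.arange(DAYS_PER_YEAR) / DAYS_PER_YEAR, len(years)
            )
            warming_daily = rate / 10.0 * frac_daily
            for vi, var in enumerate(("tasmax", "tasmin")):
                vals = _base_field(scen_cfg, years, rngs[vi], daily=True)
                off = cfg.diurnal_half_range if var == "tasmax" else -cfg.diurnal_half_range
                vals = vals + off + offsets[m] + warming_daily[:, None, None]
                bundle[var] = daily_grid(vals, years, lat, lon, var)
            frac_mon = np.repeat(years - years[0], 12) + np.tile(np.arange(12) / 12, len(years))
            tvals = _base_field(scen_cfg, years, rngs[2], daily=False)
            tvals = tvals + offsets[m] + (rate / 10.0 * frac_mon)[:, None, None]
            bundle["tas"] = monthly_grid(tvals, years, lat, lon, "tas", units="degC")
            pr_cfg = scen_cfg.replace(seed=int(mseed.generate_state(1)[0] % (2**31)))
            pr_cfg = pr_cfg.replace(years_obs=(int(years[0]), int(years[-1])))
            bundle["pr"] = gen_monthly_climate_grid(pr_cfg, "pr")
            out[scenario][member] = bundle
    return out
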