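"""Configuration objects shared across the pipeline.

The synthetic world is a small rectangular study region divided into
rectangular "provinces".  All grids use cell-center latitude/longitude
coordinates in degrees north/east and a 365-day no-leap calendar.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

DAYS_PER_YEAR = 365
MONTHS_PER_YEAR = 12

#: canonical climate variable names (CMIP vocabulary)
CLIMATE_VARS = ("hw_freq", "cw_freq", "tas", "pr")
SCENARIOS = ("SSP126", "SSP245", "SSP370", "SSP585")


class ConfigurationError(ValueError):
    """Invalid configuration value."""


@dataclass(frozen=True)
class EventInjection:
    """A synthetic exceedance run stamped into a daily temperature field.

    ``cells`` are (ilat, ilon) index pairs; the run covers ``length_days``
    consecutive days starting at day-of-year ``start_doy`` (1-based) of
    ``year`` and shifts the field by ``magnitude_degc`` (positive for warm
    runs in tasmax, negative for cold runs in tasmin).
    """

    cells: tuple
    year: int
    start_doy: int
    length_days: int
    magnitude_degc: float

    def __post_init__(self):
        if self.length_days < 1:
            raise ConfigurationError("injection length_days must be >= 1")
        if not 1 <= self.start_doy <= DAYS_PER_YEAR:
            raise ConfigurationError("start_doy must be in [1, 365]")


@dataclass(frozen=True)
class ProvinceBox:
    """Rectangular province footprint in degrees (cell centers inside count)."""

    name: str
    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float

    def mask(self, lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
        """Boolean (lat, lon) membership mask for cell-center axes."""
        inlat = (lat >= self.lat_min) & (lat <= self.lat_max)
        inlon = (lon >= self.lon_min) & (lon <= self.lon_max)
        return np.outer(inlat, inlon)


@dataclass
class SynthConfig:
    """Stated world for the synthetic generators.

    Defaults mirror the observational setting the pipeline targets:
    6 provinces, observations 1990-2021, percentile base period 1981-2010,
    a 16x16 grid at 0.5 degrees with a 2x-finer scenario grid.
    """

    seed: int = 0
    n_provinces: int = 6
    years_obs: tuple[int, int] = (1990, 2021)
    years_base: tuple[int, int] = (1981, 2010)
    years_proj: tuple[int, int] = (2021, 2100)
    grid_shape: tuple[int, int] = (16, 16)
    resolution_deg: float = 0.5
    scenario_resolution_deg: float = 0.25
    lat_start: float = 28.25
    lon_start: float = 110.25
    ar1_coeff: float = 0.7
    seasonal_amplitude: float = 12.0
    noise_sd: float = 2.0
    trend_degc_per_decade: float = 0.25
    mean_tas: float = 16.0
    lat_gradient_degc_per_deg: float = -0.6
    diurnal_half_range: float = 5.0
    event_injections: list[EventInjection] = field(default_factory=list)

    def __post_init__(self):
        nlat, nlon = self.grid_shape
        if nlat <= 0 or nlon <= 0:
            raise ConfigurationError("grid_shape must be positive")
        if not 0.0 <= self.ar1_coeff < 1.0:
            raise ConfigurationError("ar1_coeff must be in [0, 1)")
        if self.years_base[0] > self.years_obs[0]:
            raise ConfigurationError("base period must start at or before observations")
        if self.years_base[1] < self.years_base[0] or self.years_obs[1] < self.years_obs[0]:
            raise ConfigurationError("year ranges must be non-decreasing")
        if self.n_provinces < 1:
            raise ConfigurationError("n_provinces must be >= 1")

    # --- grid axes -------------------------------------------------------
    @property
    def lat(self) -> np.ndarray:
        return self.lat_start + self.resolution_deg * np.arange(self.grid_shape[0])

    @property
    def lon(self) -> np.ndarray:
        return self.lon_start + self.resolution_deg * np.arange(self.grid_shape[1])

    @property
    def scenario_lat(self) -> np.ndarray:
        """Finer-grid latitude axis strictly inside the observation hull."""
        return _refined_axis(self.lat, self.scenario_resolution_deg)

    @property
    def scenario_lon(self) -> np.ndarray:
        return _refined_axis(self.lon, self.scenario_resolution_deg)

    @property
    def obs_years(self) -> np.ndarray:
        return np.arange(self.years_obs[0], self.years_obs[1] + 1)

    @property
    def base_years(self) -> np.ndarray:
        return np.arange(self.years_base[0], self.years_base[1] + 1)

    @property
    def all_obs_years(self) -> np.ndarray:
        """Base period united with the observation period."""
        return np.arange(self.years_base[0], self.years_obs[1] + 1)

    @property
    def proj_years(self) -> np.ndarray:
        return np.arange(self.years_proj[0], self.years_proj[1] + 1)

    # --- provinces -------------------------------------------------------
    def provinces(self) -> list[ProvinceBox]:
        """Partition the study region into rectangular provinces.

        Provinces tile a ``nrows x ncols`` arrangement with nrows the largest
        divisor of ``n_provinces`` not exceeding its square root (6 -> 2x3).
        """
        n = self.n_provinces
        nrows = max(d for d in range(1, int(np.sqrt(n)) + 1) if n % d == 0)
        ncols = n // nrows
        lat, lon = self.lat, self.lon
        half = self.resolution_deg / 2
        lat_edges = np.linspace(lat[0] - half, lat[-1] + half, nrows + 1)
        lon_edges = np.linspace(lon[0] - half, lon[-1] + half, ncols + 1)
        boxes = []
        k = 0
        for i in range(nrows):
            for j in range(ncols):
                boxes.append(
                    ProvinceBox(
                        name=f"P{k:02d}",
                        lat_min=lat_edges[i],
                        lat_max=lat_edges[i + 1] - 1e-9,
                        lon_min=lon_edges[j],
                        lon_max=lon_edges[j + 1] - 1e-9,
                    )
                )
                k += 1
        return boxes

    def child_seed(self, stream: int) -> np.random.Generator:
        """Independent, reproducible RNG stream derived from the global seed."""
        return np.random.default_rng(np.random.SeedSequence((int(self.seed), int(stream))))

    def replace(self, **kw) -> "SynthConfig":
        return dataclasses.replace(self, **kw)


def _refined_axis(axis: np.ndarray, resolution: float) -> np.ndarray:
    """Axis at finer resolution spanning [axis[0], axis[-1]] inclusively.

    Nodes stay inside the coarse cell-center hull so bilinear regridding of
    fields defined on ``axis`` never extrapolates.
    """
    n = int(round((axis[-1] - axis[0]) / resolution)) + 1
    return axis[0] + resolution * np.arange(n)


@dataclass
class ResponseSpec:
    """Known ground-truth production response for synthetic provinces.

    Production follows a Cobb-Douglas core in the economic inputs with an
    exponential time-productivity trend, scaled by a climate modifier that is
    linear in the four per-province climate summaries:

        Y = scale * x1^e1 * x2^e2 * x3^e3 * exp(g*dt)
            * max(floor, 1 + c_tas*(tas - tas_ref) + c_pr*(pr - pr_ref)
                         + c_hw*hw + c_cw*cw)  + noise

    Defaults make sown area (x1) the dominant driver and extreme-event
    frequencies mildly harmful, qualitatively matching yearbook-scale data.
    """

    scale: float = 2.0
    elasticity_sown_area: float = 0.9
    elasticity_prim_ind: float = 0.10
    elasticity_mech_power: float = 0.15
    trend_per_year: float = 0.005
    coef_tas: float = -0.010
    coef_pr: float = 0.00005
    coef_hw: float = -0.020
    coef_cw: float = -0.010
    tas_ref: float = 16.0
    pr_ref: float = 1000.0
    climate_floor: float = 0.05
    noise_sd: float = 30.0

    def __post_init__(self):
        vals = [getattr(self, f.name) for f in dataclasses.fields(self)]
        if not all(np.isfinite(v) for v in vals):
            raise ConfigurationError("ResponseSpec values must be finite")

    def replace(self, **kw) -> "ResponseSpec":
        return dataclasses.replace(self, **kw)
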