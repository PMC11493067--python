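"""xarray containers and helpers for gridded climate fields.

Daily fields are DataArrays with dims ("time", "lat", "lon") and integer
auxiliary coordinates ``year`` and ``doy`` (1..365, no-leap calendar) along
time.  Monthly fields carry ``year`` and ``month`` instead.  Annual event
frequency grids use an explicit ``year`` dimension.
"""

from __future__ import annotations

import numpy as np
import xarray as xr

from .config import DAYS_PER_YEAR, MONTHS_PER_YEAR, ProvinceBox

NOLEAP = "noleap"


class AlignmentError(ValueError):
    """Objects that must share a grid or key set do not."""


def daily_grid(
    values: np.ndarray,
    years: np.ndarray,
    lat: np.ndarray,
    lon: np.ndarray,
    variable: str,
    units: str = "degC",
) -> xr.DataArray:
    """Wrap a (n_years*365, nlat, nlon) array as a daily temperature grid."""
    years = np.asarray(years)
    year_coord = np.repeat(years, DAYS_PER_YEAR)
    doy_coord = np.tile(np.arange(1, DAYS_PER_YEAR + 1), len(years))
    if values.shape[0] != year_coord.size:
        raise AlignmentError(
            f"time axis has {values.shape[0]} steps, expected {year_coord.size} "
            f"({len(years)} years x {DAYS_PER_YEAR} days)"
        )
    return xr.DataArray(
        values,
        dims=("time", "lat", "lon"),
        coords={
            "time": np.arange(values.shape[0]),
            "year": ("time", year_coord),
            "doy": ("time", doy_coord),
            "lat": lat,
            "lon": lon,
        },
        name=variable,
        attrs={"variable": variable, "units": units, "calendar": NOLEAP},
    )


def monthly_grid(
    values: np.ndarray,
    years: np.ndarray,
    lat: np.ndarray,
    lon: np.ndarray,
    variable: str,
    units: str,
) -> xr.DataArray:
    """Wrap a (n_years*12, nlat, nlon) array as a monthly climate grid."""
    years = np.asarray(years)
    year_coord = np.repeat(years, MONTHS_PER_YEAR)
    month_coord = np.tile(np.arange(1, MONTHS_PER_YEAR + 1), len(years))
    if values.shape[0] != year_coord.size:
        raise AlignmentError(
            f"time axis has {values.shape[0]} steps, expected {year_coord.size}"
        )
    return xr.DataArray(
        values,
        dims=("time", "lat", "lon"),
        coords={
            "time": np.arange(values.shape[0]),
            "year": ("time", year_coord),
            "month": ("time", month_coord),
            "lat": lat,
            "lon": lon,
        },
        name=variable,
        attrs={"variable": variable, "units": units, "calendar": NOLEAP},
    )


def annual_grid(
    values: np.ndarray,
    years: np.ndarray,
    lat: np.ndarray,
    lon: np.ndarray,
    variable: str,
    **attrs,
) -> xr.DataArray:
    """Wrap a (n_years, nlat, nlon) array as an annual grid (e.g. hw_freq)."""
    return xr.DataArray(
        values,
        dims=("year", "lat", "lon"),
        coords={"year": np.asarray(years), "lat": lat, "lon": lon},
        name=variable,
        attrs={"variable": variable, **attrs},
    )


def check_same_grid(a: xr.DataArray, b: xr.DataArray) -> None:
    if a.sizes["lat"] != b.sizes["lat"] or a.sizes["lon"] != b.sizes["lon"]:
        raise AlignmentError(
            f"grid shapes differ: {(a.sizes['lat'], a.sizes['lon'])} vs "
            f"{(b.sizes['lat'], b.sizes['lon'])}"
        )
    if not (
        np.allclose(a["lat"].values, b["lat"].values)
        and np.allclose(a["lon"].values, b["lon"].values)
    ):
        raise AlignmentError("lat/lon axes differ")


def select_years(da: xr.DataArray, start: int, stop: int) -> xr.DataArray:
    """Subset a time-resolved grid to calendar years [start, stop]."""
    years = da["year"].values
    dim = "year" if "year" in da.dims else "time"
    keep = (years >= start) & (years <= stop)
    return da.isel({dim: keep})


def interp_to_axes(da: xr.DataArray, lat: np.ndarray, lon: np.ndarray) -> xr.DataArray:
    """Bilinear interpolation onto target cell-center axes (no extrapolation)."""
    src_lat, src_lon = da["lat"].values, da["lon"].values
    if lat.min() < src_lat.min() - 1e-9 or lat.max() > src_lat.max() + 1e-9:
        raise AlignmentError("target latitude axis outside source hull")
    if lon.min() < src_lon.min() - 1e-9 or lon.max() > src_lon.max() + 1e-9:
        raise AlignmentError("target longitude axis outside source hull")
    out = da.interp(lat=lat, lon=lon, method="linear")
    out.attrs.update(da.attrs)
    return out


# --- province cropping / padding ----------------------------------------


def province_field(
    field2d: np.ndarray,
    lat: np.ndarray,
    lon: np.ndarray,
    box: ProvinceBox,
    pad_shape: tuple[int, int],
) -> np.ndarray:
    """Crop a (lat, lon) field to a province box, mask outside, zero-pad.

    Returns a (pad_shape) array; cells outside the province (or beyond the
    crop) are zero so one encoder architecture serves all provinces.
    """
    ilat = np.where((lat >= box.lat_min) & (lat <= box.lat_max))[0]
    ilon = np.where((lon >= box.lon_min) & (lon <= box.lon_max))[0]
    if ilat.size == 0 or ilon.size == 0:
        raise AlignmentError(f"province {box.name} contains no grid cells")
    crop = field2d[np.ix_(ilat, ilon)]
    out = np.zeros(pad_shape, dtype=float)
    if crop.shape[0] > pad_shape[0] or crop.shape[1] > pad_shape[1]:
        raise AlignmentError(
            f"province crop {crop.shape} exceeds pad shape {pad_shape}"
        )
    out[: crop.shape[0], : crop.shape[1]] = crop
    return out


def union_crop_shape(
    lat: np.ndarray, lon: np.ndarray, boxes: list[ProvinceBox]
) -> tuple[int, int]:
    """Smallest (H, W) covering every province's bounding-box crop."""
    h = w = 0
    for box in boxes:
        nlat = int(np.sum((lat >= box.lat_min) & (lat <= box.lat_max)))
        nlon = int(np.sum((lon >= box.lon_min) & (lon <= box.lon_max)))
        h, w = max(h, nlat), max(w, nlon)
    return h, w


def province_spatial_mean(
    da: xr.DataArray, box: ProvinceBox
) -> xr.DataArray:
    """Area mean over a province box for each time/year step."""
    lat, lon = da["lat"].values, da["lon"].values
    mask = box.mask(lat, lon)
    m = xr.DataArray(mask, dims=("lat", "lon"), coords={"lat": lat, "lon": lon})
    return da.where(m).mean(("lat", "lon"))
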