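"""Readers/writers for the pipeline's standard formats.

Gridded data travel as CF-style NetCDF (lat/lon cell-center axes, integer
year/doy or year/month time coordinates); tables as UTF-8 comma-separated
CSV with a required header; configuration as YAML; reports as JSON.  Every
artifact writer pairs the file with the hash of the configuration that
produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from .config import ConfigurationError, SynthConfig
from .pipeline import EncoderParams
from .regression import RFConfig

ECON_SCHEMA = ["province", "year", "sown_area_kha", "prim_ind_k", "mech_power_gw", "production_t"]
KELVIN_OFFSET = 273.15


class FormatError(ValueError):
    pass


class ValidationError(ValueError):
    pass


# --- NetCDF ---------------------------------------------------------------


def write_climate_netcdf(da: xr.DataArray, path) -> None:
    ds = da.to_dataset(name=da.name or "data")
    ds.attrs.update({k: _serializable(v) for k, v in da.attrs.items()})
    ds.to_netcdf(path, engine="scipy")


def read_climate_netcdf(path, variable: str) -> xr.DataArray:
    """Load a gridded variable; validates axes and honors a K units attr."""
    with xr.open_dataset(path, engine="scipy") as ds:
        if variable not in ds:
            raise FormatError(f"variable {variable!r} not present in {path}")
        da = ds[variable].load()
        da.attrs.update(ds.attrs)
    for coord in ("lat", "lon"):
        if coord not in da.coords:
            raise FormatError(f"missing coordinate {coord!r} in {path}")
        vals = da[coord].values
        d = np.diff(vals)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise FormatError(f"coordinate {coord!r} is not strictly monotone")
    units = str(da.attrs.get("units", ""))
    if units == "K":
        da = (da - KELVIN_OFFSET).assign_attrs({**da.attrs, "units": "degC"})
    return da


def _serializable(v):
    if isinstance(v, (tuple, list)):
        return list(v)
    return v


# --- CSV tables -----------------------------------------------------------


def write_econ_csv(econ: pd.DataFrame, path) -> None:
    econ[[c for c in ECON_SCHEMA if c in econ.columns]].to_csv(path, index=False)


def read_econ_csv(path, year_range: tuple[int, int] | None = None) -> pd.DataFrame:
    """Validated provincial economic table (complete, strictly positive)."""
    df = pd.read_csv(path)
    required = ECON_SCHEMA[:5]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise FormatError(f"econ CSV missing columns: {missing_cols}")
    problems = []
    numeric = [c for c in ECON_SCHEMA[2:] if c in df.columns]
    for col in numeric:
        bad = df[~(df[col] > 0)]
        problems += [f"non-positive {col} at ({r.province}, {r.year})" for r in bad.itertuples()]
    if year_range is None:
        year_range = (int(df["year"].min()), int(df["year"].max()))
    wanted = set(range(year_range[0], year_range[1] + 1))
    for prov, sub in df.groupby("province"):
        gaps = sorted(wanted - set(sub["year"]))
        problems += [f"missing ({prov}, {y})" for y in gaps]
    if problems:
        raise ValidationError("econ table validation failed: " + "; ".join(problems[:20]))
    return df


# --- run configuration ----------------------------------------------------


@dataclass
class RunConfig:
    """Everything a pipeline run needs, serializable to YAML losslessly."""

    seed: int = 0
    synth: SynthConfig = dc_field(default_factory=SynthConfig)
    rf: RFConfig = dc_field(default_factory=RFConfig)
    encoder: EncoderParams = dc_field(default_factory=EncoderParams)
    n_gcms: int = 6
    scenarios: list[str] = dc_field(default_factory=lambda: ["SSP126", "SSP245", "SSP370", "SSP585"])

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synth"]["event_injections"] = [
            dataclasses.asdict(e) if dataclasses.is_dataclass(e) else e
            for e in self.synth.event_injections
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        synth = d.get("synth", {})
        synth = {k: (tuple(v) if isinstance(v, list) and k in
                     ("years_obs", "years_base", "years_proj", "grid_shape") else v)
                 for k, v in synth.items()}
        inj = synth.pop("event_injections", [])
        from .config import EventInjection

        synth["event_injections"] = [
            EventInjection(**{**e, "cells": tuple(tuple(c) for c in e["cells"])}) for e in inj
        ]
        cfg = cls(
            seed=d.get("seed", 0),
            synth=SynthConfig(**synth),
            rf=RFConfig(**d.get("rf", {})),
            encoder=EncoderParams(**d.get("encoder", {})),
            n_gcms=d.get("n_gcms", 6),
            scenarios=list(d.get("scenarios", ["SSP126", "SSP245", "SSP370", "SSP585"])),
        )
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise ConfigurationError(f"config file {path} is not a mapping")
        return cls.from_dict(d)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def write_report(obj: dict, path, config_hash: str) -> None:
    payload = {"config_hash": config_hash, **obj}
    Path(path).write_text(json.dumps(payload, indent=2, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
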