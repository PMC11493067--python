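"""End-to-end drivers: observation-period fit and scenario projection.

The observation fit chains the full method: detect extreme-temperature
events, train one autoencoder per climate variable on per-province fields,
assemble 36-feature cases, split 80/20, grid-search the forest, and evaluate
against the two benchmarks on the shared test partition.  The projection
driver reuses every fitted component (thresholds regridded to the scenario
grid, observation-period encoders and normalizers, the tuned forest) with
economics frozen at the last observed year.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .autoencoder import ConvolutionalAutoencoder
from .benchmarks import fit_b2rf_ablation, fit_fgls_loglog
from .config import CLIMATE_VARS, ResponseSpec, SynthConfig
from .extremes import CW, HW, ExtremeEventDetector
from .features import (
    FEATURE_ORDER,
    MinMaxTransform,
    assemble_case_table,
    spatial_mean_case_table,
    split_dataset,
)
from .grids import (
    interp_to_axes,
    province_field,
    province_spatial_mean,
    select_years,
    union_crop_shape,
)
from .metrics import EvalReport, evaluate_predictions
from .regression import RFConfig, TunedForestRegressor, aggregate_importance, fit_primary_rf
from .synth import (
    gen_daily_temperature_grid,
    gen_economic_table,
    gen_monthly_climate_grid,
    gen_production,
)

MONTHLY_VARS = ("tas", "pr")
ANNUAL_VARS = ("hw_freq", "cw_freq")


# --------------------------------------------------------------------------
# per-province field stacks
# --------------------------------------------------------------------------


def province_year_fields(da: xr.DataArray, provinces, pad_shape) -> tuple[list, np.ndarray]:
    """Crop/mask/pad a gridded field into one array per (province, year).

    Annual grids yield (n, H, W) stacks; monthly grids yield (n, 12, H, W)
    calendar-year blocks.  Returns (keys, stack) with keys as
    (province, year) tuples in a fixed order.
    """
    lat, lon = da["lat"].values, da["lon"].values
    keys, fields = [], []
    if "year" in da.dims:  # annual grid
        for box in provinces:
            for y in da["year"].values:
                keys.append((box.name, int(y)))
                fields.append(
                    province_field(da.sel(year=y).values, lat, lon, box, pad_shape)
                )
        return keys, np.stack(fields)
    years = np.unique(da["year"].values)
    for box in provinces:
        for y in years:
            block = da.isel(time=da["year"].values == y).values  # (12, H, W)
            keys.append((box.name, int(y)))
            fields.append(
                np.stack([province_field(b, lat, lon, box, pad_shape) for b in block])
            )
    return keys, np.stack(fields)


def encode_province_fields(
    encoder: ConvolutionalAutoencoder, da: xr.DataArray, provinces, pad_shape, variable: str
) -> pd.DataFrame:
    """Long-format code table (province, year, variable, c0..c7)."""
    keys, stack = province_year_fields(da, provinces, pad_shape)
    codes = encoder.transform(stack)
    out = pd.DataFrame(codes, columns=[f"c{i}" for i in range(codes.shape[1])])
    out.insert(0, "province", [k[0] for k in keys])
    out.insert(1, "year", [k[1] for k in keys])
    out.insert(2, "variable", variable)
    return out


def climate_spatial_means(grids: dict[str, xr.DataArray], provinces) -> pd.DataFrame:
    """Province-year spatial summaries: mean hw/cw/tas, annual total pr (mm)."""
    frames = []
    for box in provinces:
        row = {}
        for var in ANNUAL_VARS:
            m = province_spatial_mean(grids[var], box)
            row[var] = pd.Series(m.values, index=m["year"].values)
        for var in MONTHLY_VARS:
            m = province_spatial_mean(grids[var], box)
            s = pd.Series(m.values, index=m["year"].values)
            agg = s.groupby(level=0).sum() if var == "pr" else s.groupby(level=0).mean()
            row[var] = agg
        df = pd.DataFrame(row)
        df.index.name = "year"
        df = df.reset_index()
        df.insert(0, "province", box.name)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------------
# observation fit
# --------------------------------------------------------------------------


@dataclass
class EncoderParams:
    """Desk-scale training schedule shared by the four encoder instances."""

    epochs: int = 60
    batch_size: int = 16
    learning_rate: float = 1e-3
    hidden_dim: int = 64
    code_dim: int = 8


@dataclass
class ObservationModel:
    """Every fitted component of the observation-period pipeline."""

    cfg: SynthConfig
    detectors: dict[str, ExtremeEventDetector]
    encoders: dict[str, ConvolutionalAutoencoder]
    transforms: dict[str, MinMaxTransform]
    pad_shape: tuple[int, int]
    econ: pd.DataFrame
    cases: pd.DataFrame
    cases8: pd.DataFrame
    train_index: pd.MultiIndex
    test_index: pd.MultiIndex
    rf: TunedForestRegressor
    reports: dict[str, EvalReport] = field(default_factory=dict)
    grids: dict[str, xr.DataArray] = field(default_factory=dict)

    @property
    def importance(self) -> pd.Series:
        return aggregate_importance(self.rf)


def synthesize_observations(
    cfg: SynthConfig, response: ResponseSpec
) -> tuple[dict[str, xr.DataArray], pd.DataFrame]:
    """Generate the full synthetic observation world (grids + economics)."""
    grids = {
        "tasmax": gen_daily_temperature_grid(cfg, "tasmax"),
        "tasmin": gen_daily_temperature_grid(cfg, "tasmin"),
        "tas": gen_monthly_climate_grid(cfg, "tas"),
        "pr": gen_monthly_climate_grid(cfg, "pr"),
    }
    econ = gen_economic_table(cfg)
    detectors = build_detectors(cfg)
    freq = {
        "hw_freq": detectors[HW].fit_transform(grids["tasmax"]),
        "cw_freq": detectors[CW].fit_transform(grids["tasmin"]),
    }
    obs_freq = {
        k: select_years(v, cfg.years_obs[0], cfg.years_obs[1]) for k, v in freq.items()
    }
    summaries = climate_spatial_means({**obs_freq, "tas": grids["tas"], "pr": grids["pr"]}, cfg.provinces())
    econ = econ.copy()
    prod = gen_production(econ, summaries, response, seed=cfg.seed)
    econ = econ.set_index(["province", "year"]).sort_index()
    econ["production_t"] = prod
    econ = econ.reset_index()
    grids.update(obs_freq)
    return grids, econ


def build_detectors(cfg: SynthConfig) -> dict[str, ExtremeEventDetector]:
    return {
        HW: ExtremeEventDetector(kind=HW, base_period=cfg.years_base),
        CW: ExtremeEventDetector(kind=CW, base_period=cfg.years_base),
    }


def fit_observation_model(
    cfg: SynthConfig,
    response: ResponseSpec | None = None,
    rf_cfg: RFConfig | None = None,
    encoder_params: EncoderParams | None = None,
    grids: dict[str, xr.DataArray] | None = None,
    econ: pd.DataFrame | None = None,
    with_benchmarks: bool = True,
) -> ObservationModel:
    """Fit the complete ConvAE-RF pipeline (on synthetic data by default)."""
    response = response or ResponseSpec()
    rf_cfg = rf_cfg or RFConfig(seed=cfg.seed)
    ep = encoder_params or EncoderParams()
    if grids is None or econ is None:
        grids, econ = synthesize_observations(cfg, response)
    detectors = build_detectors(cfg)
    detectors[HW].fit(grids["tasmax"])
    detectors[CW].fit(grids["tasmin"])
    provinces = cfg.provinces()
    pad_shape = union_crop_shape(cfg.lat, cfg.lon, provinces)
    encoders, code_frames = {}, []
    for vi, var in enumerate(CLIMATE_VARS):
        arch = "spatial" if var in ANNUAL_VARS else "spatiotemporal"
        enc = ConvolutionalAutoencoder(
            architecture=arch,
            code_dim=ep.code_dim,
            epochs=ep.epochs,
            batch_size=ep.batch_size,
            learning_rate=ep.learning_rate,
            hidden_dim=ep.hidden_dim,
            random_state=int(cfg.seed) * 10 + vi,
        )
        da = grids[var]
        if var in ANNUAL_VARS:
            da = select_years(da, cfg.years_obs[0], cfg.years_obs[1])
        keys, stack = province_year_fields(da, provinces, pad_shape)
        enc.fit(stack)
        encoders[var] = enc
        code_frames.append(encode_province_fields(enc, da, provinces, pad_shape, var))
    codes = pd.concat(code_frames, ignore_index=True)
    cases, transforms = assemble_case_table(econ, codes)
    means = climate_spatial_means(
        {k: (select_years(grids[k], *cfg.years_obs) if k in ANNUAL_VARS else grids[k]) for k in CLIMATE_VARS},
        provinces,
    )
    cases8, _ = spatial_mean_case_table(econ, means, transforms)
    train, test = split_dataset(cases, rf_cfg.split_fraction, rf_cfg.seed)
    rf = fit_primary_rf(train, rf_cfg)
    model = ObservationModel(
        cfg=cfg,
        detectors=detectors,
        encoders=encoders,
        transforms=transforms,
        pad_shape=pad_shape,
        econ=econ,
        cases=cases,
        cases8=cases8,
        train_index=train.index,
        test_index=test.index,
        rf=rf,
        grids=grids,
    )
    model.reports["ConvAE-RF"] = evaluate_predictions(
        test["production_t"], rf.predict(test[FEATURE_ORDER]), "ConvAE-RF"
    )
    if with_benchmarks:
        train8, test8 = cases8.loc[train.index], cases8.loc[test.index]
        fgls = fit_fgls_loglog(train8)
        b2 = fit_b2rf_ablation(train8, rf_cfg)
        from .benchmarks import BENCH_FEATURES

        model.reports["B1-FGLS"] = evaluate_predictions(
            test8["production_t"], fgls.predict(test8), "B1-FGLS"
        )
        model.reports["B2-RF"] = evaluate_predictions(
            test8["production_t"], b2.predict(test8[BENCH_FEATURES]), "B2-RF"
        )
    return model


# --------------------------------------------------------------------------
# scenario projection
# --------------------------------------------------------------------------


def _frozen_econ_features(model: ObservationModel, freeze_year: int | None = None) -> pd.DataFrame:
    """Normalized economic features per province, frozen at the freeze year."""
    year = freeze_year or int(model.cases.index.get_level_values("year").max())
    frozen = model.cases.xs(year, level="year")[list(FEATURE_ORDER[:4])]
    return frozen


def project_scenario(
    model: ObservationModel,
    bundle: dict[str, dict[str, xr.DataArray]],
    scenario: str,
    freeze_year: int | None = None,
) -> pd.DataFrame:
    """Per-GCM, per-province annual production projections for one scenario.

    Observation-period thresholds are regridded (bilinearly) to the scenario
    grid for event detection; frequency and monthly fields are interpolated
    back onto the observation axes before encoding, so the fitted encoder
    shapes apply unchanged.  Economic features (including dt) stay frozen.
    """
    cfg = model.cfg
    provinces = cfg.provinces()
    frozen = _frozen_econ_features(model, freeze_year)
    rows = []
    for gcm, fields in bundle.items():
        freq = {
            "hw_freq": model.detectors[HW].transform(fields["tasmax"]),
            "cw_freq": model.detectors[CW].transform(fields["tasmin"]),
        }
        coarse = {
            var: interp_to_axes(freq[var].astype(float), cfg.lat, cfg.lon)
            for var in ANNUAL_VARS
        }
        for var in MONTHLY_VARS:
            coarse[var] = interp_to_axes(fields[var], cfg.lat, cfg.lon)
        code_frames = [
            encode_province_fields(model.encoders[var], coarse[var], provinces, model.pad_shape, var)
            for var in CLIMATE_VARS
        ]
        codes = pd.concat(code_frames, ignore_index=True)
        wide = {
            var: codes[codes["variable"] == var].set_index(["province", "year"])
            for var in CLIMATE_VARS
        }
        years = sorted(set(wide["hw_freq"].index.get_level_values("year")))
        feats = []
        keys = []
        for box in provinces:
            for y in years:
                row = frozen.loc[box.name].to_dict()
                for var in CLIMATE_VARS:
                    cvec = wide[var].loc[(box.name, y)]
                    for i in range(8):
                        row[f"{var}_c{i}"] = float(cvec[f"c{i}"])
                feats.append(row)
                keys.append((box.name, y))
        X = pd.DataFrame(feats)[FEATURE_ORDER]
        pred = model.rf.predict(X)
        for (prov, y), p in zip(keys, pred):
            rows.append(
                {"scenario": scenario, "gcm": gcm, "province": prov, "year": int(y), "prediction_t": float(p)}
            )
    return pd.DataFrame(rows)


def region_total(projection: pd.DataFrame) -> pd.DataFrame:
    """Region-total production per (gcm, year), wide (year x gcm)."""
    tot = projection.groupby(["gcm", "year"])["prediction_t"].sum().reset_index()
    return tot.pivot(index="year", columns="gcm", values="prediction_t")
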