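"""Case assembly: economic indices + autoencoder codes -> 36-feature cases.

Each province-year case carries four economic features (min-max-normalized
sown area, primary-industry employment, machinery power, plus the raw time
dummy ``dt`` in years since the first observation year) and 8 codes for each
of the four climate variables (hw_freq, cw_freq, tas, pr): 36 features total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .config import CLIMATE_VARS
from .grids import AlignmentError

ECON_RAW = ("sown_area_kha", "prim_ind_k", "mech_power_gw")
ECON_FEATURES = ("SownArea", "PrimInd", "MechPower", "dt")
#: canonical 36-feature column order (documented contract for importances)
FEATURE_ORDER = list(ECON_FEATURES) + [
    f"{var}_c{i}" for var in CLIMATE_VARS for i in range(8)
]
VARIABLE_OF_FEATURE = {
    **{name: name for name in ECON_FEATURES},
    **{f"{var}_c{i}": var for var in CLIMATE_VARS for i in range(8)},
}
TARGET = "production_t"


class DegenerateScaleWarning(UserWarning):
    pass


@dataclass(frozen=True)
class MinMaxTransform:
    """Recorded affine [0, 1] normalization, reusable on projection inputs."""

    vmin: float
    vmax: float

    def transform(self, x):
        x = np.asarray(x, dtype=float)
        span = self.vmax - self.vmin
        if span == 0:
            return np.zeros_like(x)
        return (x - self.vmin) / span

    def inverse(self, z):
        return np.asarray(z, dtype=float) * (self.vmax - self.vmin) + self.vmin


def normalize_minmax(series) -> tuple[np.ndarray, MinMaxTransform]:
    """Map a series affinely onto [0, 1]; constant series map to 0 (warned)."""
    x = np.asarray(series, dtype=float)
    t = MinMaxTransform(float(np.min(x)), float(np.max(x)))
    if t.vmax == t.vmin:
        warnings.warn(
            "constant series: min-max scale degenerate, mapping to 0",
            DegenerateScaleWarning,
        )
    return t.transform(x), t


def assemble_case_table(
    econ: pd.DataFrame,
    codes: pd.DataFrame,
    transforms: dict[str, MinMaxTransform] | None = None,
) -> tuple[pd.DataFrame, dict[str, MinMaxTransform]]:
    """Join economics and per-variable code vectors into the case table.

    Parameters
    ----------
    econ
        Columns province, year, sown_area_kha, prim_ind_k, mech_power_gw and
        (optionally) production_t.
    codes
        Long format: columns province, year, variable, c0..c7 with one row
        per (province, year, climate variable).
    transforms
        Previously recorded min-max transforms (e.g. the observation-period
        fit, reused for projection inputs).  When None, transforms are
        learned from ``econ``.

    Returns
    -------
    (cases, transforms)
        ``cases`` is indexed by (province, year) with columns FEATURE_ORDER
        (+ production_t if available).
    """
    e = econ.set_index(["province", "year"]).sort_index()
    code_cols = [f"c{i}" for i in range(8)]
    missing = []
    wide = {}
    for var in CLIMATE_VARS:
        sub = codes[codes["variable"] == var].set_index(["province", "year"])[code_cols]
        gap = e.index.difference(sub.index)
        missing += [(p, y, var) for p, y in gap]
        wide[var] = sub
    if missing:
        raise AlignmentError(
            f"missing code vectors for {len(missing)} (province, year, variable) "
            f"keys: {missing[:10]}"
        )
    first_year = int(e.index.get_level_values("year").min())
    out = pd.DataFrame(index=e.index)
    fitted = {}
    for feat, raw in zip(ECON_FEATURES[:3], ECON_RAW):
        if transforms is not None:
            t = transforms[feat]
            out[feat] = t.transform(e[raw].values)
        else:
            out[feat], t = normalize_minmax(e[raw].values)
        fitted[feat] = t
    out["dt"] = e.index.get_level_values("year") - first_year
    for var in CLIMATE_VARS:
        block = wide[var].reindex(e.index)
        for i in range(8):
            out[f"{var}_c{i}"] = block[f"c{i}"].values
    if TARGET in e.columns:
        out[TARGET] = e[TARGET]
    return out, (transforms if transforms is not None else fitted)


def split_dataset(
    cases: pd.DataFrame, split_fraction: float = 0.8, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random, seed-reproducible split over province-year keys.

    Rounding follows scikit-learn: the test set gets ceil((1 - f) * n) cases
    (192 cases at f = 0.8 -> 153 train / 39 test).
    """
    if not 0.0 < split_fraction < 1.0:
        raise ValueError("split_fraction must be in (0, 1)")
    keys = np.array(sorted(cases.index.tolist(), key=str))
    train_keys, test_keys = train_test_split(
        keys, train_size=split_fraction, random_state=seed, shuffle=True
    )
    to_index = lambda arr: pd.MultiIndex.from_tuples(
        [(p, int(y)) for p, y in arr], names=["province", "year"]
    )
    return cases.loc[to_index(train_keys)], cases.loc[to_index(test_keys)]


def spatial_mean_case_table(
    econ: pd.DataFrame,
    climate_means: pd.DataFrame,
    transforms: dict[str, MinMaxTransform] | None = None,
) -> tuple[pd.DataFrame, dict[str, MinMaxTransform]]:
    """8-feature cases (4 econ + 4 spatial-mean climate) for the benchmarks.

    ``climate_means`` carries columns province, year, hw_freq, cw_freq, tas,
    pr (province spatial means).
    """
    e = econ.set_index(["province", "year"]).sort_index()
    c = climate_means.set_index(["province", "year"]).sort_index()
    gap = e.index.difference(c.index)
    if len(gap):
        raise AlignmentError(f"missing climate means for keys: {list(gap)[:10]}")
    first_year = int(e.index.get_level_values("year").min())
    out = pd.DataFrame(index=e.index)
    fitted = {}
    for feat, raw in zip(ECON_FEATURES[:3], ECON_RAW):
        if transforms is not None:
            t = transforms[feat]
            out[feat] = t.transform(e[raw].values)
        else:
            out[feat], t = normalize_minmax(e[raw].values)
        fitted[feat] = t
    out["dt"] = e.index.get_level_values("year") - first_year
    for var in CLIMATE_VARS:
        out[var] = c.reindex(e.index)[var].values
    # raw (positive) economic levels kept for the log-log benchmark design
    for raw in ECON_RAW:
        out[raw] = e[raw]
    if TARGET in e.columns:
        out[TARGET] = e[TARGET]
    return out, (transforms if transforms is not None else fitted)
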