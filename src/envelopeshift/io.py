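"""NetCDF and CSV input/output.

Grids travel as CF-style NetCDF (scipy backend, netCDF3): ``time``/
``lat``/``lon`` dims, ``units`` attributes (``degC``, ``mm``), float32
storage.  Occurrences travel as CSV with columns ``species``, ``lon``,
``lat``; the reader validates names and coordinate ranges and reports
the offending row on failure.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

_ENGINE = "scipy"


def write_grid(da: xr.DataArray, path) -> None:
    name = da.name or da.attrs.get("variable", "data")
    ds = da.to_dataset(name=name)
    enc = {name: {"dtype": "float32"}}
    ds.to_netcdf(path, engine=_ENGINE, encoding=enc)


def read_grid(path) -> xr.DataArray:
    ds = xr.open_dataset(path, engine=_ENGINE)
    names = [n for n in ds.data_vars]
    if len(names) != 1:
        raise ValueError(f"{path}: expected a single variable, found {names}")
    da = ds[names[0]].load()
    ds.close()
    if "units" not in da.attrs:
        raise ValueError(f"{path}: variable {names[0]!r} lacks a units attribute")
    return da


def write_dataset(ds: xr.Dataset, path, float32: bool = True) -> None:
    enc = {}
    if float32:
        enc = {name: {"dtype": "float32"} for name in ds.data_vars
               if np.issubdtype(ds[name].dtype, np.floating)}
    ds.to_netcdf(path, engine=_ENGINE, encoding=enc)


def read_dataset(path) -> xr.Dataset:
    ds = xr.open_dataset(path, engine=_ENGINE).load()
    ds.close()
    return ds


def write_occurrences(occ: pd.DataFrame, path) -> None:
    occ[["species", "lon", "lat"]].to_csv(path, index=False)


def read_occurrences(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"species", "lon", "lat"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    for col, lo, hi in (("lon", -180.0, 360.0), ("lat", -90.0, 90.0)):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < lo) | (vals > hi)
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0])
            raise ValueError(
                f"{path}: malformed {col} at data row {row + 1}: "
                f"{df[col].iloc[row]!r}")
        df[col] = vals
    return df[["species", "lon", "lat"]]


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
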