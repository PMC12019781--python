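"""Grid conventions and small helpers shared across the pipeline.

A monthly climate grid is an :class:`xarray.DataArray` with dims
``("time", "lat", "lon")``, a monthly ``time`` axis (month starts,
``datetime64``), cell-center WGS84 coordinates, and attrs ``variable``
(``"temperature"`` | ``"precipitation"``) and ``units`` (``"degC"`` |
``"mm"``).  A 12-month climatology uses dims ``("month", "lat", "lon")``
with ``month`` = 1..12.  Computation is float64; storage is float32.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr

TEMPERATURE = "temperature"
PRECIPITATION = "precipitation"

UNITS = {TEMPERATURE: "degC", PRECIPITATION: "mm"}


def monthly_time_index(year_start: int, year_end: int) -> pd.DatetimeIndex:
    """Consecutive month starts covering the inclusive year range."""
    if year_end < year_start:
        raise ValueError(f"empty year range {year_start}..{year_end}")
    return pd.date_range(f"{year_start}-01-01", f"{year_end}-12-01", freq="MS")


def make_grid(values: np.ndarray, time: pd.DatetimeIndex, lat: np.ndarray,
              lon: np.ndarray, variable: str) -> xr.DataArray:
    if variable not in UNITS:
        raise ValueError(f"unknown variable {variable!r}")
    da = xr.DataArray(
        np.asarray(values, dtype=np.float64),
        dims=("time", "lat", "lon"),
        coords={"time": time, "lat": np.asarray(lat, float), "lon": np.asarray(lon, float)},
        name=variable,
        attrs={"variable": variable, "units": UNITS[variable]},
    )
    return da


def make_climatology(values: np.ndarray, lat: np.ndarray, lon: np.ndarray,
                     variable: str) -> xr.DataArray:
    da = xr.DataArray(
        np.asarray(values, dtype=np.float64),
        dims=("month", "lat", "lon"),
        coords={"month": np.arange(1, 13), "lat": np.asarray(lat, float),
                "lon": np.asarray(lon, float)},
        name=variable,
        attrs={"variable": variable, "units": UNITS[variable]},
    )
    return da


def validate_monthly_grid(da: xr.DataArray) -> None:
    """Raise ValueError on malformed monthly climate grids."""
    if tuple(da.dims) != ("time", "lat", "lon"):
        raise ValueError(f"expected dims (time, lat, lon), got {da.dims}")
    t = pd.DatetimeIndex(da.time.values)
    if len(t) == 0:
        raise ValueError("empty time axis")
    expected = pd.date_range(t[0], periods=len(t), freq="MS")
    if not t.equals(expected):
        raise ValueError("time axis must be consecutive calendar months")
    var = da.attrs.get("variable")
    vals = da.values
    if var == PRECIPITATION and np.nanmin(vals) < 0:
        raise ValueError("precipitation must be non-negative")
    if not np.all(np.isfinite(vals) | np.isnan(vals)):
        raise ValueError("non-finite values in grid")


def climatology_of(da: xr.DataArray) -> xr.DataArray:
    """12-month mean climatology of a monthly series (keeps attrs)."""
    clim = da.groupby("time.month").mean("time")
    clim.attrs.update(da.attrs)
    return clim


def subset_years(da: xr.DataArray, year_start: int, year_end: int) -> xr.DataArray:
    sel = da.sel(time=slice(f"{year_start}-01-01", f"{year_end}-12-31"))
    if sel.sizes["time"] != 12 * (year_end - year_start + 1):
        raise ValueError(
            f"series does not fully cover {year_start}-{year_end}")
    return sel


def same_grid(a: xr.DataArray, b: xr.DataArray, tol: float = 1e-8) -> bool:
    return (a.sizes.get("lat") == b.sizes.get("lat")
            and a.sizes.get("lon") == b.sizes.get("lon")
            and np.allclose(a.lat.values, b.lat.values, atol=tol)
            and np.allclose(a.lon.values, b.lon.values, atol=tol))
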