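"""Superimposition of AMOC-collapse anomalies onto climate projections.

The collapse is represented by 12 monthly anomaly maps: additive
surface-air-temperature anomalies (SAT, degC) and relative precipitation
anomalies (RPA, a fraction, so precipitation is scaled by ``1 + RPA``).
They are applied as a step change over a single climate-normal period
(2071-2100 by default), after quantile mapping; months outside the
period pass through unchanged.
"""

from __future__ import annotations

import numpy as np
import xarray as xr

from .grids import PRECIPITATION, TEMPERATURE, make_grid

DEFAULT_PERIOD = (2071, 2100)


def validate_anomalies(anomalies: xr.Dataset) -> None:
    for name in ("sat", "rpa"):
        if name not in anomalies:
            raise ValueError(f"anomaly dataset lacks {name!r}")
        da = anomalies[name]
        if "month" not in da.dims or da.sizes["month"] != 12:
            raise ValueError(f"{name} must have exactly 12 months")
        if not np.all(np.isfinite(da.values)):
            raise ValueError(f"non-finite values in {name}")
    if anomalies["rpa"].values.min() < -1.0 - 1e-12:
        raise ValueError("RPA below -1 would remove more than all precipitation")


def regrid_anomalies(anomalies: xr.Dataset, lat: np.ndarray, lon: np.ndarray,
                     method: str = "linear") -> xr.Dataset:
    """Interpolate anomaly maps to a target grid (bilinear by default)."""
    out = anomalies.interp(lat=lat, lon=lon, method=method,
                           kwargs={"fill_value": None})
    if np.isnan(out["sat"].values).any() or np.isnan(out["rpa"].values).any():
        # target extends beyond the anomaly extent: nearest-edge fill
        out = out.ffill("lat").bfill("lat").ffill("lon").bfill("lon")
    return out


def superimpose_anomalies(series: xr.DataArray, anomalies: xr.Dataset,
                          period: tuple[int, int] = DEFAULT_PERIOD,
                          regrid: str = "linear") -> xr.DataArray:
    """Apply SAT/RPA to a monthly series within the collapse period.

    Temperature gets the matching calendar month's SAT added;
    precipitation is multiplied by ``1 + RPA`` and floored at zero.
    """
    validate_anomalies(anomalies)
    anom = anomalies
    if not (np.array_equal(anom.lat.values, series.lat.values)
            and np.array_equal(anom.lon.values, series.lon.values)):
        anom = regrid_anomalies(anomalies, series.lat.values, series.lon.values,
                                method=regrid)
        if anom.sizes["lat"] != series.sizes["lat"] or \
                anom.sizes["lon"] != series.sizes["lon"]:
            raise ValueError("grid mismatch after regridding")
    years = series.time.dt.year.values
    months = series.time.dt.month.values
    in_period = (years >= period[0]) & (years <= period[1])
    variable = series.attrs.get("variable", TEMPERATURE)
    vals = series.values.copy()
    field = anom["sat"].values if variable == TEMPERATURE else anom["rpa"].values
    for t in np.nonzero(in_period)[0]:
        m = months[t] - 1
        if variable == TEMPERATURE:
            vals[t] = vals[t] + field[m]
        else:
            vals[t] = np.maximum(vals[t] * (1.0 + field[m]), 0.0)
    return make_grid(vals, series.time.to_index(), series.lat.values,
                     series.lon.values, variable)
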