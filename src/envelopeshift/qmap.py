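"""Empirical quantile mapping of model series onto observed series.

Bias correction is fitted per grid cell and calendar month: the
empirical quantiles of the model and observed series over a calibration
window are paired at a fixed probability ladder, and applying the map
moves a model value to the observed quantile of the same (linearly
interpolated) probability.  Beyond the calibrated range the correction
is held constant — as an additive offset for temperature and a
multiplicative ratio for precipitation — which avoids runaway
extrapolation while preserving projected trends.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr
from sklearn.base import BaseEstimator, TransformerMixin

from .grids import PRECIPITATION, make_grid, same_grid, subset_years

DEFAULT_LADDER = np.linspace(0.01, 0.99, 99)
DEFAULT_CALIBRATION = (1951, 2014)
MIN_CALIBRATION_YEARS = 10


class QuantileMapper(BaseEstimator, TransformerMixin):
    """Per-cell, per-calendar-month empirical quantile mapping.

    Parameters
    ----------
    calibration_years : (int, int)
        Inclusive year range both series must cover.
    ladder : array of probabilities
        Quantile levels; 99 evenly spaced points 0.01..0.99 by default,
        stable for the 30-70 samples a monthly calibration window yields.

    Fitted attributes
    -----------------
    model_quantiles_, observed_quantiles_ : ndarray (12, n_prob, ny, nx)
    kind_ : "additive" | "multiplicative" tail-correction arithmetic
    """

    def __init__(self, calibration_years: tuple[int, int] = DEFAULT_CALIBRATION,
                 ladder: np.ndarray = DEFAULT_LADDER):
        self.calibration_years = calibration_years
        self.ladder = ladder

    def fit(self, observed: xr.DataArray,
            model_historic: xr.DataArray) -> "QuantileMapper":
        y0, y1 = self.calibration_years
        if y1 - y0 + 1 < MIN_CALIBRATION_YEARS:
            raise ValueError(
                f"calibration window {y0}-{y1} shorter than "
                f"{MIN_CALIBRATION_YEARS} years: too few samples per month")
        if not same_grid(observed, model_historic):
            raise ValueError("observed and model series are on different grids")
        obs = subset_years(observed, y0, y1)
        mod = subset_years(model_historic, y0, y1)
        prob = np.asarray(self.ladder, float)
        nq, ny, nx = prob.size, obs.sizes["lat"], obs.sizes["lon"]
        oq = np.empty((12, nq, ny, nx))
        mq = np.empty((12, nq, ny, nx))
        months = obs.time.dt.month.values
        for m in range(1, 13):
            sel = months == m
            oq[m - 1] = np.quantile(obs.values[sel], prob, axis=0)
            mq[m - 1] = np.quantile(mod.values[sel], prob, axis=0)
        self.observed_quantiles_ = oq
        self.model_quantiles_ = mq
        self.kind_ = ("multiplicative"
                      if observed.attrs.get("variable") == PRECIPITATION
                      else "additive")
        self.lat_ = observed.lat.values
        self.lon_ = observed.lon.values
        self.variable_ = observed.attrs.get("variable", "temperature")
        return self

    def transform(self, model_series: xr.DataArray) -> xr.DataArray:
        if not hasattr(self, "model_quantiles_"):
            raise RuntimeError("quantile mapper is not fitted")
        if not (np.allclose(model_series.lat.values, self.lat_)
                and np.allclose(model_series.lon.values, self.lon_)):
            raise ValueError("series grid does not match the fitted grid")
        vals = model_series.values
        out = np.empty_like(vals, dtype=float)
        months = model_series.time.dt.month.values
        ny, nx = self.lat_.size, self.lon_.size
        mult = self.kind_ == "multiplicative"
        for m in range(1, 13):
            tsel = np.nonzero(months == m)[0]
            if tsel.size == 0:
                continue
            for i in range(ny):
                for j in range(nx):
                    xq = self.model_quantiles_[m - 1, :, i, j]
                    yq = self.observed_quantiles_[m - 1, :, i, j]
                    v = vals[tsel, i, j]
                    out[tsel, i, j] = _map_values(v, xq, yq, mult)
        if mult:
            out = np.maximum(out, 0.0)
        res = make_grid(out, model_series.time.to_index(), self.lat_, self.lon_,
                        self.variable_)
        return res

    def to_dataset(self) -> xr.Dataset:
        """Serializable representation with the ladder as a coordinate."""
        coords = {"month": np.arange(1, 13), "prob": np.asarray(self.ladder, float),
                  "lat": self.lat_, "lon": self.lon_}
        dims = ("month", "prob", "lat", "lon")
        ds = xr.Dataset({"model_quantiles": (dims, self.model_quantiles_),
                         "observed_quantiles": (dims, self.observed_quantiles_)},
                        coords=coords,
                        attrs={"kind": self.kind_, "variable": self.variable_,
                               "calibration_years": list(self.calibration_years)})
        return ds

    @classmethod
    def from_dataset(cls, ds: xr.Dataset) -> "QuantileMapper":
        qm = cls(calibration_years=tuple(ds.attrs["calibration_years"]),
                 ladder=ds.prob.values)
        qm.model_quantiles_ = ds["model_quantiles"].values
        qm.observed_quantiles_ = ds["observed_quantiles"].values
        qm.kind_ = ds.attrs["kind"]
        qm.variable_ = ds.attrs["variable"]
        qm.lat_ = ds.lat.values
        qm.lon_ = ds.lon.values
        return qm


def _map_values(v: np.ndarray, xq: np.ndarray, yq: np.ndarray,
                multiplicative: bool) -> np.ndarray:
    """Map values through paired quantile tables with constant tail correction."""
    out = np.interp(v, xq, yq)
    lo = v < xq[0]
    hi = v > xq[-1]
    if multiplicative:
        r0 = yq[0] / xq[0] if xq[0] > 1e-9 else 1.0
        r1 = yq[-1] / xq[-1] if xq[-1] > 1e-9 else 1.0
        if lo.any():
            out[lo] = v[lo] * r0
        if hi.any():
            out[hi] = v[hi] * r1
    else:
        if lo.any():
            out[lo] = v[lo] + (yq[0] - xq[0])
        if hi.any():
            out[hi] = v[hi] + (yq[-1] - xq[-1])
    return out


def fit_quantile_map(observed: xr.DataArray, model_historic: xr.DataArray,
                     calibration_years: tuple[int, int] = DEFAULT_CALIBRATION
                     ) -> QuantileMapper:
    return QuantileMapper(calibration_years=calibration_years).fit(
        observed, model_historic)


def apply_quantile_map(model_series: xr.DataArray, qm: QuantileMapper) -> xr.DataArray:
    return qm.transform(model_series)


def ecdf_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Max vertical distance between the empirical CDFs of two samples."""
    a, b = np.sort(a), np.sort(b)
    grid = np.concatenate([a, b])
    fa = np.searchsorted(a, grid, side="right") / a.size
    fb = np.searchsorted(b, grid, side="right") / b.size
    return float(np.abs(fa - fb).max())
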