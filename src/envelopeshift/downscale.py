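"""Change-factor downscaling of coarse monthly climate to a fine grid.

For each fine cell the enclosing (nearest-center) coarse cell supplies a
monthly change factor relative to the coarse climatology; the factor is
added to (temperature) or multiplied onto (precipitation) the
high-resolution climatology.  This transfers the coarse grid's monthly
anomalies onto the fine grid while keeping the fine climatology's
topographic structure.
"""

from __future__ import annotations

import numpy as np
import xarray as xr
from sklearn.base import BaseEstimator, TransformerMixin

from .grids import PRECIPITATION, TEMPERATURE, make_grid

#: precipitation ratio cap and dry-climatology guard (mm/month)
RATIO_CAP = 5.0
DRY_CLIM_MM = 1.0


def _check_climatology(clim: xr.DataArray) -> None:
    if "month" not in clim.dims or clim.sizes["month"] != 12 or \
            not np.array_equal(clim.month.values, np.arange(1, 13)):
        raise ValueError("climatology must cover months 1..12")


def _nearest_index(fine: np.ndarray, coarse: np.ndarray, max_step: float) -> np.ndarray:
    idx = np.abs(fine[:, None] - coarse[None, :]).argmin(axis=1)
    if np.any(np.abs(fine - coarse[idx]) > max_step):
        raise ValueError("no spatial overlap between coarse and target grids")
    return idx


class ChangeFactorDownscaler(BaseEstimator, TransformerMixin):
    """Downscale a coarse monthly series onto a fine climatology grid.

    Parameters
    ----------
    kind : {"additive", "multiplicative", None}
        Anomaly arithmetic.  ``None`` (default) infers it from the series'
        ``variable`` attribute: temperature is additive, precipitation
        multiplicative with the ratio capped at ``ratio_cap`` and forced
        to 1 where the coarse climatology is drier than ``dry_clim_mm``.
    """

    def __init__(self, kind: str | None = None, ratio_cap: float = RATIO_CAP,
                 dry_clim_mm: float = DRY_CLIM_MM):
        self.kind = kind
        self.ratio_cap = ratio_cap
        self.dry_clim_mm = dry_clim_mm

    def fit(self, coarse_climatology: xr.DataArray,
            fine_climatology: xr.DataArray) -> "ChangeFactorDownscaler":
        _check_climatology(coarse_climatology)
        _check_climatology(fine_climatology)
        self.coarse_climatology_ = coarse_climatology
        self.fine_climatology_ = fine_climatology
        clat, clon = coarse_climatology.lat.values, coarse_climatology.lon.values
        flat, flon = fine_climatology.lat.values, fine_climatology.lon.values
        dlat = np.diff(clat).max() if clat.size > 1 else np.inf
        dlon = np.diff(clon).max() if clon.size > 1 else np.inf
        self.lat_index_ = _nearest_index(flat, clat, dlat)
        self.lon_index_ = _nearest_index(flon, clon, dlon)
        return self

    def transform(self, coarse: xr.DataArray) -> xr.DataArray:
        if not hasattr(self, "lat_index_"):
            raise RuntimeError("downscaler is not fitted")
        variable = coarse.attrs.get("variable", TEMPERATURE)
        kind = self.kind or ("multiplicative" if variable == PRECIPITATION
                             else "additive")
        midx = coarse.time.dt.month.values - 1
        cvals = coarse.values
        cclim = self.coarse_climatology_.values[midx]
        fclim = self.fine_climatology_.values[midx]
        li, lj = self.lat_index_, self.lon_index_
        if kind == "additive":
            anom = (cvals - cclim)[:, li][:, :, lj]
            fine = fclim + anom
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(cclim >= self.dry_clim_mm, cvals / np.maximum(cclim, 1e-12), 1.0)
            ratio = np.clip(ratio, 0.0, self.ratio_cap)
            fine = fclim * ratio[:, li][:, :, lj]
            fine = np.maximum(fine, 0.0)
        out = make_grid(fine, coarse.time.to_index(),
                        self.fine_climatology_.lat.values,
                        self.fine_climatology_.lon.values, variable)
        return out


def change_factor_downscale(coarse: xr.DataArray, fine_climatology: xr.DataArray,
                            coarse_climatology: xr.DataArray) -> xr.DataArray:
    """Functional wrapper over :class:`ChangeFactorDownscaler`."""
    return ChangeFactorDownscaler().fit(coarse_climatology, fine_climatology).transform(coarse)
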