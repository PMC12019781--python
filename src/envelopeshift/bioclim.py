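"""Bioclimatic variables from monthly temperature and water balance.

Seventeen variables summarise each 30-year climate normal: nine
temperature aggregates and eight climatic-water-balance (CWB =
precipitation - potential evapotranspiration) aggregates, including
seasonal integrations, the warmest/coldest/driest month, and two
continentality measures (standard deviation and range of the monthly
values over the annual cycle).  Each variable is computed per calendar
year and then averaged over the years of the period, so that extremes
(warmest month, driest month) are yearly extremes rather than artefacts
of a smoothed climatology.

PET follows Thornthwaite: a heat index accumulated from the monthly
temperature climatology, a cubic polynomial exponent, and a
day-length/month-length correction from solar geometry at each cell's
latitude.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import xarray as xr

from .grids import climatology_of, make_grid

TEMPERATURE_VARIABLES = (
    "t_ann", "t_djf", "t_mam", "t_jja", "t_son",
    "t_warmest", "t_coldest", "t_sd", "t_range",
)
CWB_VARIABLES = (
    "cwb_ann", "cwb_djf", "cwb_mam", "cwb_jja", "cwb_son",
    "cwb_driest", "cwb_sd", "cwb_range",
)
#: the canonical 17-variable catalogue
BIOCLIM_VARIABLES = TEMPERATURE_VARIABLES + CWB_VARIABLES

DAYS_IN_MONTH = np.array([31, 28.25, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
_MID_MONTH_DOY = np.array([15, 46, 74, 105, 135, 166, 196, 227, 258, 288, 319, 349])

HISTORIC = "historic"
_SSPS = ("SSP1-2.6", "SSP2-4.5", "SSP5-8.5")


@dataclass(frozen=True)
class PeriodDefinition:
    label: str
    years: tuple[int, int]
    scenario: str
    amoc_mode: str = "off"  # "on" | "off"

    def __post_init__(self):
        if self.years[1] - self.years[0] + 1 != 30:
            raise ValueError(f"{self.label}: climate normals span 30 years")
        if self.amoc_mode not in ("on", "off"):
            raise ValueError("amoc_mode must be 'on' or 'off'")


def period_catalogue() -> list[PeriodDefinition]:
    """The 14 scenario-periods: 2 historic, 9 standard projections
    (3 SSPs x 3 windows) and 3 AMOC-collapse runs in 2071-2100."""
    periods = [
        PeriodDefinition("historic_1951-1980", (1951, 1980), HISTORIC),
        PeriodDefinition("historic_1991-2020", (1991, 2020), HISTORIC),
    ]
    for ssp in _SSPS:
        for years in ((2021, 2050), (2046, 2075), (2071, 2100)):
            periods.append(PeriodDefinition(
                f"{ssp}_{years[0]}-{years[1]}", years, ssp))
    for ssp in _SSPS:
        periods.append(PeriodDefinition(
            f"{ssp}_2071-2100_amoc", (2071, 2100), ssp, amoc_mode="on"))
    return periods


def day_length_correction(lat: np.ndarray) -> np.ndarray:
    """Thornthwaite's (L/12)(N/30) factor, shape (12, nlat).

    L is the mean day length (hours) from solar declination at the
    mid-month day of year; N the number of days in the month.
    """
    lat = np.asarray(lat, float)
    phi = np.deg2rad(lat)[None, :]
    decl = 0.409 * np.sin(2 * np.pi / 365.0 * _MID_MONTH_DOY - 1.39)[:, None]
    cos_omega = np.clip(-np.tan(phi) * np.tan(decl), -1.0, 1.0)
    omega = np.arccos(cos_omega)
    day_hours = 24.0 / np.pi * omega
    return (day_hours / 12.0) * (DAYS_IN_MONTH[:, None] / 30.0)


def thornthwaite_pet(temperature: xr.DataArray,
                     latitude: np.ndarray | None = None,
                     apply_correction: bool = True,
                     heat_index_source: xr.DataArray | None = None
                     ) -> xr.DataArray:
    """Monthly potential evapotranspiration (mm/month).

    The heat index I = sum over the 12 climatological months of
    (T/5)^1.514 for T > 0; the exponent a is Thornthwaite's cubic in I;
    unadjusted PET = 16 (10 T / I)^a for T > 0, zero otherwise, scaled
    by the day-length correction unless ``apply_correction`` is False.
    """
    if latitude is None:
        if "lat" not in temperature.coords:
            raise ValueError("latitude required: series has no 'lat' coordinate")
        latitude = temperature.lat.values
    clim = climatology_of(heat_index_source
                          if heat_index_source is not None
                          else temperature).values  # (12, ny, nx)
    tpos = np.maximum(clim, 0.0)
    heat_index = np.sum((tpos / 5.0) ** 1.514, axis=0)  # (ny, nx)
    a = (6.75e-7 * heat_index ** 3 - 7.71e-5 * heat_index ** 2
         + 1.792e-2 * heat_index + 0.49239)
    t = temperature.values
    months = temperature.time.dt.month.values - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(heat_index > 0, 10.0 * np.maximum(t, 0.0)
                         / np.maximum(heat_index, 1e-12), 0.0)
        pet = np.where(t > 0, 16.0 * ratio ** a, 0.0)
    if apply_correction:
        corr = day_length_correction(latitude)  # (12, nlat)
        pet = pet * corr[months][:, :, None]
    out = make_grid(pet, temperature.time.to_index(), latitude,
                    temperature.lon.values, "precipitation")
    out.attrs.update(variable="pet", units="mm",
                     long_name="Thornthwaite potential evapotranspiration")
    return out


def monthly_cwb(precipitation: xr.DataArray, pet: xr.DataArray) -> xr.DataArray:
    """Climatic water balance: precipitation minus PET, mm/month."""
    if precipitation.sizes != pet.sizes or \
            not np.array_equal(precipitation.time.values, pet.time.values):
        raise ValueError("precipitation and PET axes are misaligned")
    cwb = xr.DataArray(precipitation.values - pet.values,
                       dims=precipitation.dims, coords=precipitation.coords,
                       name="cwb",
                       attrs={"variable": "cwb", "units": "mm",
                              "long_name": "climatic water balance"})
    return cwb


_SEASONS = {"djf": (12, 1, 2), "mam": (3, 4, 5), "jja": (6, 7, 8),
            "son": (9, 10, 11)}


def _yearly_stats(values: np.ndarray, years: np.ndarray, months: np.ndarray,
                  period: tuple[int, int], aggregate: str) -> dict[str, np.ndarray]:
    """Per-year statistics averaged over the period; values (T, ny, nx).

    ``aggregate`` is "mean" for temperature and "sum" for CWB.  DJF takes
    December from the preceding calendar year; the first year's DJF is
    skipped when that December is not in the series.
    """
    y0, y1 = period
    agg = np.mean if aggregate == "mean" else np.sum
    per_year: dict[str, list[np.ndarray]] = {
        k: [] for k in ("ann", "djf", "mam", "jja", "son",
                        "high", "low", "sd", "range")}
    for y in range(y0, y1 + 1):
        sel = np.nonzero(years == y)[0]
        if sel.size != 12:
            raise ValueError(f"incomplete year {y} in series")
        v = values[sel]  # calendar-ordered by construction
        per_year["ann"].append(agg(v, axis=0))
        for season, mm in _SEASONS.items():
            if season == "djf":
                dec = np.nonzero((years == y - 1) & (months == 12))[0]
                if dec.size == 0:
                    continue
                block = np.stack([values[dec[0]], v[0], v[1]])
            else:
                block = v[[m - 1 for m in mm]]
            per_year[season].append(agg(block, axis=0))
        per_year["high"].append(v.max(axis=0))
        per_year["low"].append(v.min(axis=0))
        per_year["sd"].append(v.std(axis=0, ddof=1))
        per_year["range"].append(v.max(axis=0) - v.min(axis=0))
    return {k: np.mean(np.stack(vlist), axis=0) for k, vlist in per_year.items()
            if vlist}


def compute_bioclim(temperature: xr.DataArray, precipitation: xr.DataArray,
                    period: PeriodDefinition | tuple[int, int],
                    variables: Sequence[str] | None = None,
                    model: str | None = None) -> xr.Dataset:
    """17-variable bioclimatic stack averaged over one climate normal.

    ``variables`` restricts the catalogue (default: all 17).  The input
    series must cover the period's 30 calendar years; a December of the
    year before the period is used for the first year's DJF if present.
    """
    if isinstance(period, PeriodDefinition):
        years_range, label = period.years, period.label
    else:
        years_range, label = tuple(period), f"{period[0]}-{period[1]}"
    catalogue = tuple(variables) if variables is not None else BIOCLIM_VARIABLES
    unknown = set(catalogue) - set(BIOCLIM_VARIABLES)
    if unknown:
        raise ValueError(f"unknown variables: {sorted(unknown)}")

    y0, y1 = years_range
    # keep a leading December if the series has it
    t_sel = temperature.sel(time=slice(f"{y0 - 1}-12-01", f"{y1}-12-31"))
    p_sel = precipitation.sel(time=slice(f"{y0 - 1}-12-01", f"{y1}-12-31"))
    t_period = temperature.sel(time=slice(f"{y0}-01-01", f"{y1}-12-31"))
    if t_period.sizes["time"] != 30 * 12:
        raise ValueError(f"series does not cover {y0}-{y1} completely")
    # heat index from the period's own 30-year climatology (stable,
    # Thornthwaite's standard usage; excludes any leading December)
    pet = thornthwaite_pet(t_sel, heat_index_source=t_period)
    cwb = monthly_cwb(p_sel, pet)

    years = pd.DatetimeIndex(t_sel.time.values).year.values
    months = pd.DatetimeIndex(t_sel.time.values).month.values
    tstats = _yearly_stats(t_sel.values, years, months, years_range, "mean")
    cstats = _yearly_stats(cwb.values, years, months, years_range, "sum")

    fields = {
        "t_ann": tstats["ann"], "t_djf": tstats["djf"], "t_mam": tstats["mam"],
        "t_jja": tstats["jja"], "t_son": tstats["son"],
        "t_warmest": tstats["high"], "t_coldest": tstats["low"],
        "t_sd": tstats["sd"], "t_range": tstats["range"],
        "cwb_ann": cstats["ann"], "cwb_djf": cstats["djf"],
        "cwb_mam": cstats["mam"], "cwb_jja": cstats["jja"],
        "cwb_son": cstats["son"], "cwb_driest": cstats["low"],
        "cwb_sd": cstats["sd"], "cwb_range": cstats["range"],
    }
    ds = xr.Dataset(
        {name: (("lat", "lon"), fields[name]) for name in catalogue},
        coords={"lat": temperature.lat.values, "lon": temperature.lon.values},
        attrs={"period": label, "model": model or "",
               "years": f"{y0}-{y1}"},
    )
    for name in catalogue:
        ds[name].attrs["units"] = "degC" if name.startswith("t_") else "mm"
    return ds
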