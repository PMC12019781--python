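"""Synthetic study world: climate series, model biases, AMOC anomalies,
and species occurrences drawn from known climate envelopes.

The generator emulates the structure of the real inputs — a coarse
gridded observational series, several pseudo-GCM series with additive
temperature and multiplicative precipitation biases plus scenario
trends, a high-resolution monthly climatology with sub-coarse-cell
topographic detail, monthly AMOC-collapse anomaly maps with strong
northern cooling and drying, and occurrence records sampled from a
product of per-variable Gaussian suitabilities — so that every
downstream stage (downscaling, quantile mapping, overlay, bioclim
derivation, envelope calibration, evaluation) can be exercised and its
behaviour checked against known ground truth.

All randomness flows through named integer seeds in the configuration;
no global random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from .grids import (PRECIPITATION, TEMPERATURE, make_climatology, make_grid,
                    monthly_time_index)

HISTORIC = "historic"
SSP126 = "SSP1-2.6"
SSP245 = "SSP2-4.5"
SSP585 = "SSP5-8.5"
SCENARIOS = (SSP126, SSP245, SSP585)


@dataclass(frozen=True)
class ModelBias:
    """Systematic error of one pseudo-GCM relative to the observations."""
    temp_offset: float = 0.0        # additive, degC
    precip_factor: float = 1.0      # multiplicative
    variance_inflation: float = 1.0  # scales the noise standard deviation


@dataclass(frozen=True)
class ScenarioTrend:
    """Forced trend applied from the first projection year onward."""
    warming_per_decade: float       # degC / decade
    precip_pct_per_decade: float    # % / decade (multiplicative ramp)


@dataclass(frozen=True)
class AmocSpec:
    """Shape of the AMOC-collapse anomaly fields.

    ``max_cooling`` is the most negative surface-air-temperature anomaly
    (degC, reached at the northern edge in winter); ``precip_reduction``
    is the strongest relative precipitation loss as a positive fraction
    (0.3 = -30%); ``gradient_power`` controls how sharply anomalies decay
    southward (higher = more concentrated in the north).
    """
    max_cooling: float = -8.0
    precip_reduction: float = 0.3
    gradient_power: float = 2.0


@dataclass
class SyntheticWorldConfig:
    grid_nx: int = 20
    grid_ny: int = 20
    lon_min: float = -10.0
    lon_max: float = 30.0
    lat_min: float = 35.0
    lat_max: float = 70.0
    fine_factor: int = 3
    elevation_seed: int = 11
    climate_seed: int = 22
    species_seed: int = 33
    years_historic: tuple[int, int] = (1951, 2020)
    years_future: tuple[int, int] = (2021, 2100)
    n_models: int = 3
    bias_specs: Sequence[ModelBias] = ()
    trend_specs: Mapping[str, ScenarioTrend] = field(default_factory=dict)
    amoc_spec: AmocSpec = field(default_factory=AmocSpec)
    noise_sd_temp: float = 1.0      # degC, monthly
    noise_cv_precip: float = 0.25   # lognormal sigma of multiplicative noise

    def __post_init__(self) -> None:
        if self.grid_nx < 2 or self.grid_ny < 2:
            raise ValueError("degenerate grid extent: need at least 2x2 cells")
        if not (self.lon_max > self.lon_min and self.lat_max > self.lat_min):
            raise ValueError("degenerate lon/lat extent")
        if self.n_models < 2:
            raise ValueError("need n_models >= 2 for ensemble statistics")
        if self.years_historic[1] < self.years_historic[0]:
            raise ValueError("empty historic year range")
        if not self.bias_specs:
            rng = np.random.default_rng(np.random.SeedSequence([self.climate_seed, 77]))
            self.bias_specs = tuple(
                ModelBias(temp_offset=float(rng.uniform(-2.0, 2.0)),
                          precip_factor=float(rng.uniform(0.8, 1.3)),
                          variance_inflation=float(rng.uniform(0.9, 1.2)))
                for _ in range(self.n_models))
        if len(self.bias_specs) != self.n_models:
            raise ValueError("bias_specs length must equal n_models")
        if not self.trend_specs:
            self.trend_specs = {
                SSP126: ScenarioTrend(0.15, -0.3),
                SSP245: ScenarioTrend(0.30, -0.7),
                SSP585: ScenarioTrend(0.55, -1.5),
            }

    # -- grid geometry -------------------------------------------------
    def coarse_axes(self) -> tuple[np.ndarray, np.ndarray]:
        lon = _cell_centers(self.lon_min, self.lon_max, self.grid_nx)
        lat = _cell_centers(self.lat_min, self.lat_max, self.grid_ny)
        return lat, lon

    def fine_axes(self) -> tuple[np.ndarray, np.ndarray]:
        lon = _cell_centers(self.lon_min, self.lon_max, self.grid_nx * self.fine_factor)
        lat = _cell_centers(self.lat_min, self.lat_max, self.grid_ny * self.fine_factor)
        return lat, lon

    @property
    def model_names(self) -> list[str]:
        return [f"model{i + 1:02d}" for i in range(self.n_models)]

    @classmethod
    def from_yaml(cls, path) -> "SyntheticWorldConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "bias_specs" in raw:
            raw["bias_specs"] = tuple(ModelBias(**b) for b in raw["bias_specs"])
        if "trend_specs" in raw:
            raw["trend_specs"] = {k: ScenarioTrend(**v) for k, v in raw["trend_specs"].items()}
        if "amoc_spec" in raw:
            raw["amoc_spec"] = AmocSpec(**raw["amoc_spec"])
        for key in ("years_historic", "years_future"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass(frozen=True)
class SyntheticSpeciesSpec:
    """A species defined by a known climate envelope.

    Suitability is the product of independent Gaussians centred at
    ``optima`` with spreads ``tolerances`` over the named bioclimatic
    variables, which makes envelope-parameter recovery well-posed.
    """
    species_name: str
    generating_variables: tuple[str, ...]
    optima: tuple[float, ...]
    tolerances: tuple[float, ...]
    n_records: int

    def __post_init__(self) -> None:
        from .bioclim import BIOCLIM_VARIABLES
        if not 2 <= len(self.generating_variables) <= 3:
            raise ValueError("need 2-3 generating variables")
        unknown = set(self.generating_variables) - set(BIOCLIM_VARIABLES)
        if unknown:
            raise ValueError(f"unknown bioclim variables: {sorted(unknown)}")
        if len(self.optima) != len(self.generating_variables) or \
                len(self.tolerances) != len(self.generating_variables):
            raise ValueError("optima/tolerances must match generating variables")
        if any(t <= 0 for t in self.tolerances):
            raise ValueError("tolerances must be positive")
        if self.n_records < 0:
            raise ValueError("n_records must be non-negative")


@dataclass
class SyntheticClimate:
    """Everything :func:`generate_climate` produces."""
    observed: dict[str, xr.DataArray]                 # variable -> series
    fine_climatology: dict[str, xr.DataArray]         # variable -> 12-month clim
    coarse_climatology: dict[str, xr.DataArray]
    models: dict[str, dict[str, dict[str, xr.DataArray]]]  # model -> scenario -> variable


def _cell_centers(lo: float, hi: float, n: int) -> np.ndarray:
    edges = np.linspace(lo, hi, n + 1)
    return 0.5 * (edges[:-1] + edges[1:])


def elevation_surface(config: SyntheticWorldConfig, lat: np.ndarray,
                      lon: np.ndarray) -> np.ndarray:
    """Fixed smooth elevation (m): low-order harmonics give broad ridges,
    higher-order ones give sub-coarse-cell relief that only the fine grid
    resolves."""
    rng = np.random.default_rng(np.random.SeedSequence([config.elevation_seed]))
    u = (lon[None, :] - config.lon_min) / (config.lon_max - config.lon_min)
    v = (lat[:, None] - config.lat_min) / (config.lat_max - config.lat_min)
    z = np.zeros((lat.size, lon.size))
    # harmonics of order 1..6; amplitude decays with order so the surface
    # stays dominated by broad structure while keeping sub-coarse-cell relief
    for kx in range(1, 7):
        for ky in range(1, 7):
            amp = 600.0 / (kx + ky)
            phix, phiy = rng.uniform(0, 2 * np.pi, 2)
            z += amp * np.sin(2 * np.pi * kx * u + phix) * np.sin(2 * np.pi * ky * v + phiy)
    # pointwise squash to 0..1200 m: identical values whatever grid the
    # surface is evaluated on (coarse cells, fine cells, station points)
    return 600.0 * (1.0 + np.tanh(z / 600.0))


def _smooth_field(config: SyntheticWorldConfig, lat: np.ndarray, lon: np.ndarray,
                  component: int) -> np.ndarray:
    """Fixed smooth geographic field in (0, 1), resolution-independent.

    Independent low-order harmonic surfaces (one per ``component``) give
    the world spatial degrees of freedom beyond latitude and elevation —
    continentality, wetness, precipitation seasonality — so that the 17
    bioclimatic variables are not collinear and envelope recovery is
    identifiable.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([config.elevation_seed, 1000 + component]))
    u = (lon[None, :] - config.lon_min) / (config.lon_max - config.lon_min)
    v = (lat[:, None] - config.lat_min) / (config.lat_max - config.lat_min)
    z = np.zeros((lat.size, lon.size))
    scale2 = 0.0
    for kx in range(0, 3):
        for ky in range(0, 3):
            if kx == 0 and ky == 0:
                continue
            amp = 1.0 / (kx + ky)
            phix, phiy = rng.uniform(0, 2 * np.pi, 2)
            z += amp * np.cos(2 * np.pi * kx * u + phix) * np.cos(2 * np.pi * ky * v + phiy)
            scale2 += 0.5 * amp ** 2
    return 0.5 * (1.0 + np.tanh(z / np.sqrt(scale2)))


def _deterministic_fields(config: SyntheticWorldConfig, lat: np.ndarray,
                          lon: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean monthly temperature and precipitation, shape (12, ny, nx)."""
    elev = elevation_surface(config, lat, lon)
    cont = _smooth_field(config, lat, lon, 1)    # continentality
    wet = _smooth_field(config, lat, lon, 2)     # baseline wetness
    phase = _smooth_field(config, lat, lon, 3)   # precip seasonality phase
    months = np.arange(1, 13)
    latf = lat[:, None]
    # temperature: south-north gradient, 6.5 K/km lapse, July-peaking
    # sinusoid whose amplitude follows the continentality surface
    amp = 4.0 + 8.0 * cont
    seasonal_t = np.cos(2 * np.pi * (months[:, None, None] - 7) / 12.0)
    t_mean = (22.0 - 0.55 * (latf - config.lat_min) - 6.5 * elev / 1000.0)
    temp = t_mean[None, :, :] + amp[None, :, :] * seasonal_t
    # precipitation: wetness surface + orographic and latitudinal gain,
    # seasonal cycle whose peak month wanders with the phase surface
    p_base = 30.0 + 70.0 * wet + 0.05 * elev + 0.6 * (latf - config.lat_min)
    peak = 4.0 + 8.0 * phase   # peak month between April and December
    seasonal_p = 1.0 + 0.35 * np.cos(
        2 * np.pi * (months[:, None, None] - peak[None, :, :]) / 12.0)
    precip = np.maximum(p_base[None, :, :] * seasonal_p, 0.0)
    return temp, precip


def _series(config: SyntheticWorldConfig, lat, lon, years: tuple[int, int],
            rng: np.random.Generator | None, variance_inflation: float = 1.0,
            temp_offset: float = 0.0, precip_factor: float = 1.0,
            trend: ScenarioTrend | None = None,
            trend_start: int | None = None) -> tuple[xr.DataArray, xr.DataArray]:
    det_t, det_p = _deterministic_fields(config, lat, lon)
    time = monthly_time_index(*years)
    n = len(time)
    midx = time.month.values - 1
    temp = det_t[midx] + temp_offset
    precip = det_p[midx] * precip_factor
    if trend is not None:
        decades = np.maximum(time.year.values - trend_start, 0) / 10.0
        temp = temp + (trend.warming_per_decade * decades)[:, None, None]
        precip = precip * (1.0 + trend.precip_pct_per_decade / 100.0 * decades)[:, None, None]
    if rng is not None:
        shape = (n, lat.size, lon.size)
        if config.noise_sd_temp > 0:
            temp = temp + rng.normal(
                0.0, config.noise_sd_temp * variance_inflation, shape)
        if config.noise_cv_precip > 0:
            sig = config.noise_cv_precip * variance_inflation
            precip = precip * rng.lognormal(-0.5 * sig ** 2, sig, shape)
    precip = np.maximum(precip, 0.0)
    return (make_grid(temp, time, lat, lon, TEMPERATURE),
            make_grid(precip, time, lat, lon, PRECIPITATION))


def generate_climate(config: SyntheticWorldConfig) -> SyntheticClimate:
    """Observed series, per-model/per-scenario series, and climatologies.

    The per-model noise draw is shared across scenarios of the same model
    (scenario runs differ only by their forced trend), and each model's
    configured bias is applied on top of the same deterministic climate
    the observations are built from, so a zero-bias zero-noise model
    reproduces the observations exactly.
    """
    lat, lon = config.coarse_axes()
    flat, flon = config.fine_axes()
    obs_rng = np.random.default_rng(np.random.SeedSequence([config.climate_seed, 0]))
    obs_t, obs_p = _series(config, lat, lon, config.years_historic, obs_rng)

    det_t_fine, det_p_fine = _deterministic_fields(config, flat, flon)
    det_t_coarse, det_p_coarse = _deterministic_fields(config, lat, lon)
    fine_clim = {TEMPERATURE: make_climatology(det_t_fine, flat, flon, TEMPERATURE),
                 PRECIPITATION: make_climatology(det_p_fine, flat, flon, PRECIPITATION)}
    coarse_clim = {TEMPERATURE: make_climatology(det_t_coarse, lat, lon, TEMPERATURE),
                   PRECIPITATION: make_climatology(det_p_coarse, lat, lon, PRECIPITATION)}

    full_years = (config.years_historic[0], config.years_future[1])
    trend_start = config.years_future[0]
    models: dict[str, dict[str, dict[str, xr.DataArray]]] = {}
    for i, name in enumerate(config.model_names):
        bias = config.bias_specs[i]
        models[name] = {}
        for scenario in SCENARIOS:
            rng = np.random.default_rng(
                np.random.SeedSequence([config.climate_seed, 1 + i]))
            t, p = _series(config, lat, lon, full_years, rng,
                           variance_inflation=bias.variance_inflation,
                           temp_offset=bias.temp_offset,
                           precip_factor=bias.precip_factor,
                           trend=config.trend_specs[scenario],
                           trend_start=trend_start)
            models[name][scenario] = {TEMPERATURE: t, PRECIPITATION: p}
    return SyntheticClimate(
        observed={TEMPERATURE: obs_t, PRECIPITATION: obs_p},
        fine_climatology=fine_clim, coarse_climatology=coarse_clim,
        models=models)


def generate_anomalies(config: SyntheticWorldConfig,
                       fine: bool = True) -> xr.Dataset:
    """Monthly AMOC-collapse anomaly maps.

    SAT (degC, additive) is <= 0 everywhere, strongest at the northern
    edge and in winter; RPA (fraction, multiplicative as ``1 + RPA``) is
    <= 0 with the same northward intensification.  Both are smooth and
    constant in longitude.
    """
    lat, lon = config.fine_axes() if fine else config.coarse_axes()
    spec = config.amoc_spec
    months = np.arange(1, 13)
    # pointwise gradient (1 at the domain's northern edge), so coarse and
    # fine evaluations of the anomaly maps agree at shared coordinates
    g = ((lat - config.lat_min) / (config.lat_max - config.lat_min)) ** spec.gradient_power
    # winter-peaking seasonal modulation in [0.6, 1]
    season = 0.8 + 0.2 * np.cos(2 * np.pi * (months - 1) / 12.0)
    shape = season[:, None, None] * g[None, :, None] * np.ones((1, 1, lon.size))
    sat = spec.max_cooling * shape
    rpa = np.maximum(-spec.precip_reduction * shape, -1.0)
    ds = xr.Dataset(
        {"sat": (("month", "lat", "lon"), sat),
         "rpa": (("month", "lat", "lon"), rpa)},
        coords={"month": months, "lat": lat, "lon": lon},
    )
    ds["sat"].attrs.update(units="degC", long_name="surface air temperature anomaly")
    ds["rpa"].attrs.update(units="1", long_name="relative precipitation anomaly",
                           convention="fraction; -0.2 means -20%")
    return ds


def generate_occurrences(specs: Sequence[SyntheticSpeciesSpec],
                         bioclim: xr.Dataset, seed: int) -> pd.DataFrame:
    """Occurrence records (species, lon, lat) sampled from known envelopes.

    Cells are drawn without replacement with probability proportional to
    the product of per-variable Gaussian suitabilities, so coordinates
    are unique within a species by construction.
    """
    records = []
    for k, spec in enumerate(specs):
        rng = np.random.default_rng(np.random.SeedSequence([seed, k]))
        loglik = np.zeros((bioclim.sizes["lat"], bioclim.sizes["lon"]))
        for var, opt, tol in zip(spec.generating_variables, spec.optima,
                                 spec.tolerances):
            x = bioclim[var].values
            loglik = loglik - 0.5 * ((x - opt) / tol) ** 2
        # shift in log space so the best cell has suitability 1 (avoids
        # underflow flattening the envelope to all-zero weights)
        flat = np.exp((loglik - loglik.max()).ravel())
        suitable = flat > 1e-12
        if spec.n_records == 0:
            continue
        if suitable.sum() < spec.n_records:
            raise ValueError(
                f"{spec.species_name}: {spec.n_records} records requested but "
                f"only {int(suitable.sum())} suitable cells available")
        flat = np.where(suitable, flat, 0.0)
        prob = flat / flat.sum()
        idx = rng.choice(flat.size, size=spec.n_records, replace=False, p=prob)
        ii, jj = np.unravel_index(idx, loglik.shape)
        records.append(pd.DataFrame({
            "species": spec.species_name,
            "lon": bioclim.lon.values[jj],
            "lat": bioclim.lat.values[ii],
        }))
    if not records:
        return pd.DataFrame(columns=["species", "lon", "lat"])
    return pd.concat(records, ignore_index=True)
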