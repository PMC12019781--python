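"""Evaluation of projected occurrence-probability fields.

Covers the four result families: relative occurrence-probability change
with extinction/expansion classes (Q1), distribution centers, spatial
extents and mean occurrence trajectories (Q1), dominance and replacement
analyses over the locally most probable species (Q2/Q3), Shannon
diversity of the projected assemblage (Q4), and the two uncertainty
analyses — percentual standard deviation across models and a per-cell
two-way ANOVA partition of variance into model, scenario and residual
components.

Probabilities below ``zero_eps`` (default 1e-3) count as absence when
classifying cells: a kernel-smoothed envelope rarely returns an exact 0
inside its support, so a small positive cutoff stabilises the
extinct/expanded classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

ZERO_EPS = 1e-3

# integer class codes for delta-p maps
CLASS_ABSENT = 0      # absent in both periods
CLASS_CHANGED = 1     # present historically, delta-p finite
CLASS_EXTINCT = 2     # present historically, absent in the future
CLASS_EXPANDED = 3    # absent historically, present in the future
DELTA_P_CLASSES = {CLASS_ABSENT: "absent", CLASS_CHANGED: "changed",
                   CLASS_EXTINCT: "extinct", CLASS_EXPANDED: "expanded"}


@dataclass
class DeltaPMap:
    """Relative change of p (%) with the cell classification."""
    delta_p: xr.DataArray    # % where classified "changed", NaN otherwise
    classes: xr.DataArray    # integer codes per DELTA_P_CLASSES
    legend: dict = None

    def __post_init__(self):
        if self.legend is None:
            self.legend = dict(DELTA_P_CLASSES)


def delta_p(p_hist: xr.DataArray, p_fut: xr.DataArray,
            zero_eps: float = ZERO_EPS) -> DeltaPMap:
    """delta-p = (p_future / p_historic - 1) x 100%.

    Cells where the species disappears (p_hist > 0, p_fut = 0) are
    classed extinct; cells colonised from zero are classed expanded and
    carry no finite delta-p.
    """
    h = np.asarray(p_hist.values, float)
    f = np.asarray(p_fut.values, float)
    if (h < 0).any() or (f < 0).any():
        raise ValueError("negative probabilities")
    pres_h = h > zero_eps
    pres_f = f > zero_eps
    cls = np.full(h.shape, CLASS_ABSENT, dtype=np.int8)
    cls[pres_h & pres_f] = CLASS_CHANGED
    cls[pres_h & ~pres_f] = CLASS_EXTINCT
    cls[~pres_h & pres_f] = CLASS_EXPANDED
    dp = np.full(h.shape, np.nan)
    mask = pres_h
    with np.errstate(divide="ignore", invalid="ignore"):
        dp[mask] = (f[mask] / h[mask] - 1.0) * 100.0
    dp[cls == CLASS_EXTINCT] = -100.0
    coords = {"lat": p_hist.lat.values, "lon": p_hist.lon.values}
    return DeltaPMap(
        delta_p=xr.DataArray(dp, dims=("lat", "lon"), coords=coords, name="delta_p",
                             attrs={"units": "%"}),
        classes=xr.DataArray(cls, dims=("lat", "lon"), coords=coords, name="class"))


def delta_p_histogram(dmap: DeltaPMap, bin_width: float = 10.0) -> pd.DataFrame:
    """Spatial shares of delta-p in 10%-wide bins, with extinct and
    expanded cells tallied as separate categories."""
    dp = dmap.delta_p.values
    cls = dmap.classes.values
    changed = dp[(cls == CLASS_CHANGED) & np.isfinite(dp)]
    occupied = np.count_nonzero(cls != CLASS_ABSENT)
    if occupied == 0:
        return pd.DataFrame(columns=["bin", "cells", "share"])
    lo = np.floor(changed.min() / bin_width) * bin_width if changed.size else 0.0
    hi = np.ceil(changed.max() / bin_width) * bin_width if changed.size else bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, _ = np.histogram(changed, bins=edges)
    rows = [{"bin": f"[{edges[i]:.0f},{edges[i+1]:.0f})", "cells": int(c)}
            for i, c in enumerate(counts)]
    rows.append({"bin": "extinct", "cells": int(np.count_nonzero(cls == CLASS_EXTINCT))})
    rows.append({"bin": "expanded", "cells": int(np.count_nonzero(cls == CLASS_EXPANDED))})
    out = pd.DataFrame(rows)
    out["share"] = out["cells"] / occupied
    return out


# ---------------------------------------------------------------------------
# distribution centers and occupancy

@dataclass
class DistributionCenter:
    lon: float
    lat: float
    extent_cells: int
    extent_area: float
    method: str


def _cell_areas(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    """Relative cell areas on a lon/lat grid (proportional to cos(lat))."""
    return np.cos(np.deg2rad(lat))[:, None] * np.ones((1, lon.size))


def distribution_center(p: xr.DataArray, method: str = "geometric",
                        zero_eps: float = 0.0) -> DistributionCenter:
    """p-weighted center of a species' distribution.

    ``method="geometric"``: weighted geometric mean of the coordinates in
    a strictly positive frame (lon + 180, lat + 90), shifted back;
    ``"arithmetic"``: plain weighted mean.  Cells with p = 0 carry no
    weight and are excluded.
    """
    if method not in ("geometric", "arithmetic"):
        raise ValueError(f"unknown method {method!r}")
    vals = np.asarray(p.values, float)
    mask = vals > zero_eps
    if not mask.any():
        raise ValueError("all-zero probability field has no center")
    lat = p.lat.values
    lon = p.lon.values
    lat2 = np.broadcast_to(lat[:, None], vals.shape)[mask]
    lon2 = np.broadcast_to(lon[None, :], vals.shape)[mask]
    w = vals[mask]
    if method == "arithmetic":
        clon = float(np.average(lon2, weights=w))
        clat = float(np.average(lat2, weights=w))
    else:
        clon = float(np.exp(np.average(np.log(lon2 + 180.0), weights=w)) - 180.0)
        clat = float(np.exp(np.average(np.log(lat2 + 90.0), weights=w)) - 90.0)
    areas = _cell_areas(lat, lon)[mask]
    return DistributionCenter(lon=clon, lat=clat, extent_cells=int(mask.sum()),
                              extent_area=float(areas.sum()), method=method)


def mean_occurrence(p: xr.DataArray, zero_eps: float = 0.0) -> float:
    """Area-weighted mean p over the cells where the species occurs."""
    vals = np.asarray(p.values, float)
    mask = vals > zero_eps
    if not mask.any():
        import warnings
        warnings.warn("no occupied cells; mean occurrence defined as 0")
        return 0.0
    areas = _cell_areas(p.lat.values, p.lon.values)
    return float(np.average(vals[mask], weights=areas[mask]))


# ---------------------------------------------------------------------------
# dominance (Q2) and replacement (Q3)

def dominant_species(em: xr.DataArray, zero_eps: float = ZERO_EPS
                     ) -> tuple[xr.DataArray, xr.DataArray]:
    """Locally most probable species from ensemble means.

    ``em`` has dims (species, lat, lon).  Returns the winning species
    index field (-1 where every species is absent; ties resolved to the
    alphabetically first species) and the winner's p field.
    """
    species = np.array([str(s) for s in em.species.values])
    order = np.argsort(species)
    vals = em.values[order]
    # argmax over species takes the first maximum -> alphabetical tie-break
    winner = np.argmax(vals, axis=0)
    pmax = np.take_along_axis(vals, winner[None], axis=0)[0]
    win_idx = order[winner].astype(np.int16)
    win_idx = np.where(pmax > zero_eps, win_idx, -1)
    coords = {"lat": em.lat.values, "lon": em.lon.values}
    label = xr.DataArray(
        win_idx, dims=("lat", "lon"), coords=coords, name="dominant",
        attrs={"legend": {int(i): str(s) for i, s in enumerate(em.species.values)}})
    pfield = xr.DataArray(np.where(win_idx >= 0, pmax, 0.0), dims=("lat", "lon"),
                          coords=coords, name="p_dominant")
    return label, pfield


CLASS_NEWLY_COLONIZED = 4
CLASS_NO_SPECIES = 5


def dominance_change_maps(cube, historic_period: str, future_period: str,
                          zero_eps: float = ZERO_EPS
                          ) -> tuple[DeltaPMap, DeltaPMap]:
    """delta-p of the historically dominant (map A) and the future-dominant
    species (map B) per cell.

    Map B adds two classes: "newly colonized" (the future dominant was
    absent historically) and "no species" (every species absent in the
    future).
    """
    em_h = cube.ensemble_mean(period=historic_period)
    em_f = cube.ensemble_mean(period=future_period)
    dom_h, _ = dominant_species(em_h, zero_eps)
    dom_f, _ = dominant_species(em_f, zero_eps)
    h_vals = em_h.values  # (species, ny, nx)
    f_vals = em_f.values
    ny, nx = dom_h.shape
    ii, jj = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")

    def _dp_for(dom_idx):
        sel = np.maximum(dom_idx, 0)
        ph = h_vals[sel, ii, jj]
        pf = f_vals[sel, ii, jj]
        ph = np.where(dom_idx >= 0, ph, 0.0)
        pf = np.where(dom_idx >= 0, pf, 0.0)
        return ph, pf

    coords = {"lat": em_h.lat.values, "lon": em_h.lon.values}
    # map A: anchored on the historic dominant
    ph, pf = _dp_for(dom_h.values)
    map_a = delta_p(xr.DataArray(ph, dims=("lat", "lon"), coords=coords),
                    xr.DataArray(pf, dims=("lat", "lon"), coords=coords),
                    zero_eps)
    # map B: anchored on the future dominant
    ph, pf = _dp_for(dom_f.values)
    map_b = delta_p(xr.DataArray(ph, dims=("lat", "lon"), coords=coords),
                    xr.DataArray(pf, dims=("lat", "lon"), coords=coords),
                    zero_eps)
    cls_b = map_b.classes.values
    cls_b[(dom_f.values >= 0) & (ph <= zero_eps)] = CLASS_NEWLY_COLONIZED
    cls_b[dom_f.values < 0] = CLASS_NO_SPECIES
    map_b.legend = dict(DELTA_P_CLASSES)
    map_b.legend.update({CLASS_NEWLY_COLONIZED: "newly colonized",
                         CLASS_NO_SPECIES: "no species"})
    return map_a, map_b


def replacement_tally(cube, focal_species: list[str], historic_period: str,
                      future_period: str, min_count: int = 0,
                      zero_eps: float = ZERO_EPS) -> pd.DataFrame:
    """Counts of (focal -> replacement) transitions.

    A transition is a cell where a focal species is historically dominant
    and locally extinct in the future (p = 0); the replacement is the
    future-dominant species there ("none" if every species is absent).
    Pairs with fewer than ``min_count`` cells are suppressed.
    """
    em_h = cube.ensemble_mean(period=historic_period)
    em_f = cube.ensemble_mean(period=future_period)
    dom_h, _ = dominant_species(em_h, zero_eps)
    dom_f, _ = dominant_species(em_f, zero_eps)
    species = [str(s) for s in em_h.species.values]
    ny, nx = dom_h.shape
    ii, jj = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    rows = {}
    for k, name in enumerate(species):
        if name not in focal_species:
            continue
        dom_cells = dom_h.values == k
        pf_focal = em_f.values[k]
        extinct = dom_cells & (pf_focal <= zero_eps)
        if not extinct.any():
            continue
        repl_idx = dom_f.values[extinct]
        for r in np.unique(repl_idx):
            repl = species[r] if r >= 0 else "none"
            rows[(name, repl)] = int(np.count_nonzero(repl_idx == r))
    out = pd.DataFrame(
        [{"focal": f, "replacement": r, "cells": c}
         for (f, r), c in sorted(rows.items())])
    if out.empty:
        return pd.DataFrame(columns=["focal", "replacement", "cells"])
    return out[out["cells"] >= min_count].reset_index(drop=True)


# ---------------------------------------------------------------------------
# diversity (Q4)

def shannon_h(p: np.ndarray, axis: int = 0, zero_eps: float = 0.0) -> np.ndarray:
    """Shannon H' = -sum pi_i ln pi_i over species with p > 0 per cell.

    pi_i is the i-th species' share of the summed occurrence
    probabilities, so H' is invariant to rescaling all p by a constant;
    cells without any species get H' = 0.
    """
    p = np.asarray(p, float)
    if (p < 0).any():
        raise ValueError("negative probabilities")
    p = np.moveaxis(p, axis, 0)
    p = np.where(p > zero_eps, p, 0.0)
    total = p.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = np.where(total > 0, p / np.where(total > 0, total, 1.0), 0.0)
        terms = np.where(pi > 0, pi * np.log(pi), 0.0)
    return -terms.sum(axis=0)


CLASS_DIV_CHANGED = 1
CLASS_DIV_DISAPPEARED = 2
CLASS_DIV_COLONIZED = 3
CLASS_NO_FOREST = 0
DIVERSITY_CLASSES = {CLASS_NO_FOREST: "no forest", CLASS_DIV_CHANGED: "changed",
                     CLASS_DIV_DISAPPEARED: "disappeared",
                     CLASS_DIV_COLONIZED: "colonized"}


@dataclass
class DiversityMap:
    h_hist: xr.DataArray
    h_fut: xr.DataArray
    delta_h: xr.DataArray
    classes: xr.DataArray
    legend: dict = None

    def __post_init__(self):
        if self.legend is None:
            self.legend = dict(DIVERSITY_CLASSES)


def diversity_change(em_hist: xr.DataArray, em_fut: xr.DataArray,
                     zero_eps: float = ZERO_EPS) -> DiversityMap:
    """H' per cell in both periods and their absolute change delta-H'.

    Cells where forest disappears (some species historically, none in the
    future) or newly appears are classed separately.
    """
    h0 = shannon_h(em_hist.values, axis=0, zero_eps=zero_eps)
    h1 = shannon_h(em_fut.values, axis=0, zero_eps=zero_eps)
    occ0 = (em_hist.values > zero_eps).any(axis=0)
    occ1 = (em_fut.values > zero_eps).any(axis=0)
    cls = np.full(h0.shape, CLASS_NO_FOREST, dtype=np.int8)
    cls[occ0 & occ1] = CLASS_DIV_CHANGED
    cls[occ0 & ~occ1] = CLASS_DIV_DISAPPEARED
    cls[~occ0 & occ1] = CLASS_DIV_COLONIZED
    coords = {"lat": em_hist.lat.values, "lon": em_hist.lon.values}
    mk = lambda v, n: xr.DataArray(v, dims=("lat", "lon"), coords=coords, name=n)
    return DiversityMap(h_hist=mk(h0, "h_hist"), h_fut=mk(h1, "h_fut"),
                        delta_h=mk(h1 - h0, "delta_h"),
                        classes=mk(cls, "class"))


# ---------------------------------------------------------------------------
# uncertainty

def percentual_sd(p_models: np.ndarray, axis: int = 0) -> np.ndarray:
    """Percentual standard deviation across models.

    Sample SD (divisor n-1) of the model values divided by their mean,
    x100%.  Cells with zero mean are undefined and returned as NaN.
    """
    p = np.asarray(p_models, float)
    n = p.shape[axis]
    if n < 2:
        raise ValueError("need at least 2 models")
    mean = p.mean(axis=axis)
    sd = p.std(axis=axis, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(mean > 0, sd / np.where(mean > 0, mean, 1.0) * 100.0,
                       np.nan)
    return out


def anova_partition(table: np.ndarray) -> tuple[float, float, float]:
    """Proportional sums of squares of a balanced two-way layout.

    ``table`` has shape (n_models, n_scenarios) with one response value
    per factor combination.  Returns (model, scenario, residual) shares
    of the total sum of squares; a constant table has no variance and
    returns all-zero shares.
    """
    t = np.asarray(table, float)
    if t.ndim != 2:
        raise ValueError("need a balanced 2-D model x scenario table")
    if np.isnan(t).any():
        raise ValueError("unbalanced table: missing responses")
    grand = t.mean()
    ss_total = ((t - grand) ** 2).sum()
    if ss_total <= 0:
        return (0.0, 0.0, 0.0)
    nm, ns = t.shape
    ss_model = ns * ((t.mean(axis=1) - grand) ** 2).sum()
    ss_scen = nm * ((t.mean(axis=0) - grand) ** 2).sum()
    ss_resid = ss_total - ss_model - ss_scen
    return (float(ss_model / ss_total), float(ss_scen / ss_total),
            float(max(ss_resid, 0.0) / ss_total))


def anova_partition_maps(p: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-cell ANOVA shares for p of shape (model, scenario, ny, nx)."""
    nm, ns, ny, nx = p.shape
    model = np.empty((ny, nx))
    scen = np.empty((ny, nx))
    resid = np.empty((ny, nx))
    for i in range(ny):
        for j in range(nx):
            model[i, j], scen[i, j], resid[i, j] = anova_partition(p[:, :, i, j])
    return model, scen, resid
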