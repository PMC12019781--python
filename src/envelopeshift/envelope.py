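"""Climate-envelope models: conflated per-variable probabilities.

A species' envelope is built from 2-3 bioclimatic variables.  For each
variable a two-sided tail probability is derived from a Gaussian-kernel
smoothed CDF of the presence values: p = 2 min(F(x), 1 - F(x)), which is
1 at the presence median, decays towards the tails, and is exactly 0
outside the presence support extended by one kernel bandwidth.  The
per-variable probabilities are conflated with Fisher's combined
probability test.  Variable subsets are selected exhaustively by the
True Skill Statistic (sensitivity + specificity - 1) against background
pseudo-absences, with the presence/absence threshold chosen on a 99-point
grid.  Because each per-variable probability vanishes outside the
presence support, projections are constrained to the historic climate
envelope by construction.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr
from scipy import special, stats
from sklearn.base import BaseEstimator

THRESHOLD_GRID = np.linspace(0.01, 0.99, 99)


# ---------------------------------------------------------------------------
# per-variable distribution

@dataclass
class VariableDistribution:
    """Gaussian-kernel smoothed presence distribution of one variable."""
    values: np.ndarray          # sorted presence values
    bandwidth: float
    support: tuple[float, float] = field(init=False)

    def __post_init__(self):
        self.values = np.sort(np.asarray(self.values, float))
        if self.values.size < 2:
            raise ValueError("need at least 2 presence values")
        if self.bandwidth <= 0:
            raise ValueError("non-positive bandwidth: variable is constant")
        self.support = (float(self.values[0] - self.bandwidth),
                        float(self.values[-1] + self.bandwidth))

    @classmethod
    def fit(cls, values: np.ndarray) -> "VariableDistribution":
        values = np.asarray(values, float)
        sd = values.std(ddof=1)
        iqr = np.subtract(*np.percentile(values, [75, 25]))
        spread = min(sd, iqr / 1.349) if iqr > 0 else sd
        h = 0.9 * spread * values.size ** (-1 / 5)  # Silverman's rule
        return cls(values=values, bandwidth=float(h))

    def cdf(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        flat = x.ravel()
        out = np.empty(flat.size)
        # chunked kernel sum keeps memory bounded on large grids
        step = max(1, int(4e6 / max(self.values.size, 1)))
        for s in range(0, flat.size, step):
            z = (flat[s:s + step, None] - self.values[None, :]) / self.bandwidth
            out[s:s + step] = special.ndtr(z).mean(axis=1)
        return out.reshape(x.shape)

    def pvalue(self, x: np.ndarray) -> np.ndarray:
        """Two-sided envelope probability; 0 outside the extended support."""
        x = np.asarray(x, float)
        f = self.cdf(x)
        p = np.clip(2.0 * np.minimum(f, 1.0 - f), 0.0, 1.0)
        lo, hi = self.support
        return np.where((x < lo) | (x > hi), 0.0, p)


# ---------------------------------------------------------------------------
# conflation and verification scores

def fisher_conflate(p_values: np.ndarray, axis: int = -1) -> np.ndarray:
    """Fisher's combined probability over k component probabilities.

    chi2 = -2 sum ln p_i with 2k degrees of freedom; a zero component
    forces the conflated probability to zero (the chi-square statistic
    diverges), all-ones give exactly 1.
    """
    p = np.asarray(p_values, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("component probabilities must lie in [0, 1]")
    k = p.shape[axis]
    with np.errstate(divide="ignore"):
        chi2 = -2.0 * np.sum(np.log(p), axis=axis)
    out = stats.chi2.sf(chi2, df=2 * k)
    return np.where(np.isinf(chi2), 0.0, out)


def tss(sensitivity: float, specificity: float) -> float:
    """True Skill Statistic = sensitivity + specificity - 1."""
    sens = np.asarray(sensitivity, float)
    spec = np.asarray(specificity, float)
    if np.any((sens < 0) | (sens > 1)) or np.any((spec < 0) | (spec > 1)):
        raise ValueError("sensitivity and specificity must lie in [0, 1]")
    return sens + spec - 1.0


def _best_threshold(p_presence: np.ndarray, p_background: np.ndarray,
                    grid: np.ndarray = THRESHOLD_GRID
                    ) -> tuple[float, float, float, float]:
    """Threshold maximising TSS (ties -> lowest threshold)."""
    sens = np.mean(p_presence[None, :] >= grid[:, None], axis=1)
    spec = np.mean(p_background[None, :] < grid[:, None], axis=1)
    scores = sens + spec - 1.0
    i = int(np.argmax(scores))  # argmax takes the first (lowest) threshold
    return float(grid[i]), float(sens[i]), float(spec[i]), float(scores[i])


# ---------------------------------------------------------------------------
# species filtering

def filter_species(occurrences: pd.DataFrame, share_threshold: float = 0.01
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Retain species holding at least a share of all records.

    The inclusion cutoff is ``ceil(share_threshold * total records)``.
    Returns the filtered table and a per-species report (count, retained
    flag, share of all records).
    """
    if not 0 < share_threshold < 1:
        raise ValueError("share_threshold must lie in (0, 1)")
    if occurrences.empty:
        raise ValueError("empty occurrence table")
    total = len(occurrences)
    cutoff = math.ceil(share_threshold * total)
    counts = occurrences["species"].value_counts()
    retained = counts[counts >= cutoff]
    report = pd.DataFrame({
        "count": counts,
        "retained": counts >= cutoff,
        "share": counts / total,
    })
    report.attrs["cutoff"] = cutoff
    report.attrs["total_records"] = total
    report.attrs["retained_records"] = int(retained.sum())
    report.attrs["retained_share"] = float(retained.sum() / total)
    out = occurrences[occurrences["species"].isin(retained.index)].copy()
    return out, report


def record_cutoff(total_records: int, share_threshold: float = 0.01) -> int:
    """Minimum record count a species needs at a given share of all data."""
    if not 0 < share_threshold < 1:
        raise ValueError("share_threshold must lie in (0, 1)")
    return math.ceil(share_threshold * total_records)


def prune_collinear_variables(bioclim: xr.Dataset,
                              threshold: float = 0.8,
                              order: Sequence[str] | None = None) -> list[str]:
    """Greedy collinearity pruning of candidate bioclim variables.

    Walks the catalogue in order and keeps a variable only if its
    absolute Pearson correlation (across grid cells) with every variable
    kept so far stays below ``threshold``.  Standard practice before
    variable selection in distribution modelling: near-duplicate
    predictors (e.g. the range and the standard deviation of the same
    monthly cycle) carry the same information and make the selected set
    arbitrary.
    """
    names = list(order) if order is not None else list(bioclim.data_vars)
    flat = {n: bioclim[n].values.ravel() for n in names}
    kept: list[str] = []
    for name in names:
        x = flat[name]
        if x.std() == 0:
            continue
        ok = True
        for other in kept:
            r = np.corrcoef(x, flat[other])[0, 1]
            if abs(r) >= threshold:
                ok = False
                break
        if ok:
            kept.append(name)
    return kept


def dedupe_occurrences(occurrences: pd.DataFrame) -> pd.DataFrame:
    """Keep only unique (species, lon, lat) triples."""
    return occurrences.drop_duplicates(subset=["species", "lon", "lat"],
                                       ignore_index=True)


# ---------------------------------------------------------------------------
# the estimator

class ClimateEnvelopeModel(BaseEstimator):
    """Conflated-PDF climate envelope with exhaustive variable selection.

    scikit-learn-style estimator on tabular data: ``fit(X, y)`` takes a
    DataFrame of candidate bioclimatic variables and a binary vector
    (1 = presence, 0 = background pseudo-absence).  Per-variable
    distributions are fitted on presences only; every 2- and 3-variable
    subset of the candidates is scored by its best-threshold TSS, and
    the best subset is kept (ties: fewer variables, then variable order).

    Parameters
    ----------
    subset_sizes : tuple of int
        Sizes of the variable subsets searched (default (2, 3)).
    threshold_grid : ndarray
        Candidate presence thresholds for the TSS optimisation.

    Fitted attributes
    -----------------
    variables_ : tuple of str — the selected subset
    distributions_ : dict name -> VariableDistribution
    threshold_ : float
    sensitivity_, specificity_, tss_ : float verification scores
    search_results_ : DataFrame of all scored subsets
    """

    def __init__(self, subset_sizes: tuple[int, ...] = (2, 3),
                 threshold_grid: np.ndarray = THRESHOLD_GRID):
        self.subset_sizes = subset_sizes
        self.threshold_grid = threshold_grid

    def fit(self, X: pd.DataFrame, y: np.ndarray) -> "ClimateEnvelopeModel":
        X = pd.DataFrame(X)
        y = np.asarray(y).astype(bool)
        if len(X) != y.size:
            raise ValueError("X and y lengths differ")
        n_pres = int(y.sum())
        if n_pres < 30:
            raise ValueError(f"too few presences ({n_pres} < 30)")
        if n_pres == y.size:
            raise ValueError("no background samples in y")
        columns = []
        dists: dict[str, VariableDistribution] = {}
        for col in X.columns:
            pres = X.loc[y, col].to_numpy(float)
            if pres.std(ddof=1) <= 0:
                warnings.warn(f"variable {col!r} is constant over presences; "
                              "excluded from the search")
                continue
            dists[col] = VariableDistribution.fit(pres)
            columns.append(col)
        if len(columns) < min(self.subset_sizes):
            raise ValueError("not enough usable candidate variables")
        # per-variable envelope probabilities for every row, computed once
        pvals = {col: dists[col].pvalue(X[col].to_numpy(float))
                 for col in columns}
        rows = []
        best = None
        for size in sorted(self.subset_sizes):
            for subset in itertools.combinations(columns, size):
                p = fisher_conflate(np.column_stack([pvals[c] for c in subset]))
                thr, sens, spec, score = _best_threshold(
                    p[y], p[~y], np.asarray(self.threshold_grid, float))
                rows.append({"variables": subset, "threshold": thr,
                             "sensitivity": sens, "specificity": spec,
                             "tss": score})
                if best is None or score > best["tss"] + 1e-12:
                    best = rows[-1]
        self.search_results_ = pd.DataFrame(rows)
        self.variables_ = tuple(best["variables"])
        self.distributions_ = {c: dists[c] for c in self.variables_}
        self.threshold_ = best["threshold"]
        self.sensitivity_ = best["sensitivity"]
        self.specificity_ = best["specificity"]
        self.tss_ = best["tss"]
        return self

    def suitability(self, X: pd.DataFrame) -> np.ndarray:
        """Conflated occurrence probability p in [0, 1] per row."""
        if not hasattr(self, "variables_"):
            raise RuntimeError("model is not fitted")
        X = pd.DataFrame(X)
        comps = np.column_stack([
            self.distributions_[c].pvalue(X[c].to_numpy(float))
            for c in self.variables_])
        return fisher_conflate(comps)

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        p = self.suitability(X)
        return np.column_stack([1.0 - p, p])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.suitability(X) >= self.threshold_).astype(int)


# ---------------------------------------------------------------------------
# grid-level wrappers

@dataclass
class SpeciesEnvelope:
    """A fitted envelope plus its verification scores."""
    species: str
    variables: tuple[str, ...]
    distributions: Mapping[str, VariableDistribution]
    threshold: float
    sensitivity: float
    specificity: float
    tss: float
    background_seed: int

    def to_json(self) -> str:
        payload = {
            "species": self.species,
            "variables": list(self.variables),
            "threshold": self.threshold,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "tss": self.tss,
            "background_seed": self.background_seed,
            "distributions": {
                name: {"bandwidth": d.bandwidth,
                       "values": d.values.tolist()}
                for name, d in self.distributions.items()},
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "SpeciesEnvelope":
        raw = json.loads(text)
        dists = {name: VariableDistribution(np.asarray(d["values"]),
                                            d["bandwidth"])
                 for name, d in raw["distributions"].items()}
        return cls(species=raw["species"], variables=tuple(raw["variables"]),
                   distributions=dists, threshold=raw["threshold"],
                   sensitivity=raw["sensitivity"],
                   specificity=raw["specificity"], tss=raw["tss"],
                   background_seed=raw["background_seed"])


def _cell_index(occ: pd.DataFrame, bioclim: xr.Dataset) -> np.ndarray:
    lat = bioclim.lat.values
    lon = bioclim.lon.values
    ii = np.abs(occ["lat"].to_numpy()[:, None] - lat[None, :]).argmin(axis=1)
    jj = np.abs(occ["lon"].to_numpy()[:, None] - lon[None, :]).argmin(axis=1)
    return np.unique(ii * lon.size + jj)


def calibrate_envelope(occurrences: pd.DataFrame, bioclim: xr.Dataset,
                       candidate_variables: Sequence[str] | None = None,
                       background_seed: int = 0,
                       subset_sizes: tuple[int, ...] = (2, 3)
                       ) -> SpeciesEnvelope:
    """Fit one species' envelope against background pseudo-absences.

    Presences are the grid cells holding the species' records;
    pseudo-absences are a uniform random sample of the remaining cells,
    of equal size, drawn with ``background_seed``.
    """
    species = occurrences["species"].iloc[0]
    candidates = (list(candidate_variables) if candidate_variables is not None
                  else list(bioclim.data_vars))
    missing = [c for c in candidates if c not in bioclim]
    if missing:
        raise ValueError(f"stack lacks candidate variables: {missing}")
    n_cells = bioclim.sizes["lat"] * bioclim.sizes["lon"]
    pres_idx = _cell_index(occurrences, bioclim)
    if pres_idx.size < 30:
        raise ValueError(f"{species}: too few presence cells ({pres_idx.size})")
    rng = np.random.default_rng(background_seed)
    absent = np.setdiff1d(np.arange(n_cells), pres_idx, assume_unique=False)
    n_bg = min(pres_idx.size, absent.size)
    bg_idx = rng.choice(absent, size=n_bg, replace=False)
    flat = {c: bioclim[c].values.ravel() for c in candidates}
    idx = np.concatenate([pres_idx, bg_idx])
    X = pd.DataFrame({c: flat[c][idx] for c in candidates})
    y = np.concatenate([np.ones(pres_idx.size, bool), np.zeros(n_bg, bool)])
    model = ClimateEnvelopeModel(subset_sizes=subset_sizes).fit(X, y)
    return SpeciesEnvelope(
        species=species, variables=model.variables_,
        distributions=model.distributions_, threshold=model.threshold_,
        sensitivity=model.sensitivity_, specificity=model.specificity_,
        tss=model.tss_, background_seed=background_seed)


def envelope_pvalue(x: np.ndarray, dist: VariableDistribution) -> np.ndarray:
    """Two-sided envelope probability of values under one fitted variable."""
    return dist.pvalue(x)


def project_occurrence(env: SpeciesEnvelope, bioclim: xr.Dataset) -> xr.DataArray:
    """Occurrence-probability field of a species on a bioclim stack.

    Cells whose values fall outside the historic presence support of any
    selected variable receive p = 0, so projections never leave the
    calibrated climate envelope.
    """
    missing = [v for v in env.variables if v not in bioclim]
    if missing:
        raise ValueError(f"stack lacks envelope variables: {missing}")
    comps = np.stack([env.distributions[v].pvalue(bioclim[v].values)
                      for v in env.variables], axis=-1)
    p = fisher_conflate(comps)
    return xr.DataArray(p, dims=("lat", "lon"),
                        coords={"lat": bioclim.lat.values,
                                "lon": bioclim.lon.values},
                        name="p",
                        attrs={"species": env.species,
                               "period": bioclim.attrs.get("period", "")})


# ---------------------------------------------------------------------------
# projection cube

@dataclass
class ProjectionCube:
    """Occurrence probability per species x period x model on the grid."""
    p: xr.DataArray  # dims (species, period, model, lat, lon)

    def __post_init__(self):
        expected = ("species", "period", "model", "lat", "lon")
        if tuple(self.p.dims) != expected:
            raise ValueError(f"cube dims must be {expected}, got {self.p.dims}")
        vals = self.p.values
        if np.nanmin(vals) < -1e-12 or np.nanmax(vals) > 1 + 1e-12:
            raise ValueError("probabilities must lie in [0, 1]")

    @property
    def species(self) -> list[str]:
        return [str(s) for s in self.p.species.values]

    @property
    def periods(self) -> list[str]:
        return [str(s) for s in self.p.period.values]

    def ensemble_mean(self, species=None, period=None) -> xr.DataArray:
        """Arithmetic mean over models, optionally for one species/period."""
        em = self.p.mean("model")
        if species is not None:
            em = em.sel(species=species)
        if period is not None:
            em = em.sel(period=period)
        return em


def ensemble_mean(cube: ProjectionCube) -> xr.DataArray:
    return cube.ensemble_mean()
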