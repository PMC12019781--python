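# Methods

This note documents the models and procedures implemented in
`envelopeshift`, the assumptions behind them, the parameters that
matter, and what the synthetic study world does and does not emulate.

## Synthetic study world

The generator produces everything the projection chain consumes, with
known ground truth.

**Geography.** A fixed elevation surface (0–1200 m) is built from
low-order harmonics squashed through a tanh, plus three independent
smooth surfaces in (0, 1) for continentality, baseline wetness and the
phase of the precipitation seasonal cycle. All four are pointwise
deterministic functions of longitude/latitude, so evaluating them on
the coarse grid, the fine grid, or any other grid gives consistent
values; the fine grid simply resolves more of the harmonic detail.
These extra degrees of freedom matter: with latitude and elevation
alone, the 17 bioclimatic variables collapse onto one or two gradients
and envelope-variable recovery becomes unidentifiable.

**Climate.** Monthly mean temperature follows a south–north gradient
(−0.55 °C/° latitude), a 6.5 °C/km lapse rate, and a July-peaking
sinusoid whose amplitude (4–12 °C) follows the continentality surface;
monthly precipitation combines the wetness surface, orographic and
latitudinal gains, and a ±35 % seasonal cycle whose peak month follows
the phase surface. Noise is additive Gaussian for temperature
(default SD 1 °C/month) and multiplicative lognormal for precipitation
(default CV 0.25, mean-one); precipitation is floored at zero.

**Pseudo-GCMs.** Each model applies an additive temperature offset
(default drawn once from ±2 °C), a multiplicative precipitation factor
(0.8–1.3) and a noise-variance inflation to the same deterministic
climate, plus a scenario trend from the first projection year: default
+0.15/+0.30/+0.55 °C per decade and −0.3/−0.7/−1.5 % precipitation per
decade for the three SSPs, linear ramps, chosen once to sit in the
range of end-of-century ensemble projections. A model's noise draw is
shared across its scenarios, so scenario runs differ only by the
forced trend. With zero bias and zero noise a model reproduces the
observations exactly — the anchor for the bias-correction tests.

**AMOC anomalies.** SAT = max_cooling · g(lat) · s(month) with
g = ((lat − lat_min)/(lat_max − lat_min))^power (power 2 by default,
so cooling concentrates in the north; the configured maximum, default
−8 °C, applies at the domain's northern edge) and a winter-peaking
modulation s ∈ [0.6, 1]. RPA uses the same shape scaled to a maximum
relative loss (default −30 %), clipped at −1. Both fields are ≤ 0,
smooth, and constant in longitude.

**Species.** Occurrence records are drawn without replacement from
grid cells with probability proportional to a product of independent
per-variable Gaussian suitabilities exp(−½((x − opt)/tol)²), computed
in log space to avoid underflow; cells below 10⁻¹² relative
suitability are ineligible, and asking for more records than eligible
cells is an error. The product-of-independent-Gaussians form matches
the conflated-independent-PDF structure of the envelope model, which
is what makes parameter recovery well-posed.

**What the world does not emulate:** real coastlines or missing-data
masks, station-density artefacts, spatially correlated noise, temporal
autocorrelation beyond the seasonal cycle, interannual modes (NAO,
ENSO), model genealogy, or dispersal limits on species. Passing tests
therefore demonstrate the correctness of the *computational chain* and
the statistical behaviour of the estimators under known conditions,
not skill on real observational data.

## Climate preparation

**Change-factor downscaling.** For each fine cell, the enclosing
(nearest-center) coarse cell supplies the monthly anomaly relative to
the coarse climatology; temperature is additive, precipitation
multiplicative with the ratio capped at 5 and forced to 1 where the
coarse climatology is below 1 mm/month (guards against dry-month
blow-ups).

**Quantile mapping.** Empirical, per cell × calendar month ×
variable: 99 paired quantiles at probabilities 0.01…0.99, linear
interpolation between them, fitted over a calibration window
(default 1951–2014; at least 10 years enforced). Outside the
calibrated range the correction is held constant — an additive offset
for temperature, a ratio for precipitation (identity if the boundary
model quantile is ~0) — which preserves projected trends (verified to
< 0.2 °C on 30-year mean differences) while avoiding unbounded
extrapolation. Corrected precipitation is floored at zero. Twelve
independent transfer functions per cell mirror the monthly resolution
of the inputs.

**AMOC overlay.** Applied after quantile mapping, as a step change
over one climate normal (default 2071–2100): SAT added to the matching
calendar month, precipitation multiplied by (1 + RPA) and floored at
zero. Months outside the period are bit-identical to the input.
Anomaly maps on a different grid are interpolated bilinearly (nearest
at the edges). No pre-2071 ramp-in is applied; the collapse is treated
as realized by the start of the period.

## Bioclimatic variables

The 17-variable catalogue: temperature — annual mean, DJF/MAM/JJA/SON
means, warmest-month and coldest-month means, SD and range of the 12
monthly values (9); CWB — annual sum, four seasonal sums, driest-month
CWB, SD and range (8). Every variable is computed per calendar year
and then averaged over the period's 30 years, so warmest/driest months
are yearly extremes. DJF takes December from the preceding year; the
first year's DJF is skipped unless the input series carries the
pre-period December. The SD/range continentality measures use the
calendar year's own 12 months (sample SD, ddof 1).

PET (Thornthwaite) uses a heat index from the period's own 30-year
monthly climatology — stable, and insulated from single-month
perturbations — and the standard (L/12)(N/30) day-length/month-length
correction from solar declination at the cell latitude. PET is zero
for T ≤ 0. Note one non-obvious consequence: under a perfectly
constant climate the CWB still has a seasonal cycle, because day
length varies; only temperature continentality collapses to zero.

Period catalogue: historic 1951–1980 and 1991–2020; SSP1-2.6, SSP2-4.5
and SSP5-8.5 at 2021–2050, 2046–2075 and 2071–2100; the three SSPs
again at 2071–2100 with AMOC collapse — 14 periods. The variable
catalogue is user-overridable (any subset of the 17).

## Envelope model

Per-variable presence distributions are Gaussian-kernel smoothed CDFs
(Silverman bandwidth, robust spread = min(SD, IQR/1.349)); the
envelope probability is the two-sided tail p = 2·min(F̂, 1 − F̂),
exactly zero outside the presence min/max extended by one bandwidth.
Conflation is Fisher's test (upper-tail χ² probability at −2Σln pᵢ,
df = 2k; any zero component forces zero). The support rule is what
keeps projections inside the historic climate envelope — the
structural property that distinguishes this model from regression-type
distribution models that happily extrapolate.

Calibration draws background pseudo-absences uniformly from
non-presence cells (equal to the presence count, fixed seed), scores
every 2- and 3-variable subset of the candidates by the TSS at its
best threshold (99-point grid 0.01…0.99; ties → lowest threshold), and
keeps the best subset (ties → fewer variables, then catalogue order).
Constant variables are excluded with a warning; fewer than 30 presence
cells is an error. The estimator (`ClimateEnvelopeModel`) is
scikit-learn shaped: `fit(X, y)` on a table of candidate variables
with a presence/background indicator, `suitability`/`predict_proba`/
`predict` for new tables; `calibrate_envelope`/`project_occurrence`
wrap it for grids. A single calibration on all data with seeded
background resampling is the default; no holdout split is performed,
so the reported TSS is a resubstitution estimate — adequate for the
synthetic recovery experiments it is used in.

**Recovery experiment design.** Several of the 17 variables are
near-duplicates by construction (the SD and the range of the same 12
monthly values correlate at r > 0.95; seasonal and annual means are
nearly as close). When a species is generated from one member of such
a pair, which twin the search selects is decided by noise, so
exact-label recovery is only well-posed over a collinearity-pruned
candidate pool. The recovery experiment therefore prunes greedily at
|r| < 0.8 (catalogue order, `prune_collinear_variables`) — standard
practice in distribution modelling — draws generating pairs from the
pruned pool (optima at the 25th–75th percentile of each variable,
tolerances 0.4 field SD, 300 records), and searches all 2-subsets of
that pool. Under these conditions the generating pair is recovered in
≥ 95 % of species across seeds, TSS ≥ 0.7 throughout, and the
projected suitable region (p ≥ threshold) overlaps the species'
occupied cells with Jaccard ≥ 0.6 (typically ≥ 0.75). The occupied
cells are the reference region because they are the realized
distribution; an iso-suitability ellipse systematically underestimates
the range the records actually sample. The full C(17,2) + C(17,3)
search stays the default for real use.

## Evaluation

δp = (p_fut/p_hist − 1)·100 % where the species was historically
present; cells are classed changed / extinct (present → absent) /
expanded (absent → present) / absent-in-both using a zero cutoff
`zero_eps` = 10⁻³ on ensemble means — a kernel-smoothed envelope
rarely returns an exact 0 inside its support, so a small positive
cutoff stabilises the classes. Histograms bin finite δp in 10 % steps
with extinct and expanded cells as separate bars.

Distribution centers weight cell coordinates by p (zero-p cells carry
no weight). The geometric method computes the weighted geometric mean
in a strictly positive frame (lon + 180, lat + 90) and shifts back,
because geometric means of signed longitudes are ill-defined; the
arithmetic method is offered alongside, and neither is asserted to be
the one true reading of "weighted geometric mean" on signed
coordinates. Extents count p > 0 cells, areas weighted by cos(lat).
Mean occurrence is the area-weighted mean of p over occupied cells.

Dominance maps take the argmax of ensemble-mean p across species per
cell (ties → alphabetical; all-absent → none); change maps anchor δp
on the historic or the future dominant, the latter with
"newly colonized" and "no species" classes. Replacement tallies count,
for each historically dominant focal species that goes locally
extinct, the future dominant per cell; pairs under `min_count`
(default 0.2 % of the grid, mirroring the original's 20,000-cell
cutoff at continental scale) are suppressed.

Shannon H′ uses natural log over the species with p > 0 (πᵢ normalized
within the cell); H′ ∈ [0, ln k], zero for empty cells, and invariant
to rescaling all p. δH′ is the absolute change, with disappeared /
colonized classes.

Percentual SD is the sample SD (ddof 1) across models over their mean,
×100 %; mean-zero cells are undefined (NaN) and excluded from the
summary maps. The ANOVA partition uses the balanced two-way layout
without replication: SS_model, SS_scenario from the factor means,
residual by subtraction, each over the total SS; constant cells return
all-zero shares. The per-cell response is one species' p over the
model × scenario grid at 2071–2100; species-wise share maps are
averaged for the summary, since the source analysis does not specify
how species enter the per-pixel ANOVA.

## Pipeline and numerics

Stages write NetCDF (CF-style, scipy backend)/CSV/JSON products under
a run directory and record SHA-256 checksums in a manifest keyed by a
configuration hash; re-runs skip stages whose hash and outputs are
intact, and a corrupted intermediate forces recomputation of that
stage and everything downstream. All randomness flows from named seeds
(elevation, climate, species, background); two runs with the same
configuration are byte-identical, including the NetCDF files.

Defaults are sized for desk-scale runs: a 15×15 coarse grid downscaled
×2, 2 pseudo-GCMs × 3 scenarios over 1951–2100, 4 species (plus one
deliberately rare species that the record-share filter removes;
the filter's share threshold defaults to 5 % in the pipeline because
1 % of a few hundred synthetic records would retain everything).
Computation is float64 throughout; grid storage is float32.

Known limitations: the envelope model ignores interactions between
variables (independence is baked into both the generator and the
conflation); pseudo-absences are climate-blind random background;
the quantile mapping assumes stationarity of the model bias; the
overlay treats the AMOC collapse as instantaneous at 2071; and no
dispersal, establishment or biotic processes are modelled — projected
p is climatic habitat suitability, not realized occupancy.
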