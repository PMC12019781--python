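"""Envelope model: per-variable probabilities, Fisher conflation,
TSS selection, projection, and the species filter."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import envelopeshift as es
from envelopeshift.envelope import (ClimateEnvelopeModel, VariableDistribution,
                                    _best_threshold)

from conftest import make_species_specs


class TestSpeciesFilter:
    def test_published_cutoff_arithmetic(self):
        assert es.record_cutoff(589_937, 0.01) == 5900

    def test_toy_share_filter(self):
        occ = pd.DataFrame({
            "species": ["a"] * 50 + ["b"] * 30 + ["c"] * 20,
            "lon": np.linspace(0, 10, 100), "lat": np.linspace(40, 50, 100)})
        kept, report = es.filter_species(occ, 0.25)
        assert set(kept["species"]) == {"a", "b"}
        assert report.attrs["cutoff"] == 25
        assert report.attrs["retained_records"] == 80

    def test_tiny_threshold_keeps_everything(self):
        occ = pd.DataFrame({"species": ["a", "b", "c"], "lon": [1., 2., 3.],
                            "lat": [45., 46., 47.]})
        kept, _ = es.filter_species(occ, 1e-9)
        assert set(kept["species"]) == {"a", "b", "c"}

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 2.0])
    def test_threshold_range_enforced(self, bad):
        occ = pd.DataFrame({"species": ["a"], "lon": [1.0], "lat": [45.0]})
        with pytest.raises(ValueError):
            es.filter_species(occ, bad)


class TestCollinearityPruning:
    def test_near_duplicates_dropped(self, historic_stack):
        pool = es.prune_collinear_variables(historic_stack, 0.8)
        # the kept set is mutually below the threshold
        vals = {v: historic_stack[v].values.ravel() for v in pool}
        for a in pool:
            for b in pool:
                if a != b:
                    r = abs(np.corrcoef(vals[a], vals[b])[0, 1])
                    assert r < 0.8, (a, b)
        # range and SD of the same cycle are near-duplicates: only one
        # of each pair survives
        assert not ({"t_sd", "t_range"} <= set(pool))
        assert not ({"cwb_sd", "cwb_range"} <= set(pool))

    def test_catalogue_order_priority(self, historic_stack):
        pool = es.prune_collinear_variables(
            historic_stack, 0.8, order=["t_range", "t_sd"])
        assert pool[0] == "t_range"


@pytest.fixture(scope="module")
def dist():
    rng = np.random.default_rng(1)
    return VariableDistribution.fit(rng.normal(10.0, 2.0, 500))


class TestVariableDistribution:
    def test_median_gets_probability_one(self, dist):
        med = np.median(dist.values)
        assert dist.pvalue(med) == pytest.approx(1.0, abs=0.05)

    def test_far_outside_support_is_zero(self, dist):
        assert dist.pvalue(1e6) == 0.0
        assert dist.pvalue(-1e6) == 0.0

    def test_tenth_percentile_maps_to_point_two(self, dist):
        """Empirical-CDF oracle: at the presence 10th percentile the
        two-sided probability is ~0.2."""
        q10 = np.quantile(dist.values, 0.10)
        assert dist.pvalue(q10) == pytest.approx(0.2, abs=0.03)

    def test_monotone_decay_from_median(self, dist):
        med = np.median(dist.values)
        xs = med + np.linspace(0, 10, 50)
        ps = dist.pvalue(xs)
        assert np.all(np.diff(ps) <= 1e-9)

    def test_constant_variable_rejected(self):
        with pytest.raises(ValueError):
            VariableDistribution.fit(np.full(50, 3.0))


class TestFisherConflation:
    def test_all_ones_give_one(self):
        assert es.fisher_conflate(np.array([1.0, 1.0])) == pytest.approx(1.0)

    def test_any_zero_gives_zero(self):
        assert es.fisher_conflate(np.array([0.0, 0.7])) == 0.0
        assert es.fisher_conflate(np.array([0.3, 0.9, 0.0])) == 0.0

    def test_half_half_closed_form(self):
        """df-4 closed form: sf(x) = exp(-x/2) (1 + x/2)."""
        x = -2.0 * (np.log(0.5) + np.log(0.5))
        expected = np.exp(-x / 2) * (1 + x / 2)
        assert es.fisher_conflate(np.array([0.5, 0.5])) == pytest.approx(
            expected, abs=1e-12)
        assert expected == pytest.approx(0.5966, abs=1e-4)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            es.fisher_conflate(np.array([0.5, 1.2]))

    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=3))
    @settings(max_examples=50, deadline=None)
    def test_conflation_shrinks_with_any_component(self, ps):
        base = es.fisher_conflate(np.array(ps))
        smaller = list(ps)
        smaller[0] *= 0.5
        assert es.fisher_conflate(np.array(smaller)) <= base + 1e-12


class TestTSS:
    @pytest.mark.parametrize("sens,spec,expected",
                             [(1.0, 1.0, 1.0), (0.5, 0.5, 0.0),
                              (0.8, 0.7, 0.5)])
    def test_definition(self, sens, spec, expected):
        assert es.tss(sens, spec) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            es.tss(1.2, 0.5)

    def test_threshold_tie_breaks_low(self):
        p_pres = np.array([0.9, 0.9, 0.9])
        p_bg = np.array([0.001, 0.001])
        thr, *_ = _best_threshold(p_pres, p_bg)
        assert thr == pytest.approx(0.01)


class TestCalibration:
    def test_recovers_generating_pair(self, fitted_envelope):
        spec, env = fitted_envelope
        assert set(env.variables) == set(spec.generating_variables)
        assert env.tss >= 0.7

    def test_null_model_has_no_skill(self, historic_stack):
        """Presences and background from identical climate: |TSS| small."""
        rng = np.random.default_rng(5)
        n = 500
        X = pd.DataFrame({
            "t_ann": rng.normal(8, 3, 2 * n),
            "cwb_ann": rng.normal(300, 120, 2 * n)})
        y = np.concatenate([np.ones(n), np.zeros(n)])
        model = ClimateEnvelopeModel(subset_sizes=(2,)).fit(X, y)
        assert abs(model.tss_) < 0.15

    def test_too_few_presences_rejected(self, historic_stack, occurrences):
        sparse = occurrences.iloc[:10]
        with pytest.raises(ValueError, match="too few"):
            es.calibrate_envelope(sparse, historic_stack)

    def test_constant_variable_excluded_with_warning(self):
        rng = np.random.default_rng(2)
        n = 100
        X = pd.DataFrame({"a": rng.normal(0, 1, 2 * n),
                          "b": rng.normal(5, 2, 2 * n),
                          "flat": np.ones(2 * n),
                          "c": rng.normal(-3, 1, 2 * n)})
        X.loc[:n - 1, "a"] += 3.0
        y = np.concatenate([np.ones(n), np.zeros(n)])
        with pytest.warns(UserWarning, match="constant"):
            model = ClimateEnvelopeModel(subset_sizes=(2,)).fit(X, y)
        assert "flat" not in model.variables_

    def test_background_seed_reproducible(self, occurrences, historic_stack,
                                          species_specs):
        name = species_specs[0].species_name
        occ = occurrences[occurrences["species"] == name]
        a = es.calibrate_envelope(occ, historic_stack, background_seed=9)
        b = es.calibrate_envelope(occ, historic_stack, background_seed=9)
        assert a.variables == b.variables
        assert a.threshold == b.threshold and a.tss == b.tss


class TestProjection:
    def test_presences_score_higher_than_background(self, fitted_envelope,
                                                    historic_stack,
                                                    occurrences):
        spec, env = fitted_envelope
        p = es.project_occurrence(env, historic_stack)
        occ = occurrences[occurrences["species"] == spec.species_name]
        lat, lon = historic_stack.lat.values, historic_stack.lon.values
        ii = np.abs(occ["lat"].to_numpy()[:, None] - lat[None, :]).argmin(axis=1)
        jj = np.abs(occ["lon"].to_numpy()[:, None] - lon[None, :]).argmin(axis=1)
        inside = np.zeros(p.shape, bool)
        inside[ii, jj] = True
        assert p.values[inside].mean() > 2 * p.values[~inside].mean()

    def test_support_constraint_far_shift_gives_zero(self, fitted_envelope,
                                                     historic_stack):
        _, env = fitted_envelope
        shifted = historic_stack + 1e4
        shifted.attrs.update(historic_stack.attrs)
        p = es.project_occurrence(env, shifted)
        assert np.all(p.values == 0.0)

    def test_projection_deterministic(self, fitted_envelope, historic_stack):
        _, env = fitted_envelope
        a = es.project_occurrence(env, historic_stack)
        b = es.project_occurrence(env, historic_stack)
        assert np.array_equal(a.values, b.values)

    def test_missing_variable_rejected(self, fitted_envelope, historic_stack):
        _, env = fitted_envelope
        reduced = historic_stack.drop_vars(env.variables[0])
        with pytest.raises(ValueError, match="lacks"):
            es.project_occurrence(env, reduced)

    def test_envelope_json_roundtrip(self, fitted_envelope, historic_stack):
        _, env = fitted_envelope
        clone = es.SpeciesEnvelope.from_json(env.to_json())
        a = es.project_occurrence(env, historic_stack)
        b = es.project_occurrence(clone, historic_stack)
        assert np.array_equal(a.values, b.values)


class TestEnsemble:
    def _cube(self, p_by_model):
        import xarray as xr
        arr = np.array(p_by_model, float)[None, None]  # species, period
        da = xr.DataArray(
            arr, dims=("species", "period", "model", "lat", "lon"),
            coords={"species": ["sp"], "period": ["h"],
                    "model": [f"m{i}" for i in range(arr.shape[2])],
                    "lat": np.arange(arr.shape[3], dtype=float),
                    "lon": np.arange(arr.shape[4], dtype=float)})
        return es.ProjectionCube(da)

    def test_identical_members_mean_equals_member(self):
        field = np.random.default_rng(0).random((3, 3))
        cube = self._cube([field, field])
        assert np.allclose(cube.ensemble_mean().values[0, 0], field)

    def test_two_member_average(self):
        cube = self._cube([np.full((2, 2), 0.2), np.full((2, 2), 0.4)])
        assert np.allclose(cube.ensemble_mean().values, 0.3)

    def test_mean_bounded_by_members(self):
        rng = np.random.default_rng(1)
        members = rng.random((4, 5, 5))
        cube = self._cube(list(members))
        em = cube.ensemble_mean().values[0, 0]
        assert np.all(em <= members.max(axis=0) + 1e-12)
        assert np.all(em >= members.min(axis=0) - 1e-12)

    def test_probability_bounds_enforced(self):
        with pytest.raises(ValueError, match="0, 1"):
            self._cube([np.full((2, 2), 1.4), np.full((2, 2), 0.2)])
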