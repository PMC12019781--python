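"""Evaluation statistics: closed forms, classifications, invariances."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr
from hypothesis import given, settings
from hypothesis import strategies as st

import envelopeshift as es
from envelopeshift.evaluation import (CLASS_ABSENT, CLASS_CHANGED,
                                      CLASS_EXPANDED, CLASS_EXTINCT,
                                      CLASS_NEWLY_COLONIZED, anova_partition,
                                      delta_p_histogram, diversity_change)


def _field(arr):
    arr = np.atleast_2d(np.asarray(arr, float))
    return xr.DataArray(arr, dims=("lat", "lon"),
                        coords={"lat": np.arange(arr.shape[0], dtype=float) + 45,
                                "lon": np.arange(arr.shape[1], dtype=float)})


def _cube(p, species=None, periods=None):
    p = np.asarray(p, float)
    ns, np_, nm, ny, nx = p.shape
    da = xr.DataArray(
        p, dims=("species", "period", "model", "lat", "lon"),
        coords={"species": species or [f"s{i}" for i in range(ns)],
                "period": periods or [f"p{i}" for i in range(np_)],
                "model": [f"m{i}" for i in range(nm)],
                "lat": np.arange(ny, dtype=float) + 45,
                "lon": np.arange(nx, dtype=float)})
    return es.ProjectionCube(da)


class TestDeltaP:
    def test_unchanged_probability_is_zero(self):
        d = es.delta_p(_field([[0.4]]), _field([[0.4]]))
        assert d.delta_p.values[0, 0] == pytest.approx(0.0)

    def test_halving_is_minus_fifty_percent(self):
        d = es.delta_p(_field([[0.4]]), _field([[0.2]]))
        assert d.delta_p.values[0, 0] == pytest.approx(-50.0)

    def test_local_extinction_class(self):
        d = es.delta_p(_field([[0.3]]), _field([[0.0]]))
        assert d.classes.values[0, 0] == CLASS_EXTINCT
        assert d.delta_p.values[0, 0] == pytest.approx(-100.0)

    def test_expansion_class(self):
        d = es.delta_p(_field([[0.0]]), _field([[0.25]]))
        assert d.classes.values[0, 0] == CLASS_EXPANDED
        assert np.isnan(d.delta_p.values[0, 0])

    def test_every_cell_in_exactly_one_class(self):
        rng = np.random.default_rng(0)
        h = rng.random((10, 10)) * (rng.random((10, 10)) > 0.3)
        f = rng.random((10, 10)) * (rng.random((10, 10)) > 0.3)
        d = es.delta_p(_field(h), _field(f))
        cls = d.classes.values
        # brute-force recount
        eps = 1e-3
        assert (cls == CLASS_EXTINCT).sum() == np.sum((h > eps) & (f <= eps))
        assert (cls == CLASS_EXPANDED).sum() == np.sum((h <= eps) & (f > eps))
        assert (cls == CLASS_CHANGED).sum() == np.sum((h > eps) & (f > eps))
        assert (cls == CLASS_ABSENT).sum() == np.sum((h <= eps) & (f <= eps))

    def test_negative_probability_rejected(self):
        with pytest.raises(ValueError):
            es.delta_p(_field([[-0.1]]), _field([[0.2]]))

    def test_histogram_bins_and_special_bars(self):
        h = _field([[0.4, 0.4, 0.4, 0.0]])
        f = _field([[0.2, 0.44, 0.0, 0.3]])
        d = es.delta_p(h, f)
        hist = delta_p_histogram(d)
        assert int(hist.loc[hist["bin"] == "extinct", "cells"].iloc[0]) == 1
        assert int(hist.loc[hist["bin"] == "expanded", "cells"].iloc[0]) == 1
        assert hist["cells"].sum() == 4
        assert hist["share"].sum() == pytest.approx(1.0)


class TestDistributionCenter:
    def test_single_cell_center(self):
        p = _field([[0.0, 0.7], [0.0, 0.0]])
        for method in ("geometric", "arithmetic"):
            c = es.distribution_center(p, method=method)
            assert c.lon == pytest.approx(1.0)
            assert c.lat == pytest.approx(45.0)
            assert c.extent_cells == 1

    def test_symmetric_pair_arithmetic_midpoint(self):
        p = xr.DataArray([[0.5], [0.5]], dims=("lat", "lon"),
                         coords={"lat": [50.0, 60.0], "lon": [5.0]})
        c = es.distribution_center(p, method="arithmetic")
        assert c.lat == pytest.approx(55.0)

    def test_weight_rescaling_leaves_center(self):
        rng = np.random.default_rng(2)
        p = _field(rng.random((6, 6)))
        a = es.distribution_center(p)
        b = es.distribution_center(p * 2.0)
        assert a.lon == pytest.approx(b.lon) and a.lat == pytest.approx(b.lat)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            es.distribution_center(_field([[0.0, 0.0]]))


class TestMeanOccurrence:
    def test_uniform_field(self):
        assert es.mean_occurrence(_field([[0.5, 0.5]])) == pytest.approx(0.5)

    def test_zero_cells_excluded(self):
        assert es.mean_occurrence(_field([[0.2, 0.4, 0.0]])) == pytest.approx(0.3)

    def test_linearity(self):
        p = _field([[0.2, 0.6, 0.1]])
        assert es.mean_occurrence(p * 0.5) == pytest.approx(
            es.mean_occurrence(p) / 2)

    def test_empty_field_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert es.mean_occurrence(_field([[0.0]])) == 0.0


class TestDominance:
    def test_single_species_dominates_everywhere(self):
        cube = _cube(np.full((1, 1, 1, 2, 2), 0.4))
        dom, pf = es.dominant_species(cube.ensemble_mean(period="p0"))
        assert np.all(dom.values == 0)
        assert np.allclose(pf.values, 0.4)

    def test_disjoint_maxima_partition(self):
        p = np.zeros((2, 1, 1, 1, 2))
        p[0, 0, 0, 0, 0] = 0.8
        p[1, 0, 0, 0, 1] = 0.6
        cube = _cube(p)
        dom, _ = es.dominant_species(cube.ensemble_mean(period="p0"))
        assert dom.values.tolist() == [[0, 1]]

    def test_tie_goes_alphabetical(self):
        p = np.full((2, 1, 1, 1, 1), 0.5)
        cube = _cube(p, species=["zeta", "alpha"])
        dom, _ = es.dominant_species(cube.ensemble_mean(period="p0"))
        legend = dom.attrs["legend"]
        assert legend[int(dom.values[0, 0])] == "alpha"

    def test_rescaling_leaves_dominance(self):
        rng = np.random.default_rng(4)
        p = rng.random((3, 1, 1, 5, 5))
        a, _ = es.dominant_species(_cube(p).ensemble_mean(period="p0"))
        b, _ = es.dominant_species(_cube(p * 0.5).ensemble_mean(period="p0"))
        assert np.array_equal(a.values, b.values)

    def test_identity_maps_zero_change(self):
        rng = np.random.default_rng(5)
        f = rng.random((2, 1, 3, 3)) * 0.9 + 0.05
        p = np.stack([f, f], axis=1)  # two identical periods
        cube = _cube(p, periods=["h", "f"])
        map_a, map_b = es.dominance_change_maps(cube, "h", "f")
        assert np.allclose(map_a.delta_p.values, 0.0)
        assert np.allclose(map_b.delta_p.values, 0.0)

    def test_extinct_dominant_and_new_colonizer(self):
        # species 0 dominant historically then gone; species 1 appears
        p = np.zeros((2, 2, 1, 1, 1))
        p[0, 0] = 0.8   # sp0 historic
        p[1, 1] = 0.5   # sp1 future only
        cube = _cube(p, periods=["h", "f"])
        map_a, map_b = es.dominance_change_maps(cube, "h", "f")
        assert map_a.classes.values[0, 0] == CLASS_EXTINCT
        assert map_b.classes.values[0, 0] == CLASS_NEWLY_COLONIZED


class TestReplacement:
    def test_no_extinctions_empty_tally(self):
        f = np.full((1, 1, 2, 2), 0.5)
        cube = _cube(np.stack([f, f], axis=1), periods=["h", "f"])
        tally = es.replacement_tally(cube, ["s0"], "h", "f")
        assert tally.empty

    def test_constructed_switch_counts_cells(self):
        p = np.zeros((2, 2, 1, 2, 3))
        p[0, 0] = 0.9           # A dominant everywhere historically
        p[1, 1] = 0.7           # only B present in the future
        cube = _cube(p, species=["A", "B"], periods=["h", "f"])
        tally = es.replacement_tally(cube, ["A"], "h", "f")
        assert tally.to_dict("records") == [
            {"focal": "A", "replacement": "B", "cells": 6}]

    def test_row_sums_match_bruteforce(self):
        rng = np.random.default_rng(6)
        p = rng.random((3, 2, 2, 8, 8))
        p[:, 1] *= rng.random((3, 1, 8, 8)) > 0.5  # some extinctions
        cube = _cube(p, periods=["h", "f"])
        tally = es.replacement_tally(cube, ["s0", "s1", "s2"], "h", "f")
        em_h = cube.ensemble_mean(period="h").values
        em_f = cube.ensemble_mean(period="f").values
        eps = 1e-3
        dom = np.where(em_h.max(axis=0) > eps, em_h.argmax(axis=0), -1)
        for k, sp in enumerate(["s0", "s1", "s2"]):
            expected = int(np.sum((dom == k) & (em_f[k] <= eps)))
            got = int(tally.loc[tally["focal"] == sp, "cells"].sum())
            assert got == expected

    def test_min_count_suppresses_rare_pairs(self):
        p = np.zeros((2, 2, 1, 1, 2))
        p[0, 0] = 0.9
        p[1, 1] = 0.7
        cube = _cube(p, species=["A", "B"], periods=["h", "f"])
        assert es.replacement_tally(cube, ["A"], "h", "f", min_count=3).empty


class TestShannon:
    def test_single_species_zero(self):
        assert es.shannon_h(np.array([[0.7]])) == pytest.approx(0.0)

    def test_two_equal_shares_ln2(self):
        assert es.shannon_h(np.array([[0.3], [0.3]]))[0] == pytest.approx(
            np.log(2))

    def test_three_equal_and_scale_invariance(self):
        p = np.array([[0.2], [0.2], [0.2]])
        assert es.shannon_h(p)[0] == pytest.approx(np.log(3))
        assert es.shannon_h(p * 3.3)[0] == pytest.approx(np.log(3))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            es.shannon_h(np.array([[-0.1], [0.5]]))

    @given(st.lists(st.floats(0.001, 1.0), min_size=1, max_size=8))
    @settings(max_examples=50, deadline=None)
    def test_bounds(self, ps):
        h = es.shannon_h(np.array(ps)[:, None])[0]
        assert -1e-9 <= h <= np.log(len(ps)) + 1e-9

    def test_delta_h_antisymmetric(self):
        rng = np.random.default_rng(7)
        a = xr.DataArray(rng.random((3, 4, 4)), dims=("species", "lat", "lon"),
                         coords={"species": list("abc"),
                                 "lat": np.arange(4.0), "lon": np.arange(4.0)})
        b = a.copy(deep=True)
        b.values[:] = rng.random((3, 4, 4))
        fwd = diversity_change(a, b)
        rev = diversity_change(b, a)
        assert np.allclose(fwd.delta_h.values, -rev.delta_h.values)


class TestUncertainty:
    def test_identical_models_zero_sd(self):
        assert es.percentual_sd(np.array([0.4, 0.4, 0.4])) == pytest.approx(0.0)

    def test_worked_example(self):
        """mean 0.3, sample SD 0.1414 -> ~47.1%."""
        sp = es.percentual_sd(np.array([0.2, 0.4]))
        assert sp == pytest.approx(np.sqrt(0.02) / 0.3 * 100, rel=1e-12)
        assert sp == pytest.approx(47.1, abs=0.05)

    def test_scale_invariance(self):
        p = np.array([0.1, 0.3, 0.25])
        assert es.percentual_sd(p * 2.0) == pytest.approx(es.percentual_sd(p))

    def test_single_model_rejected(self):
        with pytest.raises(ValueError):
            es.percentual_sd(np.array([0.4]))

    def test_anova_model_only_variation(self):
        table = np.array([[0.1, 0.1], [0.4, 0.4], [0.7, 0.7]])
        m, s, r = anova_partition(table)
        assert (m, s, r) == pytest.approx((1.0, 0.0, 0.0), abs=1e-12)

    def test_anova_hand_oracle_2x2(self):
        m, s, r = anova_partition(np.array([[0.1, 0.2], [0.3, 0.4]]))
        assert m == pytest.approx(0.8)
        assert s == pytest.approx(0.2)
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_anova_shares_sum_to_one_random(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            shares = anova_partition(rng.random((4, 3)))
            assert sum(shares) == pytest.approx(1.0)
            assert all(v >= 0 for v in shares)

    def test_anova_matches_statsmodels(self):
        """Independent oracle: OLS + anova_lm on the long-format table."""
        import statsmodels.api as sm
        from statsmodels.formula.api import ols
        rng = np.random.default_rng(9)
        table = rng.random((5, 3))
        nm, ns = table.shape
        df = pd.DataFrame({
            "p": table.ravel(),
            "model": np.repeat([f"m{i}" for i in range(nm)], ns),
            "scenario": np.tile([f"s{j}" for j in range(ns)], nm)})
        fit = ols("p ~ C(model) + C(scenario)", df).fit()
        tab = sm.stats.anova_lm(fit, typ=2)
        total = tab["sum_sq"].sum()
        m, s, r = anova_partition(table)
        assert m == pytest.approx(tab.loc["C(model)", "sum_sq"] / total)
        assert s == pytest.approx(tab.loc["C(scenario)", "sum_sq"] / total)
        assert r == pytest.approx(tab.loc["Residual", "sum_sq"] / total)

    def test_anova_level_relabelling_invariance(self):
        rng = np.random.default_rng(10)
        table = rng.random((4, 3))
        base = anova_partition(table)
        perm = anova_partition(table[rng.permutation(4)][:, rng.permutation(3)])
        assert base == pytest.approx(perm)

    def test_unbalanced_rejected(self):
        t = np.array([[0.1, np.nan], [0.3, 0.4]])
        with pytest.raises(ValueError, match="nbalanced"):
            anova_partition(t)
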