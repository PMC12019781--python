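import itertools

import numpy as np
import pytest

import envelopeshift as es


@pytest.fixture(scope="session")
def world_cfg():
    return es.SyntheticWorldConfig(grid_nx=20, grid_ny=20, fine_factor=2,
                                   n_models=2)


@pytest.fixture(scope="session")
def climate(world_cfg):
    return es.generate_climate(world_cfg)


@pytest.fixture(scope="session")
def historic_stack(climate):
    return es.compute_bioclim(climate.observed["temperature"],
                              climate.observed["precipitation"], (1951, 1980))


def make_species_specs(stack, n_species, n_records=300, seed=7,
                       tol_sd=0.4, pool=None):
    """Species with known envelopes drawn from a collinearity-pruned
    variable pool, so the generating pair is identifiable."""
    if pool is None:
        pool = es.prune_collinear_variables(stack, 0.8)
    rng = np.random.default_rng(seed)
    pairs = list(itertools.combinations(pool, 2))
    specs = []
    for k in range(n_species):
        vars_ = pairs[k % len(pairs)]
        optima = tuple(float(np.quantile(stack[v].values, rng.uniform(0.25, 0.75)))
                       for v in vars_)
        tols = tuple(float(stack[v].values.std() * tol_sd) for v in vars_)
        specs.append(es.SyntheticSpeciesSpec(
            f"sp{k:02d}", vars_, optima, tols, n_records))
    return specs


@pytest.fixture(scope="session")
def species_specs(historic_stack):
    return make_species_specs(historic_stack, n_species=3)


@pytest.fixture(scope="session")
def occurrences(species_specs, historic_stack):
    return es.generate_occurrences(species_specs, historic_stack, seed=55)


@pytest.fixture(scope="session")
def fitted_envelope(occurrences, species_specs, historic_stack):
    spec = species_specs[0]
    occ = occurrences[occurrences["species"] == spec.species_name]
    env = es.calibrate_envelope(occ, historic_stack, background_seed=1)
    return spec, env
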