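import pytest

import genoderive as gd


@pytest.fixture(scope="session")
def fixture_set():
    return gd.example_catalog()


@pytest.fixture(scope="session")
def catalog(fixture_set):
    return fixture_set.catalog


@pytest.fixture(scope="session")
def sim_run():
    """A seeded 1000-genotype simulated catalog plus one derive run."""
    params = gd.SimulationParams(seed=11, n_genotypes=1000)
    catalog, annotations = gd.simulate_catalog(params)
    derived, traces = gd.derive_annotations(annotations, catalog)
    return catalog, annotations, derived, traces
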