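import numpy as np
import pytest

from rangegap import envreduce, synth


@pytest.fixture(scope="session")
def landscape():
    """50x50, 6-variable autocorrelated present-scenario stack."""
    return synth.generate_landscape(seed=1, grid_shape=(50, 50), n_vars=6, autocorr_scale=5.0)


@pytest.fixture(scope="session")
def axis_model(landscape):
    return envreduce.fit_axes(landscape, variance_target=0.95)


@pytest.fixture(scope="session")
def score_stack(landscape, axis_model):
    return envreduce.project(landscape, axis_model)


@pytest.fixture(scope="session")
def species(landscape):
    """Virtual species whose optimum sits at a real cell's climate (non-empty range)."""
    anchor = (25, 25)
    niche = {
        name: (float(landscape.layers[i, anchor[0], anchor[1]]), 1.0)
        for i, name in enumerate(landscape.var_names)
    }
    return synth.generate_virtual_species(landscape, niche, range_cut=0.3, taxon_id="sp_fix")


@pytest.fixture(scope="session")
def occurrences(species):
    n = min(60, int(species.true_range.sum()))
    return synth.sample_occurrences(species, n, seed=5)


@pytest.fixture(scope="session")
def protected_areas():
    return synth.generate_protected_areas((50, 50), n_areas=40, size_range=(2, 6), seed=3)


@pytest.fixture(scope="session")
def landcover():
    return synth.generate_landcover((50, 50), forest_fraction=0.7, autocorr_scale=5.0, seed=4)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
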