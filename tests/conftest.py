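import numpy as np
import pytest

from keyhabitat import occurrence as occ
from keyhabitat import synth
from keyhabitat.grid import GridLayer


@pytest.fixture(scope="session")
def landscape():
    return synth.generate_landscape(seed=1)


@pytest.fixture(scope="session")
def small_landscape():
    return synth.generate_landscape(seed=7, coarse_shape=(30, 30),
                                    refine_factor=2)


@pytest.fixture(scope="session")
def design(landscape):
    return synth.simulate_ground_truth(landscape, n_points=30, stops=3,
                                       spacing=500.0, n_discard=5, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def simple_layer():
    return GridLayer(np.arange(16, dtype=float).reshape(4, 4), cell_size=1.0)


@pytest.fixture(scope="session")
def truth_stack(landscape):
    """Standardized stack over the generating covariates, no study mask, so
    its standardization equals the landscape's truth standardization."""
    names = list(landscape.truth_covariates)
    stack = occ.CovariateStack(names,
                               {n: landscape.layers[n] for n in names})
    return occ.transform_and_standardize(stack, [])
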