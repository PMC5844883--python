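import numpy as np
import pytest

from cisflux import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tracing_scenario():
    return synthetic.default_tracing_scenario(seed=7)


@pytest.fixture
def noiseless_tracing():
    return synthetic.default_tracing_scenario(seed=7, noise_cv=0.0)


@pytest.fixture
def image_scenario():
    return synthetic.ImageScenario(n_nuclei=10, image_size=(256, 256),
                                   background_sd=0.0,
                                   foci_per_nucleus=("fixed", 0), seed=3)


def random_mids(rng: np.random.Generator, n_carbons: int, size: int) -> np.ndarray:
    """Random valid MIDs (rows sum to 1, non-negative) via a flat Dirichlet."""
    return rng.dirichlet(np.ones(n_carbons + 1), size=size)
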