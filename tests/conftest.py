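import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20140108)


@pytest.fixture(scope="session")
def glmm_dataset():
    """Small clustered binary dataset: 20 sets x ~12 fish, sigma = 0.5."""
    rng = np.random.default_rng(7)
    n_sets = 20
    nf = np.maximum(rng.poisson(12, n_sets), 1)
    groups = np.repeat(np.arange(n_sets), nf)
    b = rng.normal(0, 0.5, n_sets)
    length = rng.normal(85, 8, groups.size)
    eta = 0.2 * (length - 87) + b[groups]
    y = (rng.random(groups.size) < 1 / (1 + np.exp(-eta))).astype(float)
    X = np.column_stack([np.ones_like(length), length - 85.0])
    return X, y, groups


@pytest.fixture(scope="session")
def small_population():
    """Default-scale synthetic scenario (~1500-fish sample)."""
    from matogive import PopulationParams, simulate_population

    params = PopulationParams(seed=11)
    pop = simulate_population(params)
    return params, pop
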