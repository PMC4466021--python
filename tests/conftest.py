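import numpy as np
import pytest

from lgmlayers import EnsembleConfig, GridSpec, generate_pseudo_gcm_ensemble


@pytest.fixture(scope="session")
def coarse_grid() -> GridSpec:
    """A 4-degree global grid: cheap but large enough for spatial structure."""
    return GridSpec.global_grid(4.0)


@pytest.fixture(scope="session")
def default_ensemble(coarse_grid):
    """One default 9-model / 4-group synthetic ensemble, shared across tests."""
    return generate_pseudo_gcm_ensemble(EnsembleConfig(seed=42), coarse_grid)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
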