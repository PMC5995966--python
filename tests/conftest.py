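import numpy as np
import pytest

from eegsnn.brain_space import SmallWorldConfig, build_atlas, init_small_world
from eegsnn.reservoir_learning import ReservoirModel


@pytest.fixture(scope="session")
def coarse_atlas():
    """~220-neuron atlas shared by tests that need a realistic head lattice."""
    return build_atlas(resolution=2.0)


@pytest.fixture(scope="session")
def default_atlas():
    """Full-resolution (~1,700 neuron) atlas; built once per session."""
    return build_atlas(resolution=1.0)


@pytest.fixture()
def small_model(coarse_atlas):
    syn = init_small_world(coarse_atlas, SmallWorldConfig(seed=7))
    return ReservoirModel(coarse_atlas, syn)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
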