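import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

import pathcommit as pc


@pytest.fixture(scope="session")
def dw_1d():
    """Bare 1D double well (no bath, no noise), default barrier."""
    return pc.PotentialSpec(kind="double_well_bath", n_bath=0,
                            n_noise_features=0)


@pytest.fixture(scope="session")
def states():
    return pc.default_states()


@pytest.fixture(scope="session")
def octahedron():
    return pc.make_ideal_shell("octahedron", 0.2)


@pytest.fixture(scope="session")
def sigmoid_dataset():
    """2000-point binomially labelled dataset, committor sigmoid(3 x1),
    10 pure-noise features, 100 trials per point."""
    return pc.fixture_shooting_data(
        n_points=2000, n_features=11, n_trials=100, seed=11
    )


@pytest.fixture(scope="session")
def trained_model(sigmoid_dataset):
    spec = pc.MLPSpec(n_hidden_layers=2, neurons_per_layer=64,
                      learning_rate=1e-3)
    return pc.train(spec, sigmoid_dataset, rng_seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
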