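import numpy as np
import pytest

from cfdeconv import BetaParams, SimulationConfig, simulate_fragments


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def two_class_config():
    """Small tumor/normal simulation used across modules."""
    return SimulationConfig.uniform_markers(
        {"tumor": BetaParams(8, 2), "normal": BetaParams(2, 8)},
        {"tumor": 0.2, "normal": 0.8},
        n_markers=5,
        n_fragments=500,
        seed=11,
    )


@pytest.fixture
def two_class_sim(two_class_config):
    return simulate_fragments(two_class_config)
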