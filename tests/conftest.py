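import numpy as np
import pytest

from moodfuse import preprocess
from moodfuse.simulate import SimulatorConfig, simulate_dataset


@pytest.fixture(scope="session")
def tiny_config():
    return SimulatorConfig(n_participants=4, n_days=3, prompts_per_day=5,
                           speech_dim=12, seed=7)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    dataset, truth = simulate_dataset(tiny_config)
    return dataset, truth


@pytest.fixture(scope="session")
def prepared(tiny_dataset):
    """Cleaned, normalized, standardized tiny dataset with its split."""
    dataset, _ = tiny_dataset
    ds, split, stats, report = preprocess(dataset)
    return ds, split, stats, report


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
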