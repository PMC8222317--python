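import numpy as np
import pytest

from clickchange.params import ObserverParams, TaskConfig
from clickchange.task import generate_dataset


@pytest.fixture(scope="session")
def observer():
    return ObserverParams()


@pytest.fixture(scope="session")
def task_config():
    return TaskConfig()


@pytest.fixture(scope="session")
def dataset_3k(task_config, observer):
    """Shared synthetic dataset: 3000 trials of the full task design."""
    trials, clicks = generate_dataset(task_config, observer, 3000, seed=101)
    return trials, clicks


@pytest.fixture(scope="session")
def dataset_small(task_config, observer):
    """Small dataset for API-level tests."""
    trials, clicks = generate_dataset(task_config, observer, 300, seed=7)
    return trials, clicks


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
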