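import numpy as np
import pytest

from emgdenoise import SimulationSpec, make_training_set, simulate_record
from emgdenoise.detect import train_classifier


@pytest.fixture(scope="session")
def default_spec():
    return SimulationSpec(seed=42)


@pytest.fixture(scope="session")
def record(default_spec):
    return simulate_record(default_spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_training_set():
    """40 epochs per class at the default (well separated) artifact gain."""
    return make_training_set(40, SimulationSpec(seed=7))


@pytest.fixture(scope="session")
def trained_model(small_training_set):
    epochs, labels = small_training_set
    model, report = train_classifier(epochs, labels, seed=0)
    return model, report
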