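import numpy as np
import pytest

from harcascade import ClassifierSpec, feature_table, simulate_scenario
from harcascade.protocols import separable_config, separable_training_script


@pytest.fixture(scope="session")
def clean_config():
    """Low-noise, spike-free configuration of the separable regime."""
    return separable_config(seed=11)


@pytest.fixture(scope="session")
def separable_stream(clean_config):
    """Well-separated training stream: many short segments per activity."""
    return simulate_scenario(separable_training_script(reps=8), clean_config)


@pytest.fixture(scope="session")
def separable_table(separable_stream):
    return feature_table(separable_stream)


@pytest.fixture(scope="session")
def rf_spec():
    return ClassifierSpec("RF", seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
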