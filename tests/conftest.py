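import numpy as np
import pytest

from pupilvalence import GeneratorConfig, generate_dataset, preprocess_dataset
from pupilvalence.features import extract_feature_table
from pupilvalence.io import stimuli_frame


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down study: 12 participants x 16 stimuli, default effects."""
    return GeneratorConfig(seed=1004, n_participants=12, n_positive=8, n_negative=8)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_feature_table(small_dataset):
    trials, stimuli = small_dataset
    kept, _ = preprocess_dataset(trials)
    return extract_feature_table(kept, stimuli_frame(stimuli))


@pytest.fixture()
def rng():
    return np.random.default_rng(1004)
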