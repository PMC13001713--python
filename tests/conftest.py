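import numpy as np
import pytest

from speechtrace import synth


@pytest.fixture(scope="session")
def small_config():
    """A small but complete study configuration shared across tests."""
    return synth.SynthConfig(n_subjects=3, n_sentences_per_cell=3,
                             speakers=2, seed=123, epoch_post=3.5)


@pytest.fixture(scope="session")
def small_stimuli(small_config):
    return synth.gen_stimuli(small_config)


@pytest.fixture(scope="session")
def square_positions():
    """Four electrodes on a unit square (2-D)."""
    return np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
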