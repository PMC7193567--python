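import numpy as np
import pytest

from dcmir import dcm, synthgen


@pytest.fixture(scope="session")
def model_space():
    return dcm.enumerate_model_space()


@pytest.fixture(scope="session")
def full_model(model_space):
    return model_space[-1]


@pytest.fixture()
def small_config():
    """A light cohort: 2 subjects, few trials, coarse frequency grid."""
    return synthgen.SimConfig(
        n_subjects=2,
        n_trials=6,
        freq_grid=np.arange(4.0, 49.0, 4.0),
        seed=123,
    )


@pytest.fixture()
def sim_grid():
    cfg = synthgen.SimConfig()
    return cfg.sim_t_grid()
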