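import numpy as np
import pytest

from attnpupil.pupil_preprocess import SampleSeries
from attnpupil.trial_design import DesignConfig, build_design


@pytest.fixture
def default_config():
    return DesignConfig(seed=7)


@pytest.fixture
def default_design(default_config):
    return build_design(default_config)


@pytest.fixture
def small_config():
    return DesignConfig(n_trials=16, n_blocks=4, seed=3)


def make_series(pupil, fs=1000.0, valid=None):
    pupil = np.asarray(pupil, dtype=float)
    if valid is None:
        valid = np.ones(pupil.size, dtype=bool)
    return SampleSeries(time=np.arange(pupil.size) / fs, pupil=pupil,
                        valid=np.asarray(valid, dtype=bool), sampling_rate=fs)


@pytest.fixture
def constant_series():
    return make_series(np.full(2000, 5.0))
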