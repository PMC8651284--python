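import numpy as np
import pytest

from gliderpsych import ObserverParams, default_grid


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def std_params():
    """The canonical starting point of the fitting procedure."""
    return ObserverParams(prior_logodds=0.1, noise_sd=0.4)


@pytest.fixture
def grid():
    return default_grid()
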