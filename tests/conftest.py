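import numpy as np
import pytest

from sornseq import SornParams, SornSequenceLearner, init_network
from sornseq.io import make_fixture


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_params():
    return SornParams(n_excitatory=20, n_inhibitory=4, n_input_per_symbol=2, seed=7)


@pytest.fixture
def tiny_net(tiny_params, rng):
    return init_network(tiny_params, rng)


@pytest.fixture
def toy_tasks(rng):
    return make_fixture("toy-tasks", rng)


@pytest.fixture
def fitted_tiny_learner(toy_tasks):
    learner = SornSequenceLearner(
        n_excitatory=20, n_input_per_symbol=2, record_states=True, random_state=3
    )
    return learner.fit(toy_tasks)
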