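import numpy as np
import pytest

from rstdp import NetworkParams, NeuronParams, PlasticityParams


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture
def net():
    return NetworkParams()


@pytest.fixture
def neuron():
    return NeuronParams()


@pytest.fixture
def plast():
    # unit learning rate: pair contributions equal the raw window amplitudes
    return PlasticityParams(eta=1.0)


@pytest.fixture
def tiny_net():
    """A small network for fast end-to-end runs."""
    return NetworkParams(N_U=40, N_T=2, N_B=2 * 250)
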