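import numpy as np
import pytest

from spikecsp import NetworkSpec, NeuronParams
from spikecsp.energy import EnergyModel


@pytest.fixture
def two_neuron_net() -> NetworkSpec:
    """Two principal neurons, zero biases, symmetric weight 1."""
    net = NetworkSpec()
    a = net.add_neuron(NeuronParams(), principal=True)
    b = net.add_neuron(NeuronParams(), principal=True)
    net.add_symmetric(a, b, 1.0)
    return net


@pytest.fixture
def small_symmetric_model() -> EnergyModel:
    """Seeded random 6-unit symmetric energy model with moderate couplings."""
    rng = np.random.default_rng(123)
    n = 6
    W = rng.normal(scale=0.6, size=(n, n))
    W = np.triu(W, 1)
    W = W + W.T
    b = rng.normal(scale=0.5, size=n)
    return EnergyModel(b, W)


def net_from_model(model: EnergyModel) -> NetworkSpec:
    """Spiking network whose principal subnetwork realizes the model."""
    net = NetworkSpec()
    ids = [net.add_neuron(NeuronParams(bias=b), principal=True) for b in model.biases]
    n = model.n_units
    for i in range(n):
        for j in range(i + 1, n):
            if model.weights[i, j] != 0.0:
                net.add_symmetric(ids[i], ids[j], float(model.weights[i, j]))
    return net
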