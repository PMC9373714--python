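import numpy as np
import pytest

from dopanet.cells import build_template
from dopanet.fixtures import two_neuron_config
from dopanet.io import load_manifest
from dopanet.network import build_network


@pytest.fixture(scope="session")
def templates():
    return {k: build_template(k) for k in ("MSN", "PYR", "PV", "CB")}


@pytest.fixture(scope="session")
def default_config():
    return load_manifest()


@pytest.fixture(scope="session")
def default_network(default_config):
    return build_network(default_config)


@pytest.fixture(scope="session")
def two_neuron_net():
    cfg = two_neuron_config(seed=11, duration=600.0)
    return build_network(cfg)


@pytest.fixture(scope="session")
def short_recording(two_neuron_net):
    """A short (600 ms) two-neuron trial, reused by io/analysis tests."""
    from dopanet.simulate import SimulationProtocol, run_trial

    proto = SimulationProtocol(duration=600.0, dt=0.02)
    return run_trial(two_neuron_net.config, proto, trial_index=0)
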