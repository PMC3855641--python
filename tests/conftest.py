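import numpy as np
import pytest

from laminet import build_network, load_model_spec, make_fixture_network
from laminet.engine import attach_background


@pytest.fixture(scope="session")
def fixture_net():
    """Miniature 8-microcircuit network (20 neurons/population)."""
    spec, net = make_fixture_network(n_per_population=20, seed=7)
    return spec, net


@pytest.fixture(scope="session")
def fixture_net_bg(fixture_net):
    spec, net = fixture_net
    return spec, net, attach_background(net, spec)


@pytest.fixture(scope="session")
def reference_spec():
    return load_model_spec(None)
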