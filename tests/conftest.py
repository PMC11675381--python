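import networkx as nx
import numpy as np
import pytest

import spinflow as sf

# study settings for the kite reference analysis
KITE_BETA = 0.534
TAU_MAX = 300
# levels up to the tipping point; the zero-field model is flip-symmetric,
# so levels above 1/2 mirror these exactly
KITE_GAMMAS = np.arange(0, 6) / 10


@pytest.fixture(scope="session")
def kite_system():
    return sf.SpinSystem(graph=sf.make_kite(), beta=KITE_BETA)


@pytest.fixture(scope="session")
def kite_transfer(kite_system):
    return sf.build_transfer_operator(kite_system)


@pytest.fixture(scope="session")
def kite_pi(kite_transfer):
    return sf.stationary_distribution(kite_transfer)


@pytest.fixture(scope="session")
def kite_flows(kite_transfer, kite_pi):
    return sf.information_flows(
        kite_transfer, kite_pi, gammas=KITE_GAMMAS, tau_max=TAU_MAX
    )


@pytest.fixture(scope="session")
def kite_roles(kite_flows):
    return sf.assign_roles(kite_flows)


@pytest.fixture(scope="session")
def triangle_system():
    return sf.SpinSystem(graph=nx.complete_graph(3), beta=1.0)


@pytest.fixture(scope="session")
def triangle_transfer(triangle_system):
    return sf.build_transfer_operator(triangle_system)


@pytest.fixture(scope="session")
def er_system():
    graph = sf.make_er(10, 0.2, seed=7, require_connected=True)
    return sf.SpinSystem(graph=graph, beta=KITE_BETA)
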