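import numpy as np
import pytest

from dfscan.enm import build_network, pseudo_inverse
from dfscan.fixtures import FixtureSpec, make_structure


@pytest.fixture(scope="session")
def tetrahedron():
    return make_structure(FixtureSpec("tetrahedron"))


@pytest.fixture(scope="session")
def tetra_net(tetrahedron):
    return build_network(tetrahedron, r_c=5.0)


@pytest.fixture(scope="session")
def helix20():
    return make_structure(FixtureSpec("helix", 20))


@pytest.fixture(scope="session")
def helix20_net(helix20):
    return build_network(helix20)


@pytest.fixture(scope="session")
def helix20_invH(helix20_net):
    return pseudo_inverse(helix20_net)


@pytest.fixture()
def rng():
    return np.random.default_rng(20170814)
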