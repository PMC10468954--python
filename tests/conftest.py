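import pytest

import fluxgeom as fg


def _shape_for_seed(seed: int) -> tuple[int, int, int]:
    """Deterministic small-network shapes for the cross-method test pool."""
    m = 3 + seed % 3
    n = 6 + seed % 5
    n_irr = (seed * 7) % (n + 1)
    return m, n, n_irr


@pytest.fixture(scope="session")
def ex54_net():
    return fg.fixture_ex54()


@pytest.fixture(scope="session")
def ex54_cone(ex54_net):
    return fg.build_cone(ex54_net)


@pytest.fixture(scope="session")
def ex54_efms(ex54_cone):
    return fg.enumerate_efms(ex54_cone)


@pytest.fixture(scope="session")
def fig1_net():
    return fg.fixture_fig1()


@pytest.fixture(scope="session")
def fig1_cone(fig1_net):
    return fg.build_cone(fig1_net)


@pytest.fixture(scope="session")
def fig1_canonical(fig1_cone):
    return fg.canonicalize(fig1_cone)


@pytest.fixture(scope="session")
def fig1_efms(fig1_cone):
    return fg.enumerate_efms(fig1_cone)


@pytest.fixture(scope="session")
def fig1_canonical_efms(fig1_canonical):
    return fg.enumerate_efms(fig1_canonical)


@pytest.fixture(scope="session")
def random_pool():
    """A reusable pool of small random networks with their cones."""
    out = []
    for seed in range(1, 13):
        m, n, n_irr = _shape_for_seed(seed)
        net = fg.random_network(m, n, n_irr, seed)
        out.append((seed, net, fg.build_cone(net)))
    return out
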