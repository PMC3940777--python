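"""Shared fixtures: catalogs are expensive to build, so they are session-scoped."""

import networkx as nx
import pytest

from orbitlp.catalog import build_catalog
from orbitlp.network import Network


@pytest.fixture(scope="session")
def cat3():
    return build_catalog(3)


@pytest.fixture(scope="session")
def cat4():
    return build_catalog(4)


@pytest.fixture(scope="session")
def cat5():
    return build_catalog(5)


@pytest.fixture
def triangle():
    return Network(edges=[("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def path4():
    return Network(edges=[("a", "b"), ("b", "c"), ("c", "d")])


@pytest.fixture
def small_er():
    """A 12-node Erdos-Renyi test graph, fixed seed."""
    return Network.from_networkx(nx.gnp_random_graph(12, 0.3, seed=42))
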