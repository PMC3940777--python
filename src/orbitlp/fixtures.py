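"""Seeded generators of synthetic test networks and annotations.

Every evaluation stage of this package can be exercised without any
download: random-graph models stand in for PPI networks and a tunable
annotation generator stands in for gene-GO mappings.  All generators are
deterministic given their seed.

The ``geometric`` model is the default stand-in for a PPI network: random
geometric graphs reproduce the high clustering of physical interaction
maps better than Erdos-Renyi or preferential-attachment graphs do.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .io import AnnotationTable
from .network import Network

MODELS = ("erdos_renyi", "barabasi_albert", "geometric", "ring_chords")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic network.

    ``density`` is model-specific: edge probability for ``erdos_renyi``,
    attachment count m for ``barabasi_albert``, connection radius for
    ``geometric``, and chords-per-node for ``ring_chords``.
    """

    model: str = "geometric"
    n: int = 60
    density: float = 0.18
    seed: int = 0

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; choose from {MODELS}")
        if self.n < 2:
            raise ValueError("n must be >= 2")


def _node_name(i: int, width: int) -> str:
    return "n%0*d" % (width, i)


def make_network(spec: FixtureSpec) -> Network:
    """Generate a simple undirected network from the named random-graph model."""
    width = len(str(spec.n - 1))
    if spec.model == "erdos_renyi":
        g = nx.gnp_random_graph(spec.n, spec.density, seed=spec.seed)
    elif spec.model == "barabasi_albert":
        m = max(1, int(round(spec.density)))
        g = nx.barabasi_albert_graph(spec.n, m, seed=spec.seed)
    elif spec.model == "geometric":
        g = nx.random_geometric_graph(spec.n, spec.density, seed=spec.seed)
    else:  # ring_chords
        g = nx.cycle_graph(spec.n)
        rng = np.random.default_rng(spec.seed)
        n_chords = int(round(spec.density * spec.n))
        for _ in range(n_chords):
            u, v = rng.integers(0, spec.n, size=2)
            if u != v:
                g.add_edge(int(u), int(v))
    return Network(
        (_node_name(i, width) for i in g.nodes),
        ((_node_name(u, width), _node_name(v, width)) for u, v in g.edges),
    )


@dataclass(frozen=True)
class AnnotationSpec:
    """Recipe for synthetic annotations.

    ``assortativity`` in [0, 1] controls how much more often adjacent nodes
    share a term than random node pairs do: 0 assigns terms independently
    of the topology, 1 forces every edge to share at least one term.  The
    knob exists so that enrichment tests have signal to detect.
    """

    n_terms: int = 20
    terms_per_gene: float = 2.0
    assortativity: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.assortativity <= 1.0:
            raise ValueError("assortativity must be in [0, 1]")
        if self.n_terms < 1:
            raise ValueError("n_terms must be >= 1")


def make_annotations(net: Network, spec: AnnotationSpec) -> AnnotationTable:
    """Assign each node 1+Poisson(terms_per_gene - 1) terms, optionally assortatively.

    After the independent assignment, each edge propagates one term across
    it with probability ``assortativity``, so adjacent nodes share terms
    more often than random pairs when the knob is positive.
    """
    rng = np.random.default_rng(spec.seed)
    table: dict[str, set[str]] = {}
    terms = ["T%03d" % t for t in range(spec.n_terms)]
    for node in net.sorted_nodes():
        k = 1 + rng.poisson(max(spec.terms_per_gene - 1.0, 0.0))
        picks = rng.choice(spec.n_terms, size=min(k, spec.n_terms), replace=False)
        table[node] = {terms[int(t)] for t in picks}
    if spec.assortativity > 0:
        for u, v in sorted(net.edges):
            if rng.random() < spec.assortativity:
                donor, receiver = (u, v) if rng.random() < 0.5 else (v, u)
                shared = sorted(table[donor])
                table[receiver].add(shared[int(rng.integers(len(shared)))])
    return {n: frozenset(t) for n, t in table.items()}


def paper_scale_spec(seed: int = 0) -> FixtureSpec:
    """A benchmark-sized fixture mirroring a yeast interactome's dimensions.

    About 1,000 nodes and 8,000 edges -- the size class of an AP/MS yeast
    network.  Intended for benchmarks, not routine tests.
    """
    return FixtureSpec(model="geometric", n=1004, density=0.072, seed=seed)
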