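"""Biological-correctness scoring of predicted edges.

Two checks, each with an upper-tail hypergeometric p-value:

* **GO-term sharing enrichment** -- among predicted edges whose endpoints
  are both annotated, the fraction whose endpoints share at least one term,
  against the null of drawing the same number of pairs uniformly from all
  annotated node pairs of the universe network.
* **external validation** -- among predicted edges absent from the original
  network, the fraction present in an independent reference network,
  against the null of drawing uniformly from the original network's
  non-edges over nodes shared with the reference.

Term sharing is a non-empty intersection of the annotation sets as given;
no ontology-graph propagation is performed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from scipy import stats

from .io import AnnotationTable
from .network import Network, norm_edge

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    eligible_edges: int
    hits: int
    p_value: float

    @property
    def fraction(self) -> float:
        """Hit fraction; NaN when no edge was eligible."""
        return self.hits / self.eligible_edges if self.eligible_edges else math.nan


def _hypergeom_upper(hits: int, population: int, successes: int, draws: int) -> float:
    """P[X >= hits] for X ~ Hypergeom(population, successes, draws)."""
    if draws == 0:
        return 1.0
    return float(stats.hypergeom.sf(hits - 1, population, successes, draws))


def go_enrichment(
    edges: set[tuple[str, str]], ann: AnnotationTable, universe: Network
) -> EnrichmentResult:
    """Enrichment of an edge set in shared GO terms.

    Eligible edges have both endpoints annotated; a hit shares >= 1 term.
    The hypergeometric population is every unordered node pair of the
    universe with both endpoints annotated.
    """
    annotated = sorted(n for n in universe.nodes if n in ann)
    eligible = []
    hits = 0
    for u, v in edges:
        if u in ann and v in ann:
            eligible.append((u, v))
            if ann[u] & ann[v]:
                hits += 1
    population = 0
    successes = 0
    for i in range(len(annotated)):
        terms_i = ann[annotated[i]]
        for j in range(i + 1, len(annotated)):
            population += 1
            if terms_i & ann[annotated[j]]:
                successes += 1
    if not eligible:
        log.warning("go_enrichment: no eligible edges (fraction undefined)")
        return EnrichmentResult(eligible_edges=0, hits=0, p_value=1.0)
    p = _hypergeom_upper(hits, population, successes, len(eligible))
    return EnrichmentResult(eligible_edges=len(eligible), hits=hits, p_value=p)


def external_validation(
    new_edges: set[tuple[str, str]], original: Network, reference: Network
) -> EnrichmentResult:
    """Validation of predicted-new edges against an independent reference.

    Predictions already present in the original network are filtered out
    (and logged).  The hypergeometric population is the original network's
    non-edges over nodes shared with the reference; successes are those
    present in the reference.
    """
    shared_nodes = original.nodes & reference.nodes
    if not shared_nodes:
        raise ValueError(
            "original and reference networks share no nodes "
            "(overlap 0 of %d / %d)" % (original.n_nodes, reference.n_nodes)
        )
    new_edges = {norm_edge(*e) for e in new_edges}
    filtered = new_edges - original.edges
    if len(filtered) < len(new_edges):
        log.info(
            "external_validation: filtered %d predictions already in the original network",
            len(new_edges) - len(filtered),
        )
    nodes = sorted(shared_nodes)
    population = 0
    successes = 0
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            pair = (nodes[i], nodes[j])
            if pair in original.edges:
                continue
            population += 1
            if pair in reference.edges:
                successes += 1
    hits = sum(1 for e in filtered if e in reference.edges)
    p = _hypergeom_upper(hits, population, successes, len(filtered))
    return EnrichmentResult(eligible_edges=len(filtered), hits=hits, p_value=p)
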