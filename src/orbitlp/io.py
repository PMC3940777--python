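"""Plain-text readers/writers: edge lists, annotation tables, prediction tables.

The interchange format for networks is a two-column, tab- or
whitespace-separated edge list; lines starting with ``#`` are comments.
Annotation tables are two- or three-column (gene, term[, evidence code]),
a flattened GAF-like gene-to-GO mapping.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

from .network import Network, norm_edge

log = logging.getLogger(__name__)

AnnotationTable = dict[str, frozenset[str]]


class ParseError(ValueError):
    """A malformed line in an input file; the message names the line number."""


def read_edge_list(path: str | Path) -> Network:
    """Read an undirected simple network from a two-column edge list.

    Self-loops are dropped and duplicate/reversed edges collapsed; the number
    of such lines is logged.
    """
    path = Path(path)
    edges: set[tuple[str, str]] = set()
    nodes: set[str] = set()
    dropped = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise ParseError(f"{path}:{lineno}: expected >=2 columns, got {len(tokens)}")
            u, v = tokens[0], tokens[1]
            nodes.update((u, v))
            if u == v:
                dropped += 1
                continue
            e = norm_edge(u, v)
            if e in edges:
                dropped += 1
            else:
                edges.add(e)
    if dropped:
        log.info("read_edge_list(%s): dropped %d self-loop/duplicate lines", path, dropped)
    return Network(nodes, edges)


def write_edge_list(net: Network, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# %d nodes\t%d edges\n" % (net.n_nodes, net.n_edges))
        for n in net.sorted_nodes():
            if not net.neighbors(n):
                fh.write("# node\t%s\n" % n)
        for u, v in sorted(net.edges):
            fh.write(f"{u}\t{v}\n")


def read_annotations(
    path: str | Path, evidence_filter: set[str] | None = None
) -> AnnotationTable:
    """Read a gene-to-term annotation table.

    Rows are (gene, term) or (gene, term, evidence code).  When
    ``evidence_filter`` is given, rows whose code is outside the filter are
    excluded; genes left with zero terms are absent from the result.
    """
    path = Path(path)
    table: dict[str, set[str]] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise ParseError(f"{path}:{lineno}: expected >=2 columns, got {len(tokens)}")
            gene, term = tokens[0], tokens[1]
            code = tokens[2] if len(tokens) >= 3 else None
            if evidence_filter is not None and code not in evidence_filter:
                continue
            table.setdefault(gene, set()).add(term)
    return {g: frozenset(t) for g, t in table.items() if t}


def write_annotations(table: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for gene in sorted(table):
            for term in sorted(table[gene]):
                fh.write(f"{gene}\t{term}\n")


def write_predictions(scores, path: str | Path) -> None:
    """Write a ranked prediction table: ``u<TAB>v<TAB>score`` lines.

    Rows are sorted by descending score with lexicographic tie-breaking, the
    same deterministic order used for top-k prediction.
    """
    from .evaluation import rank_pairs  # local import to avoid a cycle

    with Path(path).open("w") as fh:
        for (u, v) in rank_pairs(scores):
            fh.write(f"{u}\t{v}\t{scores.scores[(u, v)]:.10g}\n")


def read_scores(path: str | Path, tag: str = "external"):
    """Read a prediction table back as a :class:`PairScoreTable`.

    This is the plug-in route for comparing against externally computed
    measures (e.g. random-walk scores produced by other software).
    """
    from .baselines import PairScoreTable

    path = Path(path)
    scores: dict[tuple[str, str], float] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) < 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns, got {len(tokens)}")
            scores[norm_edge(tokens[0], tokens[1])] = float(tokens[2])
    return PairScoreTable(scores=scores, tag=tag)
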