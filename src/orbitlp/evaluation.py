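"""Synthetic-noise evaluation of link-prediction measures.

Noise is injected by removing a fraction of edges uniformly at random; a
measure then scores every node pair of the noisy network and the ranking is
scored against the original edges as ground truth.  At each prediction
budget k (0..100 % of all pairs) the top round(k% * #pairs) pairs are
called edges and a confusion table is tallied; AUROC and AUPR summarise the
whole ranking.  The per-k table follows the 1 %-increment grid, while the
areas are integrated over the full ranking resolution (one threshold per
rank) so that a perfect ranking scores exactly 1 and a fully inverted one
exactly 0.

De-noising replaces the network's edge set with the top |E| ranked pairs;
two de-noised networks are compared by edge-set intersection and Jaccard.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .baselines import PairScoreTable
from .network import Network


@dataclass(frozen=True)
class NoiseReplicate:
    """One noised copy of a network: the removed edges are the planted truth."""

    noisy: Network
    removed: frozenset[tuple[str, str]]
    fraction: float
    seed: int


def remove_edges(net: Network, fraction: float, seed: int) -> NoiseReplicate:
    """Remove round(fraction * |E|) edges uniformly at random, deterministically.

    Fractions above 0.5 exceed the noise range this harness is meant for and
    trigger a warning but are allowed.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if fraction > 0.5:
        import warnings

        warnings.warn(f"noise fraction {fraction} exceeds 0.5", stacklevel=2)
    edges = sorted(net.edges)
    n_remove = round(fraction * len(edges))
    rng = np.random.default_rng(seed)
    removed_idx = rng.choice(len(edges), size=n_remove, replace=False)
    removed = frozenset(edges[i] for i in removed_idx)
    noisy = Network(net.nodes, set(net.edges) - removed)
    return NoiseReplicate(noisy=noisy, removed=removed, fraction=fraction, seed=seed)


def rank_pairs(scores: PairScoreTable) -> list[tuple[str, str]]:
    """Pairs by descending score, ties broken by lexicographic pair order."""
    return sorted(scores.scores, key=lambda p: (-scores.scores[p], p))


@dataclass
class EvalCurve:
    """Confusion statistics on the k-grid plus ranking-resolution areas."""

    table: pd.DataFrame  # rows k = 0..100
    auroc: float
    aupr: float


def curve(
    ranking: list[tuple[str, str]],
    positives: set[tuple[str, str]],
    total_pairs: int | None = None,
) -> EvalCurve:
    """Evaluate a ranking against a positive edge set.

    ``positives`` must be a subset of the ranked pairs; ``total_pairs``
    defaults to the ranking length.
    """
    if not positives:
        raise ValueError("empty positive set: recall is undefined")
    if total_pairs is None:
        total_pairs = len(ranking)
    pos = set(positives)
    if not pos <= set(ranking):
        raise ValueError("positives must be a subset of the scored pairs")

    hit = np.fromiter((p in pos for p in ranking), dtype=bool, count=len(ranking))
    tp_at = np.concatenate(([0], np.cumsum(hit)))  # tp_at[m] = TP among top m
    n_pos = len(pos)
    n_neg = total_pairs - n_pos

    rows = []
    for k in range(101):
        m = round(k / 100.0 * total_pairs)
        tp = int(tp_at[m])
        fp = m - tp
        fn = n_pos - tp
        tn = n_neg - fp
        precision = tp / m if m > 0 else 1.0
        recall = tp / n_pos
        f_score = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
        specificity = tn / n_neg if n_neg > 0 else 1.0
        rows.append(
            dict(
                k=k,
                predicted=m,
                tp=tp,
                fp=fp,
                tn=tn,
                fn=fn,
                precision=precision,
                recall=recall,
                f_score=f_score,
                sensitivity=recall,
                specificity=specificity,
            )
        )
    table = pd.DataFrame(rows)

    m_all = np.arange(total_pairs + 1)
    tpr = tp_at / n_pos
    fpr = (m_all - tp_at) / n_neg if n_neg > 0 else np.zeros_like(tp_at, dtype=float)
    auroc = float(np.trapezoid(tpr, fpr))
    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(m_all > 0, tp_at / np.where(m_all > 0, m_all, 1), 1.0)
    aupr = float(np.trapezoid(prec, tpr))
    return EvalCurve(table=table, auroc=auroc, aupr=aupr)


def replicate_mean(curves: list[EvalCurve]) -> EvalCurve:
    """Pointwise mean of per-k tables; mean of per-replicate areas."""
    if not curves:
        raise ValueError("no curves to average")
    table = sum(c.table for c in curves) / len(curves)
    return EvalCurve(
        table=table,
        auroc=float(np.mean([c.auroc for c in curves])),
        aupr=float(np.mean([c.aupr for c in curves])),
    )


def paired_t(a: list[float], b: list[float]) -> float:
    """Two-sided paired t-test p-value on per-replicate AUROC differences.

    A degenerate all-equal difference vector yields p = 1 when the two lists
    are identical and p = 0 otherwise (flagging a constant offset).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length lists with n >= 2")
    diff = a - b
    if np.allclose(diff.std(), 0.0):
        return 1.0 if np.allclose(diff, 0.0) else 0.0
    return float(stats.ttest_rel(a, b).pvalue)


def denoise(net: Network, scores: PairScoreTable, m: int) -> Network:
    """Replace the edge set with the top-m ranked pairs over the same nodes."""
    if m < 0:
        raise ValueError("m must be non-negative")
    if m > len(scores):
        raise ValueError(f"m={m} exceeds the {len(scores)} scored pairs")
    top = rank_pairs(scores)[:m]
    return Network(net.nodes, top)


def intersect(a: Network, b: Network) -> tuple[int, float]:
    """Shared edge count and Jaccard similarity of two edge sets."""
    shared = len(a.edges & b.edges)
    union = len(a.edges | b.edges)
    return shared, (shared / union if union else 0.0)
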