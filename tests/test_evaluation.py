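"""Noise injection, ranking, confusion curves, replicate statistics, de-noising."""

import numpy as np
import pytest
from scipy import stats

from orbitlp.baselines import PairScoreTable, oracle_scores, random_scores
from orbitlp.evaluation import (
    curve,
    denoise,
    intersect,
    paired_t,
    rank_pairs,
    remove_edges,
    replicate_mean,
)
from orbitlp.network import Network


def test_remove_edges_count_and_determinism(small_er):
    rep = remove_edges(small_er, 0.5, seed=3)
    assert len(rep.removed) == round(0.5 * small_er.n_edges)
    assert rep.noisy.edges == small_er.edges - rep.removed
    assert rep.noisy.nodes == small_er.nodes
    rep2 = remove_edges(small_er, 0.5, seed=3)
    assert rep2.removed == rep.removed
    assert remove_edges(small_er, 0.5, seed=4).removed != rep.removed


def test_remove_edges_rounding_at_interactome_scale():
    # 2,518 edges at 5% noise: round(125.9) = 126 removed
    ring = Network(edges=[(f"n{i}", f"n{(i + 1) % 2518}") for i in range(2518)])
    assert len(remove_edges(ring, 0.05, seed=0).removed) == 126


def test_remove_edges_validation(small_er):
    with pytest.raises(ValueError):
        remove_edges(small_er, 0.0, seed=0)
    with pytest.raises(ValueError):
        remove_edges(small_er, 1.5, seed=0)
    with pytest.warns(UserWarning):
        remove_edges(small_er, 0.8, seed=0)


def test_rank_pairs_ties_and_permutation_invariance():
    t = PairScoreTable({("a", "b"): 1.0, ("a", "c"): 2.0, ("b", "c"): 1.0}, "t")
    assert rank_pairs(t) == [("a", "c"), ("a", "b"), ("b", "c")]
    shuffled = PairScoreTable(dict(reversed(list(t.scores.items()))), "t")
    assert rank_pairs(shuffled) == rank_pairs(t)


def test_curve_perfect_and_reversed(small_er):
    rep = remove_edges(small_er, 0.25, seed=1)
    positives = set(small_er.edges)
    perfect = curve(rank_pairs(oracle_scores(rep.noisy, small_er)), positives)
    assert perfect.auroc == 1.0
    assert perfect.aupr == pytest.approx(1.0)
    reversed_scores = PairScoreTable(
        {p: -s for p, s in oracle_scores(rep.noisy, small_er).scores.items()}, "rev"
    )
    assert curve(rank_pairs(reversed_scores), positives).auroc == 0.0


def test_curve_hand_enumerated_confusion():
    """4 nodes, 6 pairs, 2 positives, fixed ranking: at k=50% (3 predictions)
    the ranking [ab+, ac, ad+, bc, bd, cd] yields TP=2? no: top-3 holds ab,ac,ad
    -> TP=2 (ab, ad), FP=1, FN=0, TN=3."""
    ranking = [("a", "b"), ("a", "c"), ("a", "d"), ("b", "c"), ("b", "d"), ("c", "d")]
    positives = {("a", "b"), ("a", "d")}
    c = curve(ranking, positives)
    row = c.table[c.table.k == 50].iloc[0]
    assert (row.tp, row.fp, row.tn, row.fn) == (2, 1, 3, 0)
    assert row.precision == pytest.approx(2 / 3)
    assert row.recall == 1.0


def test_curve_conservation_and_boundary_rows(small_er):
    rep = remove_edges(small_er, 0.25, seed=2)
    c = curve(rank_pairs(random_scores(rep.noisy, seed=0)), set(small_er.edges))
    total = len(list(small_er.all_pairs()))
    for _, row in c.table.iterrows():
        assert row.tp + row.fp + row.tn + row.fn == total
    assert c.table.iloc[0].specificity == 1.0 and c.table.iloc[0].precision == 1.0
    assert c.table.iloc[100].sensitivity == 1.0


def test_curve_requires_positives(small_er):
    with pytest.raises(ValueError):
        curve(list(small_er.all_pairs()), set())


def test_random_ranking_auroc_near_half(small_er):
    """AUROC of a random ranking is 0.5 within 3 standard errors (50 replicates)."""
    positives = set(small_er.edges)
    aurocs = [
        curve(rank_pairs(random_scores(small_er, seed=s)), positives).auroc
        for s in range(50)
    ]
    se = np.std(aurocs, ddof=1) / np.sqrt(len(aurocs))
    assert abs(np.mean(aurocs) - 0.5) < 3 * se + 1e-9


def test_replicate_mean_averages_pointwise(small_er):
    reps = [remove_edges(small_er, 0.25, seed=s) for s in range(3)]
    curves = [
        curve(rank_pairs(random_scores(r.noisy, seed=s)), set(small_er.edges))
        for s, r in enumerate(reps)
    ]
    mean = replicate_mean(curves)
    assert mean.auroc == pytest.approx(np.mean([c.auroc for c in curves]))
    assert mean.table.tp.iloc[50] == pytest.approx(
        np.mean([c.table.tp.iloc[50] for c in curves])
    )


def test_paired_t_degenerate_and_textbook():
    assert paired_t([0.7] * 5, [0.7] * 5) == 1.0
    assert paired_t([0.8] * 5, [0.7] * 5) == 0.0
    a = [0.91, 0.93, 0.90, 0.94, 0.92]
    b = [0.88, 0.90, 0.89, 0.91, 0.90]
    diff = np.array(a) - np.array(b)
    t_stat = diff.mean() / (diff.std(ddof=1) / np.sqrt(5))
    expected = 2 * stats.t.sf(abs(t_stat), df=4)
    assert paired_t(a, b) == pytest.approx(expected)


def test_denoise_identity_and_validation(small_er):
    scores = oracle_scores(small_er, small_er)
    dn = denoise(small_er, scores, small_er.n_edges)
    assert dn == small_er
    with pytest.raises(ValueError):
        denoise(small_er, scores, -1)
    with pytest.raises(ValueError):
        denoise(small_er, scores, len(scores) + 1)


def test_intersect(small_er):
    assert intersect(small_er, small_er) == (small_er.n_edges, 1.0)
    other = Network(small_er.nodes, [("zzz1", "zzz2")])
    assert intersect(small_er, other) == (0, 0.0)
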