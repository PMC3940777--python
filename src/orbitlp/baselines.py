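"""Classical link-prediction baselines.

All measures score every unordered node pair of the network and are
symmetric in (u, v):

* ``dp``   degree product  d(u) * d(v)                 (preferential attachment)
* ``sn``   shared neighbours |N(u) & N(v)|
* ``jc``   Jaccard coefficient |N(u) & N(v)| / |N(u) | N(v)|
* ``aa``   Adamic-Adar  sum over shared z of 1 / ln d(z)
* ``rai``  resource allocation  sum over shared z of 1 / d(z)
* ``katz`` sum over walk lengths l of beta^l * (#length-l walks), via the
  resolvent (I - beta A)^-1 - I, or a truncated power series
* ``lpi``  local path index  (A^2)_uv + eps * (A^3)_uv

Scores are computed with dense adjacency-matrix algebra; for the network
sizes this package targets (PPI networks of a few thousand proteins) that
is both simple and fast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .network import Network


@dataclass
class PairScoreTable:
    """Scores for unordered node pairs, tagged with the producing measure."""

    scores: dict[tuple[str, str], float]
    tag: str = ""

    def __len__(self) -> int:
        return len(self.scores)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        u, v = pair
        return self.scores[(u, v) if u <= v else (v, u)]


class ConfigurationError(ValueError):
    pass


def _adjacency(net: Network) -> tuple[np.ndarray, list[str]]:
    names = net.sorted_nodes()
    index = {n: i for i, n in enumerate(names)}
    a = np.zeros((len(names), len(names)))
    for u, v in net.edges:
        a[index[u], index[v]] = 1.0
        a[index[v], index[u]] = 1.0
    return a, names


def _table_from_matrix(m: np.ndarray, names: list[str], tag: str) -> PairScoreTable:
    n = len(names)
    iu, iv = np.triu_indices(n, k=1)
    scores = {
        (names[i], names[j]): float(m[i, j]) for i, j in zip(iu.tolist(), iv.tolist())
    }
    return PairScoreTable(scores=scores, tag=tag)


def dp(net: Network) -> PairScoreTable:
    """Degree product: high-degree nodes are more likely to interact."""
    a, names = _adjacency(net)
    deg = a.sum(axis=1)
    return _table_from_matrix(np.outer(deg, deg), names, "dp")


def sn(net: Network) -> PairScoreTable:
    """Shared-neighbour count; equals (A^2)_uv off-diagonal."""
    a, names = _adjacency(net)
    return _table_from_matrix(a @ a, names, "sn")


def jc(net: Network) -> PairScoreTable:
    """Jaccard coefficient of the two neighbourhoods (0 when both are empty)."""
    a, names = _adjacency(net)
    shared = a @ a
    deg = a.sum(axis=1)
    union = deg[:, None] + deg[None, :] - shared  # |N(u) | N(v)|
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(union > 0, shared / np.where(union > 0, union, 1.0), 0.0)
    return _table_from_matrix(out, names, "jc")


def aa(net: Network) -> PairScoreTable:
    """Adamic-Adar: shared neighbours weighted by 1/ln(degree)."""
    a, names = _adjacency(net)
    deg = a.sum(axis=1)
    # a shared neighbour necessarily has degree >= 2, so ln(deg) > 0 wherever used
    inv = np.zeros_like(deg)
    mask = deg >= 2
    inv[mask] = 1.0 / np.log(deg[mask])
    return _table_from_matrix(a @ np.diag(inv) @ a, names, "aa")


def rai(net: Network) -> PairScoreTable:
    """Resource allocation: shared neighbours weighted by 1/degree."""
    a, names = _adjacency(net)
    deg = a.sum(axis=1)
    inv = np.where(deg > 0, 1.0 / np.where(deg > 0, deg, 1.0), 0.0)
    return _table_from_matrix(a @ np.diag(inv) @ a, names, "rai")


@dataclass(frozen=True)
class KatzConfig:
    beta: float = 0.005
    max_length: int | None = None


def katz(net: Network, cfg: KatzConfig = KatzConfig()) -> PairScoreTable:
    """Katz index: beta^l-discounted count of walks of every length l >= 1.

    The closed form uses the resolvent (I - beta A)^-1 - I and requires
    beta below the reciprocal spectral radius; ``max_length`` switches to a
    truncated power series instead.
    """
    a, names = _adjacency(net)
    n = len(names)
    if n == 0:
        return PairScoreTable(scores={}, tag="katz")
    if cfg.max_length is not None:
        out = np.zeros_like(a)
        power = np.eye(n)
        scale = 1.0
        for _ in range(cfg.max_length):
            power = power @ a
            scale *= cfg.beta
            out += scale * power
    else:
        radius = float(np.max(np.abs(np.linalg.eigvalsh(a)))) if net.n_edges else 0.0
        if radius > 0 and cfg.beta >= 1.0 / radius:
            raise ConfigurationError(
                "katz beta=%g does not converge: spectral radius %.4f requires beta < %.6f"
                % (cfg.beta, radius, 1.0 / radius)
            )
        out = np.linalg.inv(np.eye(n) - cfg.beta * a) - np.eye(n)
    return _table_from_matrix(out, names, "katz(beta=%g)" % cfg.beta)


def lpi(net: Network, epsilon: float = 0.005) -> PairScoreTable:
    """Local path index: length-2 paths plus eps-discounted length-3 walks."""
    a, names = _adjacency(net)
    a2 = a @ a
    return _table_from_matrix(a2 + epsilon * (a2 @ a), names, "lpi(eps=%g)" % epsilon)


def random_scores(net: Network, seed: int = 0) -> PairScoreTable:
    """Uniform random scores; the null baseline for the evaluation harness."""
    rng = np.random.default_rng(seed)
    pairs = list(net.all_pairs())
    return PairScoreTable(
        scores=dict(zip(pairs, rng.random(len(pairs)).tolist())), tag="random(seed=%d)" % seed
    )


def oracle_scores(net: Network, truth: Network) -> PairScoreTable:
    """Indicator of ground-truth edges: the perfect scorer, for sanity checks."""
    return PairScoreTable(
        scores={p: (1.0 if p in truth.edges else 0.0) for p in net.all_pairs()},
        tag="oracle",
    )


def _gdv_measure(net: Network, **params) -> PairScoreTable:
    from .measures import CombinedScoreConfig, combined_score_table

    return combined_score_table(net, CombinedScoreConfig(**params))


MEASURES: dict[str, Callable[..., PairScoreTable]] = {
    "dp": dp,
    "sn": sn,
    "jc": jc,
    "aa": aa,
    "rai": rai,
    "katz": lambda net, beta=0.005, max_length=None: katz(
        net, KatzConfig(beta=beta, max_length=max_length)
    ),
    "lpi": lpi,
    "gdv": _gdv_measure,
    "random": random_scores,
}


def get_measure(name: str) -> Callable[..., PairScoreTable]:
    try:
        return MEASURES[name]
    except KeyError:
        raise ConfigurationError(
            "unknown measure %r; available: %s" % (name, ", ".join(sorted(MEASURES)))
        ) from None
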