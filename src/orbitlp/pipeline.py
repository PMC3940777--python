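"""End-to-end evaluation pipelines.

Three tests mirror how link-prediction measures are compared on PPI data:

1. **Noise reconstruction** (`run_test1`): remove a fraction of edges,
   score the noisy network, and measure how well the ranking recovers the
   original edge set (AUROC/AUPR over replicates, paired t-tests between
   measures).
2. **External ground truth** (`run_test2`): score the intact network and
   evaluate against a user-supplied positive edge set (e.g. low-confidence
   interactions for a high-confidence network).
3. **De-noising** (`run_test3`): replace the edge set with the top-|E|
   ranked pairs, then judge the result biologically: GO-term sharing
   enrichment before vs after, pairwise intersections between de-noised
   networks, and optional validation of newly predicted edges against an
   independent reference network.

Every run is reproducible from its manifest: all randomness derives from
the master seed (replicate r of noise level f uses seed master + r).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from .baselines import PairScoreTable, get_measure
from .enrichment import external_validation, go_enrichment
from .evaluation import (
    EvalCurve,
    curve,
    denoise,
    intersect,
    paired_t,
    rank_pairs,
    remove_edges,
    replicate_mean,
)
from .io import AnnotationTable
from .network import Network

log = logging.getLogger(__name__)

DEFAULT_NOISE_FRACTIONS = (0.05, 0.10, 0.15, 0.20, 0.25, 0.50)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``measures`` maps a registry name to its keyword parameters, e.g.
    ``{"gdv": {"alpha": 0.8, "max_graphlet_nodes": 4}, "sn": {}}``.
    """

    measures: dict[str, dict[str, Any]] = field(default_factory=lambda: {"sn": {}})
    noise_fractions: tuple[float, ...] = DEFAULT_NOISE_FRACTIONS
    replicates: int = 5
    seed: int = 0
    out_dir: Path | None = None

    def manifest(self) -> dict[str, Any]:
        return {
            "version": __version__,
            "measures": self.measures,
            "noise_fractions": list(self.noise_fractions),
            "replicates": self.replicates,
            "seed": self.seed,
        }


def _score(name: str, params: dict[str, Any], net: Network) -> PairScoreTable:
    t0 = time.perf_counter()
    table = get_measure(name)(net, **params)
    log.info("scored %s with %s in %.2fs", net, table.tag or name, time.perf_counter() - t0)
    return table


@dataclass
class NoiseReport:
    """Per-measure, per-noise-level evaluation with replicate statistics."""

    summary: pd.DataFrame  # measure, fraction, mean/sd AUROC, mean/sd AUPR
    aurocs: dict[tuple[str, float], list[float]]  # per-replicate values
    curves: dict[tuple[str, float], EvalCurve]  # replicate-mean curves
    manifest: dict[str, Any]

    def pairwise_p(self, fraction: float) -> pd.DataFrame:
        """Paired t-test p-values between all measure pairs at one noise level."""
        names = sorted({m for (m, f) in self.aurocs if f == fraction})
        out = pd.DataFrame(index=names, columns=names, dtype=float)
        for a in names:
            for b in names:
                out.loc[a, b] = paired_t(self.aurocs[(a, fraction)], self.aurocs[(b, fraction)])
        return out


def run_test1(cfg: RunConfig, net: Network) -> NoiseReport:
    """Noise-reconstruction evaluation of every configured measure."""
    rows = []
    aurocs: dict[tuple[str, float], list[float]] = {}
    curves: dict[tuple[str, float], EvalCurve] = {}
    positives = set(net.edges)
    for fraction in cfg.noise_fractions:
        replicates = [
            remove_edges(net, fraction, cfg.seed + r) for r in range(cfg.replicates)
        ]
        for name, params in cfg.measures.items():
            per_rep = []
            for rep in replicates:
                scores = _score(name, params, rep.noisy)
                per_rep.append(curve(rank_pairs(scores), positives))
            aurocs[(name, fraction)] = [c.auroc for c in per_rep]
            curves[(name, fraction)] = replicate_mean(per_rep)
            rows.append(
                dict(
                    measure=name,
                    fraction=fraction,
                    auroc_mean=pd.Series([c.auroc for c in per_rep]).mean(),
                    auroc_sd=pd.Series([c.auroc for c in per_rep]).std(ddof=1),
                    aupr_mean=pd.Series([c.aupr for c in per_rep]).mean(),
                    aupr_sd=pd.Series([c.aupr for c in per_rep]).std(ddof=1),
                )
            )
    report = NoiseReport(
        summary=pd.DataFrame(rows), aurocs=aurocs, curves=curves, manifest=cfg.manifest()
    )
    _maybe_write(cfg, report.summary, "test1_summary.tsv", report.manifest)
    return report


def run_test2(cfg: RunConfig, net: Network, ground_truth: Network) -> NoiseReport:
    """Evaluation against an external positive edge set, without noise."""
    if not ground_truth.edges:
        raise ValueError("ground-truth network has no edges")
    positives = {e for e in ground_truth.edges if e[0] in net.nodes and e[1] in net.nodes}
    if not positives:
        raise ValueError("ground truth shares no scoreable pairs with the input network")
    rows = []
    aurocs: dict[tuple[str, float], list[float]] = {}
    curves: dict[tuple[str, float], EvalCurve] = {}
    for name, params in cfg.measures.items():
        scores = _score(name, params, net)
        c = curve(rank_pairs(scores), positives)
        aurocs[(name, 0.0)] = [c.auroc]
        curves[(name, 0.0)] = c
        rows.append(
            dict(
                measure=name,
                fraction=0.0,
                auroc_mean=c.auroc,
                auroc_sd=0.0,
                aupr_mean=c.aupr,
                aupr_sd=0.0,
            )
        )
    report = NoiseReport(
        summary=pd.DataFrame(rows), aurocs=aurocs, curves=curves, manifest=cfg.manifest()
    )
    _maybe_write(cfg, report.summary, "test2_summary.tsv", report.manifest)
    return report


@dataclass
class DenoiseReport:
    """Biological quality of de-noised networks, per measure."""

    summary: pd.DataFrame
    denoised: dict[str, Network]
    intersections: pd.DataFrame
    manifest: dict[str, Any]


def run_test3(
    cfg: RunConfig,
    net: Network,
    ann: AnnotationTable,
    reference: Network | None = None,
) -> DenoiseReport:
    """De-noise with every measure and score the results biologically."""
    if not ann:
        raise ValueError("annotation table is empty")
    original_enr = go_enrichment(set(net.edges), ann, net)
    rows = [
        dict(
            measure="original",
            eligible=original_enr.eligible_edges,
            hits=original_enr.hits,
            fraction=original_enr.fraction,
            p_value=original_enr.p_value,
            new_edges=0,
            validated=None,
            validation_p=None,
        )
    ]
    denoised: dict[str, Network] = {}
    for name, params in cfg.measures.items():
        scores = _score(name, params, net)
        dn = denoise(net, scores, net.n_edges)
        denoised[name] = dn
        enr = go_enrichment(set(dn.edges), ann, net)
        new_edges = dn.edges - net.edges
        validated = validation_p = None
        if reference is not None:
            val = external_validation(set(new_edges), net, reference)
            validated, validation_p = val.hits, val.p_value
        rows.append(
            dict(
                measure=name,
                eligible=enr.eligible_edges,
                hits=enr.hits,
                fraction=enr.fraction,
                p_value=enr.p_value,
                new_edges=len(new_edges),
                validated=validated,
                validation_p=validation_p,
            )
        )
    names = sorted(denoised)
    inter_rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            shared, jac = intersect(denoised[a], denoised[b])
            inter_rows.append(dict(measure_a=a, measure_b=b, shared_edges=shared, jaccard=jac))
    report = DenoiseReport(
        summary=pd.DataFrame(rows),
        denoised=denoised,
        intersections=pd.DataFrame(inter_rows),
        manifest=cfg.manifest(),
    )
    _maybe_write(cfg, report.summary, "test3_summary.tsv", report.manifest)
    return report


def _maybe_write(cfg: RunConfig, table: pd.DataFrame, name: str, manifest: dict) -> None:
    if cfg.out_dir is None:
        return
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / name, sep="\t", index=False)
    with (out / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
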