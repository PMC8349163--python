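"""Gene-level significance scores and ROC-based density selection.

Because the clustering is overlapping, a gene can sit in several clusters and
therefore carry several enrichment p-values; its SScore is the -log10 of the
smallest of them. Genes outside every cluster score 0. Treating bait genes as
positives, sweeping a threshold over the observed scores yields a ROC curve
whose area (AUC) measures how well clustering at a given density separates
bait from non-bait genes; the density with the highest AUC is selected for
candidate extraction. AUC is invariant under any strictly increasing
transform of the scores, so the choice of log base cannot change the
selection.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve as _sk_roc_curve

from .dpcluso import cluster_graph
from .enrich import EnrichedCluster, evaluate_clusters
from .netio import GeneNetwork, KnownGeneSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneScoreTable:
    """Per-gene SScore = -log10(min p over containing clusters); 0 if unclustered."""

    scores: dict[str, float]
    best_cluster: dict[str, int]  # gene -> cluster_id attaining the minimal p

    def __len__(self) -> int:
        return len(self.scores)


@dataclass(frozen=True)
class ROCResult:
    points: tuple[tuple[float, float], ...]  # (FPR, TPR) from (0,0) to (1,1)
    auc: float
    thresholds: tuple[float, ...]  # descending unique score values


@dataclass(frozen=True)
class DensityRecord:
    d_min: float
    n_clusters: int
    scores: GeneScoreTable
    roc: ROCResult
    enriched: list[EnrichedCluster]


@dataclass(frozen=True)
class DensityScan:
    records: tuple[DensityRecord, ...]
    selected_density: float

    @property
    def selected(self) -> DensityRecord:
        for rec in self.records:
            if rec.d_min == self.selected_density:
                return rec
        raise RuntimeError("selected density missing from scan records")

    def auc_by_density(self) -> dict[float, float]:
        return {rec.d_min: rec.roc.auc for rec in self.records}


def sscore_table(enriched: list[EnrichedCluster],
                 network: GeneNetwork) -> GeneScoreTable:
    """Assign every network gene its SScore and best (lowest-p) cluster."""
    best_p: dict[str, float] = {}
    best_id: dict[str, int] = {}
    for ec in enriched:
        for gene in ec.cluster.members:
            if gene not in best_p or ec.p_value < best_p[gene]:
                best_p[gene] = ec.p_value
                best_id[gene] = ec.cluster_id
    scores = {g: 0.0 for g in network.nodes}
    for gene, p in best_p.items():
        scores[gene] = -math.log10(p) if p > 0 else math.inf
    return GeneScoreTable(scores=scores, best_cluster=best_id)


def roc_curve(scores: GeneScoreTable, known: KnownGeneSet) -> ROCResult:
    """ROC over score thresholds with bait genes as positives.

    A gene counts as predicted-positive at threshold th when SScore >= th.
    Ties receive half credit, so the AUC equals the normalized Mann-Whitney
    statistic over bait/non-bait pairs.
    """
    genes = sorted(scores.scores)
    y_true = np.array([g in known for g in genes], dtype=int)
    y_score = np.array([scores.scores[g] for g in genes], dtype=float)
    n_pos = int(y_true.sum())
    n_neg = len(genes) - n_pos
    if n_pos == 0:
        raise ValueError("no positives: the known set does not intersect the scored genes")
    if n_neg == 0:
        raise ValueError("no negatives: every scored gene is in the known set")

    fpr, tpr, thr = _sk_roc_curve(y_true, y_score, drop_intermediate=False)
    points = [(float(f), float(t)) for f, t in zip(fpr, tpr)]
    if points[0] != (0.0, 0.0):
        points.insert(0, (0.0, 0.0))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    auc = float(roc_auc_score(y_true, y_score))
    thresholds = tuple(sorted({float(s) for s in y_score}, reverse=True))
    return ROCResult(points=tuple(points), auc=auc, thresholds=thresholds)


def scan_densities(network: GeneNetwork, known: KnownGeneSet,
                   densities: list[float] | tuple[float, ...] = (0.5, 0.6, 0.7, 0.8, 0.9),
                   cp_min: float = 0.5) -> DensityScan:
    """Cluster, enrich and score at each density; select the max-AUC density.

    Ties in AUC break toward the larger density (the stricter clustering).
    """
    if not densities:
        raise ValueError("densities must be non-empty")
    records = []
    for d_min in densities:
        clusterset = cluster_graph(network, d_min=d_min, cp_min=cp_min)
        enriched = evaluate_clusters(clusterset, known, network)
        scores = sscore_table(enriched, network)
        roc = roc_curve(scores, known)
        logger.info("d_min=%.2f: %d clusters, AUC=%.4f", d_min, len(clusterset), roc.auc)
        records.append(DensityRecord(d_min=d_min, n_clusters=len(clusterset),
                                     scores=scores, roc=roc, enriched=enriched))
    selected = max(records, key=lambda r: (r.roc.auc, r.d_min)).d_min
    return DensityScan(records=tuple(records), selected_density=selected)


def write_scores_tsv(scores: GeneScoreTable, known: KnownGeneSet,
                     path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tsscore\tbest_cluster_id\tis_known\n")
        for gene in sorted(scores.scores):
            best = scores.best_cluster.get(gene, "")
            fh.write(f"{gene}\t{scores.scores[gene]:.4f}\t{best}\t"
                     f"{int(gene in known)}\n")


def write_roc_tsv(scores: GeneScoreTable, known: KnownGeneSet, roc: ROCResult,
                  path: str | Path) -> None:
    """Confusion counts and rates at each observed score threshold."""
    vals = scores.scores
    pos = {g for g in vals if g in known}
    neg = set(vals) - pos
    with open(path, "w") as fh:
        fh.write("threshold\ttp\tfp\ttn\tfn\ttpr\tfpr\n")
        for th in roc.thresholds:
            tp = sum(1 for g in pos if vals[g] >= th)
            fp = sum(1 for g in neg if vals[g] >= th)
            fn = len(pos) - tp
            tn = len(neg) - fp
            fh.write(f"{th:.4f}\t{tp}\t{fp}\t{tn}\t{fn}\t"
                     f"{tp / len(pos):.4f}\t{fp / len(neg):.4f}\n")


def write_scan_json(scan: DensityScan, path: str | Path) -> None:
    payload = {
        "auc_by_density": {f"{d:.2f}": auc for d, auc in scan.auc_by_density().items()},
        "selected_density": scan.selected_density,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
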