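"""Candidate ("potential") gene extraction from significant clusters.

A candidate is a non-bait gene residing in at least one cluster whose
enrichment p-value falls strictly below the significance level. Candidates
are ranked by SScore (ties: lexicographic gene identifier) so the report is
deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from .enrich import EnrichedCluster
from .netio import KnownGeneSet
from .score_roc import GeneScoreTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CandidateGene:
    gene: str
    sscore: float
    best_cluster_id: int
    n_significant_clusters: int


@dataclass(frozen=True)
class CandidateReport:
    alpha: float
    significant_clusters: list[EnrichedCluster]
    candidates: list[CandidateGene]


def significant_clusters(enriched: list[EnrichedCluster],
                         alpha: float = 0.05) -> list[EnrichedCluster]:
    """Clusters with p strictly below alpha, input order preserved."""
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    return [ec for ec in enriched if ec.p_value < alpha]


def top_k_clusters(enriched: list[EnrichedCluster], k: int = 6) -> list[EnrichedCluster]:
    """The k most enriched clusters, ascending p (ties: smaller cluster id)."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > len(enriched):
        logger.warning("requested top %d clusters but only %d available", k, len(enriched))
    ranked = sorted(enriched, key=lambda ec: (ec.p_value, ec.cluster_id))
    return ranked[:k]


def potential_genes(clusters: list[EnrichedCluster], known: KnownGeneSet,
                    scores: GeneScoreTable) -> list[CandidateGene]:
    """Unique non-bait members of the given clusters, ranked by SScore.

    Each candidate is annotated with its best (lowest-p) cluster and how many
    of the given clusters contain it.
    """
    counts: dict[str, int] = {}
    for ec in clusters:
        for gene in ec.cluster.members:
            if gene not in known:
                counts[gene] = counts.get(gene, 0) + 1
    out = [
        CandidateGene(
            gene=g,
            sscore=scores.scores.get(g, 0.0),
            best_cluster_id=scores.best_cluster.get(g, 0),
            n_significant_clusters=n,
        )
        for g, n in counts.items()
    ]
    out.sort(key=lambda c: (-c.sscore, c.gene))
    return out


def candidate_report(enriched: list[EnrichedCluster], known: KnownGeneSet,
                     scores: GeneScoreTable, alpha: float = 0.05) -> CandidateReport:
    sig = significant_clusters(enriched, alpha=alpha)
    return CandidateReport(alpha=alpha, significant_clusters=sig,
                           candidates=potential_genes(sig, known, scores))


def write_candidates_tsv(candidates: list[CandidateGene], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tsscore\tbest_cluster_id\tn_significant_clusters\n")
        for c in candidates:
            fh.write(f"{c.gene}\t{c.sscore:.4f}\t{c.best_cluster_id}\t"
                     f"{c.n_significant_clusters}\n")


def write_top_clusters_tsv(clusters: list[EnrichedCluster], known: KnownGeneSet,
                           path: str | Path) -> None:
    """Report mirroring the candidate-per-cluster table: id, size, candidates, p."""
    with open(path, "w") as fh:
        fh.write("cluster_id\tsize\tcandidate_genes\tn_candidates\tp_value\n")
        for ec in clusters:
            cands = sorted(g for g in ec.cluster.members if g not in known)
            fh.write(f"{ec.cluster_id}\t{len(ec.cluster)}\t{','.join(cands)}\t"
                     f"{len(cands)}\t{ec.p_value:.6e}\n")
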