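"""End-to-end orchestration: merge -> density scan -> candidates -> ORA.

Every stage writes its tabular output into the run directory and a manifest
records the configuration, per-stage counts, the per-density AUCs and the
selected density, so a run is fully reproducible from its inputs and
manifest alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

from . import __version__
from .candidates import (CandidateReport, candidate_report, top_k_clusters,
                         write_candidates_tsv, write_top_clusters_tsv)
from .dpcluso import write_clusters_tsv, ClusterSet
from .enrich import write_enrichment_tsv
from .netio import (GeneNetwork, KnownGeneSet, load_known_genes, merge_networks,
                    network_summary, read_edge_list, write_network_tsv,
                    write_summary_json)
from .pathway_ora import (ora, pathway_graph, read_gmt, write_kappa_tsv,
                          write_ora_tsv)
from .score_roc import (DensityScan, scan_densities, write_roc_tsv,
                        write_scan_json, write_scores_tsv)

logger = logging.getLogger(__name__)

DEFAULT_DENSITIES = (0.5, 0.6, 0.7, 0.8, 0.9)


@dataclass
class PipelineConfig:
    edge_lists: list[tuple[str, str]]  # (path, dialect) pairs
    known_path: str
    out_dir: str
    densities: tuple[float, ...] = DEFAULT_DENSITIES
    cp_min: float = 0.5
    alpha: float = 0.05
    top_k: int = 6
    gmt_path: str | None = None
    kappa_min: float = 0.5

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "edge_lists" in raw:
            raw["edge_lists"] = [tuple(e) if isinstance(e, (list, tuple)) else (e, "tsv2col")
                                 for e in raw["edge_lists"]]
        if "densities" in raw:
            raw["densities"] = tuple(float(d) for d in raw["densities"])
        return cls(**raw)


@dataclass
class RunManifest:
    config: dict
    n_nodes: int
    n_edges: int
    n_known_in_network: int
    auc_by_density: dict[str, float]
    selected_density: float
    n_clusters_selected: int
    n_significant_clusters: int
    n_candidates: int
    n_significant_pathways: int | None
    version: str = __version__
    timestamp: str = field(default_factory=lambda: datetime.now(timezone.utc).isoformat())

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n")


def run(config: PipelineConfig) -> RunManifest:
    """Execute the full pipeline and write all outputs under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    logger.info("stage: merge")
    sources = [read_edge_list(p, dialect=d) for p, d in config.edge_lists]
    network = merge_networks(sources)
    known = load_known_genes(config.known_path)
    write_network_tsv(network, out / "merged_network.tsv")
    write_summary_json(network_summary(network, sources), out / "network_summary.json")

    logger.info("stage: density scan")
    scan = scan_densities(network, known, densities=config.densities,
                          cp_min=config.cp_min)
    for rec in scan.records:
        tag = f"d{rec.d_min:.2f}".replace(".", "")
        clusterset = ClusterSet(d_min=rec.d_min, cp_min=config.cp_min,
                                clusters=tuple(ec.cluster for ec in rec.enriched))
        write_clusters_tsv(clusterset, out / f"clusters_{tag}.tsv")
        write_enrichment_tsv(rec.enriched, out / f"enrichment_{tag}.tsv")
        write_scores_tsv(rec.scores, known, out / f"scores_{tag}.tsv")
        write_roc_tsv(rec.scores, known, rec.roc, out / f"roc_{tag}.tsv")
    write_scan_json(scan, out / "scan_summary.json")

    logger.info("stage: candidates (density %.2f)", scan.selected_density)
    sel = scan.selected
    report = candidate_report(sel.enriched, known, sel.scores, alpha=config.alpha)
    write_candidates_tsv(report.candidates, out / "candidates.tsv")
    top = top_k_clusters(report.significant_clusters, k=min(config.top_k,
                         max(1, len(report.significant_clusters))))
    write_top_clusters_tsv(top, known, out / "top_clusters.tsv")

    n_sig_pathways = None
    if config.gmt_path:
        logger.info("stage: pathway ORA")
        db = read_gmt(config.gmt_path)
        query = {c.gene for c in report.candidates} | (known.members & network.nodes)
        results = ora(query, db)
        write_ora_tsv(results, out / "pathway_ora.tsv")
        edges = pathway_graph(results, db, kappa_min=config.kappa_min,
                              alpha=config.alpha)
        write_kappa_tsv(edges, out / "pathway_kappa_edges.tsv")
        n_sig_pathways = sum(1 for r in results if r.p_bonferroni <= config.alpha)

    manifest = RunManifest(
        config={
            "edge_lists": [list(e) for e in config.edge_lists],
            "known_path": config.known_path,
            "densities": list(config.densities),
            "cp_min": config.cp_min,
            "alpha": config.alpha,
            "top_k": config.top_k,
            "gmt_path": config.gmt_path,
            "kappa_min": config.kappa_min,
            "out_dir": config.out_dir,
        },
        n_nodes=network.n_nodes,
        n_edges=network.n_edges,
        n_known_in_network=len(known.members & network.nodes),
        auc_by_density={f"{d:.2f}": auc for d, auc in scan.auc_by_density().items()},
        selected_density=scan.selected_density,
        n_clusters_selected=sel.n_clusters,
        n_significant_clusters=len(report.significant_clusters),
        n_candidates=len(report.candidates),
        n_significant_pathways=n_sig_pathways,
    )
    manifest.write(out / "manifest.json")
    return manifest
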