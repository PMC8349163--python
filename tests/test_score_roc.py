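from __future__ import annotations

import math
import random

import pytest

from clusterbait.candidates import candidate_report
from clusterbait.dpcluso import Cluster, cluster_graph
from clusterbait.enrich import (ContingencyTable, EnrichedCluster,
                                evaluate_clusters, fisher_greater)
from clusterbait.netio import GeneNetwork, KnownGeneSet
from clusterbait.score_roc import (GeneScoreTable, roc_curve, scan_densities,
                                   sscore_table)
from clusterbait.synthgen import SyntheticSpec, generate

from oracles import hypergeom_upper_tail, mann_whitney_auc


def enriched_from(members, cluster_id, p):
    n = len(members)
    cl = Cluster(frozenset(members), n - 1, (n - 1) / (n * (n - 1) // 2))
    a = 0
    return EnrichedCluster(cluster_id, cl,
                           ContingencyTable(a, n - a, 5, 20), p)


class TestSScoreTable:
    def net(self):
        return GeneNetwork([("g1", "g2"), ("g2", "g3"), ("g3", "g4")])

    def test_single_cluster_score_is_neg_log10(self):
        enriched = [enriched_from(["g1", "g2"], 1, 1e-3)]
        table = sscore_table(enriched, self.net())
        assert table.scores["g1"] == pytest.approx(3.0)
        assert table.best_cluster["g1"] == 1

    def test_overlapping_gene_takes_minimum_p(self):
        enriched = [enriched_from(["g1", "g2"], 1, 1e-3),
                    enriched_from(["g2", "g3"], 2, 1e-7)]
        table = sscore_table(enriched, self.net())
        assert table.scores["g2"] == pytest.approx(7.0)
        assert table.best_cluster["g2"] == 2

    def test_unclustered_genes_score_zero_but_are_present(self):
        enriched = [enriched_from(["g1", "g2"], 1, 1e-3)]
        table = sscore_table(enriched, self.net())
        assert table.scores["g4"] == 0.0
        assert set(table.scores) == self.net().nodes

    def test_score_of_bait_rich_worked_example_cluster(self):
        """-log10 of the exact Fisher tail for the (47,4,65,154) table."""
        p_exact = float(hypergeom_upper_tail(47, 4, 65, 154))
        enriched = [enriched_from(["g1", "g2"], 1,
                                  fisher_greater(ContingencyTable(47, 4, 65, 154)))]
        table = sscore_table(enriched, self.net())
        assert table.scores["g1"] == pytest.approx(-math.log10(p_exact), rel=1e-9)
        assert table.scores["g1"] == pytest.approx(16.24, abs=0.01)


class TestROC:
    def table(self, scores):
        return GeneScoreTable(scores=scores, best_cluster={})

    def test_perfect_separation_gives_auc_one(self):
        scores = {f"p{i}": 10.0 for i in range(5)} | {f"n{i}": 0.0 for i in range(5)}
        roc = roc_curve(self.table(scores), KnownGeneSet(frozenset(f"p{i}" for i in range(5))))
        assert roc.auc == 1.0

    def test_all_tied_scores_give_half(self):
        scores = {g: 2.5 for g in ["a", "b", "c", "d"]}
        roc = roc_curve(self.table(scores), KnownGeneSet(frozenset({"a", "b"})))
        assert roc.auc == pytest.approx(0.5)

    def test_one_concordant_one_discordant_pair(self):
        scores = {"g1": 3.0, "g2": 2.0, "g3": 1.0}
        roc = roc_curve(self.table(scores), KnownGeneSet(frozenset({"g1", "g3"})))
        assert roc.auc == pytest.approx(0.5)

    def test_missing_class_is_domain_error(self):
        scores = {"a": 1.0, "b": 2.0}
        with pytest.raises(ValueError, match="no positives"):
            roc_curve(self.table(scores), KnownGeneSet(frozenset({"zzz"})))
        with pytest.raises(ValueError, match="no negatives"):
            roc_curve(self.table(scores), KnownGeneSet(frozenset({"a", "b"})))

    def test_points_span_unit_square_and_are_monotone(self):
        rng = random.Random(5)
        scores = {f"g{i}": rng.choice([0.0, 1.0, 2.5, 7.0]) for i in range(30)}
        known = KnownGeneSet(frozenset(g for g in scores if rng.random() < 0.4))
        roc = roc_curve(self.table(scores), known)
        assert roc.points[0] == (0.0, 0.0) and roc.points[-1] == (1.0, 1.0)
        fprs = [p[0] for p in roc.points]
        tprs = [p[1] for p in roc.points]
        assert fprs == sorted(fprs) and tprs == sorted(tprs)
        assert 0.0 <= roc.auc <= 1.0
        assert roc.thresholds == tuple(sorted(set(scores.values()), reverse=True))

    def test_agrees_with_mann_whitney_enumeration(self):
        rng = random.Random(99)
        for _ in range(100):
            n = rng.randint(4, 50)
            scores = {f"g{i}": round(rng.uniform(0, 8), 1) for i in range(n)}
            pos = {g for g in scores if rng.random() < 0.5}
            if not pos or len(pos) == n:
                continue
            roc = roc_curve(self.table(scores), KnownGeneSet(frozenset(pos)))
            assert roc.auc == pytest.approx(mann_whitney_auc(scores, pos), abs=1e-12)

    def test_auc_invariant_under_log_base_change(self):
        """-log10(p) and -ln(p) scores give the identical AUC."""
        rng = random.Random(3)
        pvals = {f"g{i}": 10 ** -rng.uniform(0, 12) for i in range(40)}
        known = KnownGeneSet(frozenset(g for g in pvals if rng.random() < 0.4))
        log10_scores = {g: -math.log10(p) for g, p in pvals.items()}
        ln_scores = {g: -math.log(p) for g, p in pvals.items()}
        a1 = roc_curve(self.table(log10_scores), known).auc
        a2 = roc_curve(self.table(ln_scores), known).auc
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_reversed_labels_flip_auc(self):
        rng = random.Random(11)
        scores = {f"g{i}": rng.uniform(0, 5) for i in range(25)}  # tie-free a.s.
        pos = frozenset(g for g in list(scores)[:10])
        a = roc_curve(self.table(scores), KnownGeneSet(pos)).auc
        b = roc_curve(self.table(scores), KnownGeneSet(frozenset(scores) - pos)).auc
        assert a == pytest.approx(1 - b, abs=1e-12)


class TestScanDensities:
    def test_single_density_is_selected(self, triangle_pair, known_ab):
        scan = scan_densities(triangle_pair, known_ab, densities=(0.8,))
        assert scan.selected_density == 0.8
        assert len(scan.records) == 1

    def test_tied_auc_prefers_larger_density(self, triangle_pair, known_ab):
        # both densities produce the identical clustering of two triangles
        scan = scan_densities(triangle_pair, known_ab, densities=(0.8, 0.9))
        aucs = scan.auc_by_density()
        assert aucs[0.8] == aucs[0.9]
        assert scan.selected_density == 0.9

    def test_empty_density_list_rejected(self, triangle_pair, known_ab):
        with pytest.raises(ValueError):
            scan_densities(triangle_pair, known_ab, densities=())

    def test_selected_density_recovers_planted_truth_better_than_worst(self):
        """Jaccard between the candidate genes pulled from significant clusters
        and the planted ground-truth candidates is higher at the AUC-selected
        density than at the worst-AUC density (averaged over seeds). The best
        per-module cluster match is near-perfect at every density; what the
        AUC selection buys is a candidate set uncontaminated by the sloppy
        bait-poor clusters lower densities admit."""

        def truth_jaccard(ds, record):
            report = candidate_report(record.enriched, ds.known, record.scores)
            found = {c.gene for c in report.candidates}
            return len(found & ds.planted_candidates) / \
                max(1, len(found | ds.planted_candidates))

        gains = []
        for seed in range(5):
            ds = generate(SyntheticSpec(seed=seed))
            scan = scan_densities(ds.network, ds.known)
            worst = min(scan.records, key=lambda r: r.roc.auc)
            gains.append(truth_jaccard(ds, scan.selected) - truth_jaccard(ds, worst))
        assert sum(gains) > 0
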