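# Methods

## Model and assumptions

The package operationalizes guilt-by-association on a co-expression
network: if a pathway's genes are co-regulated, they form densely
interconnected regions of the network, and an unannotated gene embedded in
such a region is a plausible pathway member. Three assumptions follow:

- the input network is meaningful as an *unweighted* simple graph — edge
  confidence scores, if present, are discarded, because density and the
  cluster property are defined on edge counts;
- the bait (known) gene list is a reasonably complete, low-noise positive
  label set over the network's nodes;
- the network itself is the right statistical universe for enrichment:
  the Fisher test margins use the network's node count and the number of
  bait genes *present in the network*, not genome-wide totals. A bait gene
  with no edge cannot appear in any cluster and is excluded from the
  positive class (it can receive no score).

Gene identifiers are opaque case-sensitive strings; no alias resolution is
attempted (synonymous identifiers in curated lists are a curation problem
upstream of this pipeline).

## Clustering

The overlapping density-periphery clustering is specified exactly, so runs
are bit-reproducible:

1. All nodes with degree ≥ 1 start unassigned.
2. While unassigned nodes remain: seed a cluster at the unassigned node of
   highest full-network degree (ties: lexicographically smallest id).
3. Grow greedily: among all outside nodes adjacent to the cluster
   (assigned or not), the preferred candidate maximizes edges-into-cluster
   |E_nk| (ties: higher network degree, then lexicographically smallest).
   It joins iff the enlarged cluster's density ≥ d_min **and** its cluster
   property cp = |E_nk| / (d_k·|N_k|) against the *current* cluster ≥
   cp_min. Both the post-join density and cp are monotone increasing in
   |E_nk|, so if the preferred candidate fails, every candidate fails; the
   growth loop therefore tests only the preferred candidate and stops at
   the first rejection, which also establishes maximality of every emitted
   cluster.
4. A finished cluster (size ≥ 2) marks its members assigned. Previously
   assigned nodes remain eligible to join later clusters — that is the
   overlap mechanism.

Degenerate cases: the cluster property is undefined against a singleton
(its density has a zero denominator), so the first extension from a seed
accepts the best-connected neighbor unconditionally — the resulting 2-node
density is 1.0, which satisfies any d_min. A seed with degree ≥ 1 therefore
always yields a cluster of at least two nodes, and every non-isolated node
ends up in at least one cluster. Isolated nodes cannot arise from edge-list
input and are never clustered.

Parameters: `d_min` (density floor, scanned over 0.5–0.9 by default, the
conventional range for near-clique modules) and `cp_min` (candidate
attachment strength, default 0.5, the conventional recommended value).
Higher `d_min` yields more, smaller, purer clusters.

## Enrichment, SScore, ROC

Cluster enrichment is the hypergeometric upper tail P(X ≥ a) (one-sided
Fisher exact test), computed via `scipy.stats.hypergeom.sf`, which is
accurate at the ~1e-17 p-values bait-saturated clusters produce. The
one-sided direction is the only choice consistent with the published
worked-example p-values this package reproduces. No multiple-testing
correction is applied to cluster p-values by default, matching the raw
p < 0.05 significance convention of the source analyses; a
Benjamini–Hochberg option exists (`evaluate_clusters(..., correction="bh")`).

SScore uses log base 10 (the base is immaterial for density selection —
AUC is invariant under strictly increasing transforms, asserted by test —
but a fixed base makes score files reproducible). The minimum p over *all*
containing clusters is used, significant or not; significance filtering
happens only at candidate extraction. Unclustered genes score 0 and count
among the ROC negatives rather than being dropped.

The ROC sweeps thresholds over the observed score values (predicted
positive when SScore ≥ th), prepends (0,0) and appends (1,1), and takes the
trapezoidal area — equivalently the Mann–Whitney statistic with half
credit for ties (cross-checked against pairwise enumeration to 1e-12).
`sklearn.metrics` provides the curve and area. Density-selection ties
break toward the larger (stricter) density.

## Candidates

"Significant" means p strictly below alpha (default 0.05). Candidates are
the union of non-bait members of the significant clusters at the selected
density, annotated with SScore, best cluster and significant-cluster
membership count, and ranked by SScore descending (ties: lexicographic).
The ranking is this package's addition — a deterministic report order —
not part of the underlying statistic. The top-k cluster report (default
k = 6) mirrors the conventional per-cluster candidate table.

## Pathway ORA and kappa grouping

ORA uses the hypergeometric upper tail with the annotation universe as
population (by default the union of all pathway gene sets; overridable),
Bonferroni-corrected across the pathways tested. Plain Bonferroni on the
hypergeometric tail is implemented deliberately; FDR-style corrections are
available upstream but are not what this procedure describes. The pathway
graph links pathways with corrected p ≤ alpha (note: ≤, per the
conventional significance phrasing for this step) whenever the Cohen's
kappa of their binary membership vectors over the universe reaches
`kappa_min` (default 0.5). Kappa is defined as 0 when chance agreement is
1 (both marginals degenerate).

## Synthetic data generator

`synthgen.generate` draws a planted-partition (stochastic-block) network:
`n_modules` modules with sizes uniform in `module_size` (default 4 modules,
30–50 nodes), within-module edge probability `p_within` (0.9), background
pairs at `p_background` (0.02), module-background pairs at `p_attach`
(0.01), with `known_frac_module` (0.9) of each module's members and
`known_frac_background` (0.02) of background nodes labeled bait. The
near-clique modules (expected density 0.9) reproduce the structure of
bait-assembled co-expression networks, where the densest clusters are
almost entirely bait genes; with 200 background nodes the overall bait
fraction averages ≈ 0.41 of ≈ 360 nodes, matching the composition of the
motivating network (41% bait). A planted-partition construction was chosen
over degree-corrected models because the target modules are near-cliques,
which uniform within-module edge draws reproduce directly.

What it does *not* emulate: scale-free degree structure in the background,
correlated noise between modules, weighted or signed co-expression, and
bait labels that are themselves wrong. Passing recovery tests on this
generator shows the pipeline's machinery is sound under clean planted
structure, not that real networks satisfy these assumptions.

`holdout_known` hides `round(fraction·|bait|)` labels (seeded), enabling
the recovery experiment: cluster with the visible baits, then ask whether
the hidden baits outrank background genes by SScore (ROC AUC) and whether
the deliberately unlabeled module members surface as candidates.

## Numerical and design choices

- All randomness flows through a single integer seed per generated
  dataset; the draw order is fixed (module sizes, within-module edges,
  background edges, attachment edges, labels), so datasets are
  byte-reproducible.
- Tie-breaks everywhere are lexicographic on gene identifier, making
  cluster emission order, candidate ranking and all output files
  deterministic; reruns are bit-identical apart from the manifest
  timestamp.
- Output precision is fixed (p-values: 6 significant digits scientific;
  scores/densities/kappa: 4 decimals) so runs diff cleanly.
- The full density sweep re-clusters from scratch at each density; no
  incremental reuse, for simplicity and determinism.
- Problem sizes in the test suite and acceptance script (≈360-node
  networks, 10–20 seeds, 200 random oracle tables) were chosen as the
  smallest sizes at which the statistical assertions are stable.

## Known limitations

- The exact cluster count and numbering depend on the specified tie-break
  rules; other implementations of density-periphery clustering will emit
  differently numbered (and possibly differently composed) clusters, so
  cluster ids are not comparable across tools. Summary statistics reported
  for the original glucosinolate analysis (per-density cluster counts, its
  AUC of 0.87, 148 significant clusters, 127 candidates) depend on an
  unpublished merged network and on that tool's internals; they are not
  recomputable here and are represented instead by the synthetic recovery
  experiments and the cluster-count-vs-density trend test. Incidentally,
  the default synthetic conditions yield a bait ROC AUC of ≈ 0.89 at the
  selected density — the same regime as the original report — but this is
  a property of the generator, not a reproduction.
- Candidate quality degrades gracefully but noticeably as planting weakens
  (`p_within` toward `p_background`); the pipeline does not estimate its
  own confidence beyond the per-cluster p-values.
- The enrichment test treats genes as exchangeable; degree bias (hub genes
  joining many clusters) is not corrected for.
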