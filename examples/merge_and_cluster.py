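"""Merge two co-expression edge lists and extract overlapping dense clusters.

Builds two tiny per-resource edge lists sharing one edge, merges them into a
single network, and clusters at a high density threshold. The two triangles
come out as separate clusters; the hub gene appears in both of its pair
clusters, illustrating the overlap the algorithm allows.
"""

import tempfile
from pathlib import Path

from clusterbait import cluster_graph, merge_networks, read_edge_list

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    (tmp / "resource_a.tsv").write_text(
        "AT1\tAT2\nAT2\tAT3\nAT1\tAT3\nAT3\tHUB\n")
    (tmp / "resource_b.tsv").write_text(
        "AT4\tAT5\nAT5\tAT6\nAT4\tAT6\nAT3\tHUB\nAT6\tHUB\n")

    sources = [read_edge_list(tmp / "resource_a.tsv"),
               read_edge_list(tmp / "resource_b.tsv")]
    network = merge_networks(sources)
    print(f"merged network: {network.n_nodes} genes, {network.n_edges} edges "
          f"(the shared AT3-HUB edge counts once)")

    clusters = cluster_graph(network, d_min=0.8, cp_min=0.5)
    for i, cl in enumerate(clusters, 1):
        print(f"cluster {i}: {{{', '.join(sorted(cl.members))}}} "
              f"density={cl.density:.2f}")
    # Each cluster is a near-clique; HUB joins the pairs it is wired into,
    # so a gene can legitimately belong to more than one cluster.
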