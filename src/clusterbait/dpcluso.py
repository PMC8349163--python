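"""Overlapping density-constrained graph clustering (DPClusO lineage).

The algorithm grows one cluster at a time from a high-degree seed, greedily
absorbing the neighbor with the most edges into the current cluster, subject
to two acceptance conditions: the enlarged cluster's density must stay at or
above ``d_min``, and the candidate's cluster property

    cp(n, k) = |E_nk| / (d_k * |N_k|)

— its edge count into cluster k relative to the cluster's density and size —
must reach ``cp_min``. Members of finished clusters remain eligible as
candidates for clusters grown from later seeds, which is what produces
overlap. All choices are deterministic: ties in degree or connectivity break
lexicographically on the gene identifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from .netio import GeneNetwork

logger = logging.getLogger(__name__)


def _pairs(n: int) -> int:
    return n * (n - 1) // 2


@dataclass(frozen=True)
class Cluster:
    """A node subset with its internal edge count and density."""

    members: frozenset[str]
    internal_edge_count: int
    density: float

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a cluster needs at least two members")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, node: str) -> bool:
        return node in self.members


@dataclass(frozen=True)
class ClusterSet:
    """All clusters emitted at one (d_min, cp_min) setting, in emission order."""

    d_min: float
    cp_min: float
    clusters: tuple[Cluster, ...]

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)


def density(members: set[str] | frozenset[str], network: GeneNetwork) -> float:
    """Fraction of present edges among all possible edges within ``members``."""
    if len(members) < 2:
        raise ValueError("density is undefined for fewer than two nodes")
    missing = set(members) - network.nodes
    if missing:
        raise ValueError(f"members not in network: {sorted(missing)[:5]}")
    return network.edges_within(members) / _pairs(len(members))


def cluster_property(node: str, cluster: Cluster, network: GeneNetwork) -> float:
    """Cluster property cp = |E_nk| / (d_k * |N_k|) of an outside node."""
    if node in cluster.members:
        raise ValueError(f"{node!r} is already a cluster member")
    if cluster.density <= 0:
        raise ValueError("cluster property is undefined against an edgeless cluster")
    e_nk = network.edges_between(node, set(cluster.members))
    return e_nk / (cluster.density * len(cluster.members))


def cluster_graph(network: GeneNetwork, d_min: float, cp_min: float = 0.5) -> ClusterSet:
    """Extract overlapping dense clusters from the network.

    Parameters
    ----------
    network
        The merged co-expression network; must contain at least one edge.
    d_min
        Minimum cluster density in (0, 1]. Every emitted cluster satisfies it.
    cp_min
        Minimum cluster property a candidate must reach to join (>= 0);
        0.5 is the conventional default.

    Procedure: while any node with degree >= 1 is unassigned, seed a cluster
    at the unassigned node of highest full-network degree (ties break
    lexicographically) and grow it. At each step the candidate maximizing
    edges-into-cluster |E_nk| (ties: higher degree, then lexicographically
    smaller) joins iff the enlarged density stays >= d_min and its cp against
    the current cluster is >= cp_min. Both conditions are monotone in |E_nk|,
    so rejecting the preferred candidate rejects all. The first extension from
    a singleton seed takes the best-connected neighbor unconditionally (the
    2-node density is 1.0 and cp is undefined for a singleton). A finished
    cluster marks its members assigned; already-assigned nodes may still join
    later clusters, producing overlap.
    """
    if not 0 < d_min <= 1:
        raise ValueError(f"d_min must be in (0, 1], got {d_min}")
    if cp_min < 0:
        raise ValueError(f"cp_min must be >= 0, got {cp_min}")
    if network.n_edges == 0:
        raise ValueError("cannot cluster a network with no edges")

    degree = {n: network.degree(n) for n in network.nodes}
    unassigned = {n for n, d in degree.items() if d >= 1}
    clusters: list[Cluster] = []

    while unassigned:
        seed = min(unassigned, key=lambda n: (-degree[n], n))
        members: set[str] = {seed}
        internal = 0
        # edges from each outside neighbor into the current cluster
        conn: dict[str, int] = {nb: 1 for nb in network.neighbors(seed)}

        while conn:
            cand = min(conn, key=lambda n: (-conn[n], -degree[n], n))
            e_nk = conn[cand]
            n_k = len(members)
            if n_k == 1:
                accept = True  # resulting 2-node density is 1.0
            else:
                d_k = internal / _pairs(n_k)
                new_density = (internal + e_nk) / _pairs(n_k + 1)
                cp = e_nk / (d_k * n_k)
                accept = new_density >= d_min and cp >= cp_min
            if not accept:
                break
            members.add(cand)
            internal += e_nk
            del conn[cand]
            for nb in network.neighbors(cand):
                if nb not in members:
                    conn[nb] = conn.get(nb, 0) + 1

        if len(members) >= 2:
            clusters.append(Cluster(
                members=frozenset(members),
                internal_edge_count=internal,
                density=internal / _pairs(len(members)),
            ))
            unassigned -= members
        else:  # degree >= 1 guarantees a first extension; defensive only
            unassigned.discard(seed)

    logger.info("d_min=%.2f cp_min=%.2f: %d clusters", d_min, cp_min, len(clusters))
    return ClusterSet(d_min=d_min, cp_min=cp_min, clusters=tuple(clusters))


def write_clusters_tsv(clusterset: ClusterSet, path: str | Path) -> None:
    """Write clusters as TSV: 1-based id, size, internal edges, density, members."""
    with open(path, "w") as fh:
        fh.write("cluster_id\tsize\tinternal_edges\tdensity\tmembers\n")
        for i, cl in enumerate(clusterset.clusters, start=1):
            fh.write(f"{i}\t{len(cl)}\t{cl.internal_edge_count}\t"
                     f"{cl.density:.4f}\t{','.join(sorted(cl.members))}\n")
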