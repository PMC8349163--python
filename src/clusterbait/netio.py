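"""Reading, merging and writing gene co-expression edge lists.

Gene identifiers are opaque, case-sensitive strings (AGI locus codes in the
motivating application). Networks are simple undirected graphs: no self-loops,
no duplicate edges, no edge weights — the downstream clustering is defined on
edge counts only, so any confidence column in the input is discarded.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

Edge = tuple[str, str]


class ParseError(ValueError):
    """A malformed row in an input file."""


class EmptyInputError(ValueError):
    """An input that yields no usable records after filtering."""


def canonical_edge(u: str, v: str) -> Edge:
    """Return the unordered pair in canonical (lexicographic) orientation."""
    return (u, v) if u <= v else (v, u)


@dataclass(frozen=True)
class SourceEdgeList:
    """Edges from a single co-expression resource, before merging.

    Edges are deduplicated, self-pair-free and stored with the
    lexicographically smaller identifier first.
    """

    source_name: str
    edges: frozenset[Edge]

    def __post_init__(self) -> None:
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-pair ({u},{v}) in source {self.source_name!r}")
            if u > v:
                raise ValueError(f"non-canonical edge ({u},{v}) in source {self.source_name!r}")


class GeneNetwork:
    """Simple undirected network of gene identifiers.

    Thin wrapper over :class:`networkx.Graph` enforcing canonical,
    self-loop-free edges, with the subgraph edge-count queries the
    clustering and enrichment stages need. Nodes exist only via edges.
    """

    def __init__(self, edges: Iterable[Edge],
                 provenance: Mapping[Edge, frozenset[str]] | None = None) -> None:
        g = nx.Graph()
        for u, v in edges:
            if u == v:
                raise ValueError(f"self-loop on {u!r}")
            g.add_edge(*canonical_edge(u, v))
        self._g = g
        self.provenance: dict[Edge, frozenset[str]] = dict(provenance or {})

    @property
    def nodes(self) -> set[str]:
        return set(self._g.nodes)

    @property
    def edges(self) -> set[Edge]:
        return {canonical_edge(u, v) for u, v in self._g.edges}

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def __contains__(self, node: str) -> bool:
        return node in self._g

    def has_edge(self, u: str, v: str) -> bool:
        return self._g.has_edge(u, v)

    def neighbors(self, node: str) -> set[str]:
        return set(self._g.neighbors(node))

    def degree(self, node: str) -> int:
        return self._g.degree(node)

    def edges_within(self, members: Iterable[str]) -> int:
        """Number of network edges with both endpoints in ``members``."""
        return self._g.subgraph(members).number_of_edges()

    def edges_between(self, node: str, members: set[str]) -> int:
        """Number of network edges joining ``node`` to ``members``."""
        return sum(1 for nb in self._g.neighbors(node) if nb in members)

    def to_networkx(self) -> nx.Graph:
        return self._g.copy()


@dataclass(frozen=True)
class KnownGeneSet:
    """The bait genes: experimentally verified members of the pathway."""

    members: frozenset[str]

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members

    def in_network(self, network: GeneNetwork) -> frozenset[str]:
        """Bait genes that actually appear in the network."""
        present = self.members & network.nodes
        absent = len(self.members) - len(present)
        if absent:
            logger.info("%d known genes absent from the network", absent)
        return frozenset(present)


def _parse_tsv2col(lines: Iterable[tuple[int, str]]) -> Iterable[tuple[int, list[str]]]:
    for lineno, line in lines:
        fields = line.rstrip("\n").split("\t")
        fields = [f.strip() for f in fields]
        if len(fields) < 2 or not fields[0] or not fields[1]:
            raise ParseError(f"line {lineno}: expected two tab-separated identifiers, got {line!r}")
        yield lineno, fields[:2]


def read_edge_list(path: str | Path, dialect: str = "tsv2col",
                   source_name: str | None = None) -> SourceEdgeList:
    """Read one co-expression resource's export into a :class:`SourceEdgeList`.

    Parameters
    ----------
    path
        A two-column tab-separated file (``tsv2col``) or a SIF file (``sif``:
        whitespace-delimited ``source interaction target [target ...]`` rows,
        expanded pairwise; the interaction type is ignored).
    dialect
        ``"tsv2col"`` or ``"sif"``.
    source_name
        Label kept for provenance; defaults to the file stem.

    A third (weight/confidence) column in TSV input is accepted and discarded.
    A header row ``source<TAB>target`` is auto-detected and skipped.
    Self-pairs are dropped (with a logged count); duplicate pairs collapse.
    """
    path = Path(path)
    if dialect not in ("tsv2col", "sif"):
        raise ValueError(f"unknown dialect {dialect!r}")
    name = source_name or path.stem
    try:
        raw = path.read_text()
    except OSError as exc:
        raise OSError(f"cannot read edge list {path}: {exc}") from exc

    pairs: set[Edge] = set()
    self_pairs = 0
    lines = [(i, ln) for i, ln in enumerate(raw.splitlines(), start=1)
             if ln.strip() and not ln.lstrip().startswith("#")]
    if dialect == "tsv2col":
        if lines:
            first = [f.strip().lower() for f in lines[0][1].split("\t")[:2]]
            if first == ["source", "target"]:
                lines = lines[1:]
        for lineno, (u, v) in _parse_tsv2col(lines):
            if u == v:
                self_pairs += 1
                continue
            pairs.add(canonical_edge(u, v))
    else:
        for lineno, line in lines:
            fields = line.split()
            if len(fields) == 1:
                raise ParseError(f"line {lineno}: SIF row with a single field: {line!r}")
            if len(fields) == 2:
                raise ParseError(
                    f"line {lineno}: SIF row needs source, interaction and >=1 target: {line!r}")
            src, _interaction, *targets = fields
            for tgt in targets:
                if src == tgt:
                    self_pairs += 1
                    continue
                pairs.add(canonical_edge(src, tgt))

    if self_pairs:
        logger.info("%s: dropped %d self-pair(s)", name, self_pairs)
    if not pairs:
        raise EmptyInputError(f"{path}: no edges after filtering")
    return SourceEdgeList(source_name=name, edges=frozenset(pairs))


def merge_networks(sources: list[SourceEdgeList]) -> GeneNetwork:
    """Union one or more per-resource edge lists into one integrated network.

    The merged node set is the union of all endpoints and the edge set is the
    union of canonical edges; an edge found by several resources appears once.
    Per-edge provenance (which sources contributed it) is retained on the
    returned network for reporting.
    """
    if not sources:
        raise ValueError("merge_networks requires at least one source")
    provenance: dict[Edge, set[str]] = {}
    for src in sources:
        for edge in src.edges:
            provenance.setdefault(edge, set()).add(src.source_name)
    frozen = {e: frozenset(names) for e, names in provenance.items()}
    return GeneNetwork(frozen.keys(), provenance=frozen)


def load_known_genes(path: str | Path) -> KnownGeneSet:
    """Load the bait gene list: one identifier per line.

    Blank lines and ``#`` comments are ignored; duplicates collapse;
    identifiers are whitespace-trimmed and case-preserved.
    """
    path = Path(path)
    members = set()
    for line in path.read_text().splitlines():
        token = line.strip()
        if not token or token.startswith("#"):
            continue
        members.add(token)
    if not members:
        raise EmptyInputError(f"{path}: no gene identifiers found")
    return KnownGeneSet(members=frozenset(members))


def write_network_tsv(network: GeneNetwork, path: str | Path) -> None:
    """Write the network as a canonical two-column TSV with a header."""
    with open(path, "w") as fh:
        fh.write("source\ttarget\n")
        for u, v in sorted(network.edges):
            fh.write(f"{u}\t{v}\n")


def network_summary(network: GeneNetwork,
                    sources: list[SourceEdgeList] | None = None) -> dict:
    """JSON-serializable summary: node/edge totals and per-source counts."""
    summary = {"nodes": network.n_nodes, "edges": network.n_edges}
    if sources is not None:
        summary["per_source"] = {
            s.source_name: {
                "edges": len(s.edges),
                "nodes": len({n for e in s.edges for n in e}),
            }
            for s in sources
        }
    return summary


def write_summary_json(summary: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
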