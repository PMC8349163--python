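"""Pathway over-representation analysis and kappa-based pathway grouping.

A gene list is tested against each pathway with the hypergeometric upper
tail (population = the annotation universe, successes = the pathway,
draws = the query restricted to the universe), Bonferroni-corrected across
the pathways tested. Significant pathways are then linked whenever the
Cohen's kappa agreement of their binary gene-membership vectors reaches a
threshold, giving a pathway-pathway graph whose connected groups share
genes beyond chance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from itertools import combinations

from scipy.stats import hypergeom

from .netio import ParseError


@dataclass(frozen=True)
class PathwayDB:
    """Pathway id -> gene set, with the annotation universe."""

    pathways: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        for name, genes in self.pathways.items():
            if not genes:
                raise ValueError(f"pathway {name!r} has no genes")
            if not genes <= self.universe:
                raise ValueError(f"pathway {name!r} has genes outside the universe")

    def __len__(self) -> int:
        return len(self.pathways)


@dataclass(frozen=True)
class ORAResult:
    pathway: str
    overlap: int
    p_hyper: float
    p_bonferroni: float


@dataclass(frozen=True)
class KappaEdge:
    pathway_a: str
    pathway_b: str
    kappa: float


def read_gmt(path: str | Path, universe: set[str] | None = None) -> PathwayDB:
    """Read a GMT file: name, description, then one gene per column.

    The universe defaults to the union of all pathway gene sets; pass an
    explicit universe to test against a wider annotation space.
    """
    path = Path(path)
    pathways: dict[str, frozenset[str]] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: GMT row needs name, description and >=1 gene")
        name, _desc, *genes = fields
        genes = [g.strip() for g in genes]
        if any(not g for g in genes):
            raise ParseError(f"{path}:{lineno}: empty gene field")
        pathways[name] = frozenset(genes)
    if not pathways:
        raise ParseError(f"{path}: no pathways found")
    full = frozenset(universe) if universe is not None else frozenset().union(*pathways.values())
    return PathwayDB(pathways=pathways, universe=full)


def ora(query: set[str] | frozenset[str], db: PathwayDB,
        alpha_sort: bool = True) -> list[ORAResult]:
    """Hypergeometric over-representation of the query in each pathway.

    Query genes outside the universe are ignored. Bonferroni multiplies by
    the number of pathways tested, capped at 1. Results sort by raw p
    ascending (ties: pathway id) unless ``alpha_sort`` is False.
    """
    eff = frozenset(query) & db.universe
    if not eff:
        raise ValueError("query does not intersect the annotation universe")
    m = len(db.universe)
    n_draw = len(eff)
    n_tests = len(db.pathways)
    results = []
    for name, genes in db.pathways.items():
        k = len(eff & genes)
        p = float(hypergeom.sf(k - 1, m, len(genes), n_draw))
        p = min(p, 1.0)
        results.append(ORAResult(pathway=name, overlap=k, p_hyper=p,
                                 p_bonferroni=min(1.0, p * n_tests)))
    if alpha_sort:
        results.sort(key=lambda r: (r.p_hyper, r.pathway))
    return results


def kappa(p1: set[str] | frozenset[str], p2: set[str] | frozenset[str],
          universe: set[str] | frozenset[str]) -> float:
    """Cohen's kappa of two pathways' binary membership vectors over the universe.

    kappa = (po - pe) / (1 - pe) where po is the observed agreement fraction
    and pe the chance agreement from the marginals; defined as 0 when pe = 1
    (both marginals degenerate).
    """
    if not universe:
        raise ValueError("kappa needs a non-empty universe")
    u = frozenset(universe)
    if not (frozenset(p1) <= u and frozenset(p2) <= u):
        raise ValueError("pathway gene sets must be subsets of the universe")
    s1, s2 = frozenset(p1), frozenset(p2)
    n = len(u)
    both = len(s1 & s2)
    only1 = len(s1) - both
    only2 = len(s2) - both
    neither = n - both - only1 - only2
    po = (both + neither) / n
    pe = (len(s1) * len(s2) + (n - len(s1)) * (n - len(s2))) / (n * n)
    if pe == 1.0:
        return 0.0
    return (po - pe) / (1 - pe)


def pathway_graph(results: list[ORAResult], db: PathwayDB,
                  kappa_min: float = 0.5, alpha: float = 0.05) -> list[KappaEdge]:
    """Link significant pathways (p_bonferroni <= alpha) with kappa >= kappa_min.

    Edges are emitted with the lexicographically smaller pathway first and
    sorted for reproducible output.
    """
    if not 0 <= kappa_min <= 1:
        raise ValueError(f"kappa_min must be in [0, 1], got {kappa_min}")
    sig = sorted(r.pathway for r in results if r.p_bonferroni <= alpha)
    edges = []
    for a, b in combinations(sig, 2):
        k = kappa(db.pathways[a], db.pathways[b], db.universe)
        if k >= kappa_min:
            edges.append(KappaEdge(pathway_a=a, pathway_b=b, kappa=k))
    return edges


def write_ora_tsv(results: list[ORAResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("pathway\toverlap\tp_hyper\tp_bonferroni\n")
        for r in results:
            fh.write(f"{r.pathway}\t{r.overlap}\t{r.p_hyper:.6e}\t{r.p_bonferroni:.6e}\n")


def write_kappa_tsv(edges: list[KappaEdge], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("pathway_a\tpathway_b\tkappa\n")
        for e in edges:
            fh.write(f"{e.pathway_a}\t{e.pathway_b}\t{e.kappa:.4f}\n")
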