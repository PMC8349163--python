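from __future__ import annotations

import itertools

import pytest

from clusterbait.netio import GeneNetwork, KnownGeneSet


def make_network(edges) -> GeneNetwork:
    return GeneNetwork(edges)


@pytest.fixture
def triangle_pair() -> GeneNetwork:
    """Two disjoint triangles."""
    return make_network([("a1", "a2"), ("a2", "a3"), ("a1", "a3"),
                         ("b1", "b2"), ("b2", "b3"), ("b1", "b3")])


@pytest.fixture
def star4() -> GeneNetwork:
    """Star with center c and leaves l1..l3."""
    return make_network([("c", "l1"), ("c", "l2"), ("c", "l3")])


@pytest.fixture
def k5() -> GeneNetwork:
    """Complete graph on five nodes."""
    nodes = [f"n{i}" for i in range(5)]
    return make_network(list(itertools.combinations(nodes, 2)))


@pytest.fixture
def path3() -> GeneNetwork:
    return make_network([("A", "B"), ("B", "C")])


@pytest.fixture
def known_ab() -> KnownGeneSet:
    return KnownGeneSet(frozenset({"a1", "a2", "a3"}))
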