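"""Synthetic networks with planted bait-enriched dense modules.

The generator emulates the structure of a bait-assembled co-expression
network: a handful of near-clique modules whose members are mostly labeled
known (bait) genes, embedded in a sparse background. It is a planted-
partition (stochastic-block) construction: within-module pairs draw edges at
``p_within`` (~0.9 by default, matching the near-clique densities such
networks show), background pairs at ``p_background``, and module-background
pairs at ``p_attach``. Labels are drawn without replacement to hit the
stated fractions, giving ~90% known genes inside modules and an overall
known fraction around 0.41.

The unlabeled module members — ``planted_candidates`` — are the ground
truth a candidate-prioritization pipeline should recover, enabling
label-holdout and recovery experiments without any external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .netio import GeneNetwork, KnownGeneSet, canonical_edge


@dataclass(frozen=True)
class SyntheticSpec:
    """Generation parameters; defaults emulate a bait-rich ~360-node network."""

    n_background: int = 200
    n_modules: int = 4
    module_size: int | tuple[int, int] = (30, 50)
    p_within: float = 0.9
    p_background: float = 0.02
    p_attach: float = 0.01
    known_frac_module: float = 0.9
    known_frac_background: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_within", "p_background", "p_attach",
                     "known_frac_module", "known_frac_background"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_background < 0 or self.n_modules < 0:
            raise ValueError("sizes must be >= 0")
        sizes = self.module_size if isinstance(self.module_size, tuple) else (self.module_size,)
        if any(s < 2 for s in sizes):
            raise ValueError("module sizes must be >= 2")
        if self.p_within <= self.p_background:
            raise ValueError("p_within must exceed p_background for meaningful planting")


@dataclass(frozen=True)
class SyntheticDataset:
    network: GeneNetwork
    known: KnownGeneSet
    modules: tuple[frozenset[str], ...]  # ground-truth planted modules
    planted_candidates: frozenset[str]   # unlabeled module members

    def module_of(self, gene: str) -> int | None:
        for i, m in enumerate(self.modules):
            if gene in m:
                return i
        return None


def _module_sizes(spec: SyntheticSpec, rng: np.random.Generator) -> list[int]:
    if isinstance(spec.module_size, tuple):
        lo, hi = spec.module_size
        return [int(rng.integers(lo, hi + 1)) for _ in range(spec.n_modules)]
    return [spec.module_size] * spec.n_modules


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw one synthetic dataset; deterministic given ``spec.seed``.

    Draw order is fixed: module sizes, then within-module edges (module by
    module, node-index order), background edges, attachment edges, and
    finally the known labels (per module, then background).
    """
    rng = np.random.default_rng(spec.seed)
    sizes = _module_sizes(spec, rng)

    modules: list[list[str]] = []
    for j, size in enumerate(sizes):
        modules.append([f"M{j}_{i:03d}" for i in range(size)])
    background = [f"B{i:03d}" for i in range(spec.n_background)]

    edges: list[tuple[str, str]] = []
    for mod in modules:
        for ai in range(len(mod)):
            for bi in range(ai + 1, len(mod)):
                if rng.random() < spec.p_within:
                    edges.append(canonical_edge(mod[ai], mod[bi]))
    for ai in range(len(background)):
        for bi in range(ai + 1, len(background)):
            if rng.random() < spec.p_background:
                edges.append(canonical_edge(background[ai], background[bi]))
    for mod in modules:
        for m_node in mod:
            for b_node in background:
                if rng.random() < spec.p_attach:
                    edges.append(canonical_edge(m_node, b_node))

    known: set[str] = set()
    for mod in modules:
        n_known = round(spec.known_frac_module * len(mod))
        picked = rng.choice(len(mod), size=n_known, replace=False)
        known.update(mod[i] for i in sorted(picked))
    n_known_bg = round(spec.known_frac_background * len(background))
    if n_known_bg:
        picked = rng.choice(len(background), size=n_known_bg, replace=False)
        known.update(background[i] for i in sorted(picked))

    network = GeneNetwork(edges)
    module_sets = tuple(frozenset(m) for m in modules)
    planted = frozenset().union(*module_sets) - known if module_sets else frozenset()
    return SyntheticDataset(network=network, known=KnownGeneSet(frozenset(known)),
                            modules=module_sets, planted_candidates=planted)


def holdout_known(known: KnownGeneSet, fraction: float,
                  seed: int) -> tuple[KnownGeneSet, KnownGeneSet]:
    """Split the bait set into (visible, hidden) for recovery experiments.

    ``round(fraction * |known|)`` genes are hidden; the draw is seeded and
    the partition is disjoint and exhaustive.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    members = sorted(known.members)
    n_hidden = round(fraction * len(members))
    if n_hidden == 0 or n_hidden == len(members):
        raise ValueError(f"degenerate holdout: {n_hidden} of {len(members)} hidden")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(members))
    hidden = frozenset(members[i] for i in order[:n_hidden])
    visible = frozenset(members) - hidden
    return KnownGeneSet(visible), KnownGeneSet(hidden)


def write_dataset(ds: SyntheticDataset, outdir: str | Path,
                  prefix: str = "synthetic") -> dict[str, Path]:
    """Emit edge-list TSV, known-gene list and ground-truth JSON.

    The files are exactly what the pipeline consumes as real inputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "edges": outdir / f"{prefix}_edges.tsv",
        "known": outdir / f"{prefix}_known.txt",
        "truth": outdir / f"{prefix}_truth.json",
    }
    with open(paths["edges"], "w") as fh:
        fh.write("source\ttarget\n")
        for u, v in sorted(ds.network.edges):
            fh.write(f"{u}\t{v}\n")
    with open(paths["known"], "w") as fh:
        for g in sorted(ds.known.members):
            fh.write(g + "\n")
    truth = {
        "modules": [sorted(m) for m in ds.modules],
        "planted_candidates": sorted(ds.planted_candidates),
    }
    paths["truth"].write_text(json.dumps(truth, indent=2) + "\n")
    return paths
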