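"""Benchmark data generator: random trees and inversion evolution.

Model trees are unrooted binary trees over a configurable number of leaves.
Two edge-length regimes are provided:

* ``uniform`` — the topology is uniform over unrooted binary leaf-labelled
  trees and every edge's expected inversion count is drawn uniformly in
  ``[r*n*(1-f), r*n*(1+f)]`` where ``r`` is the per-edge rate as a fraction
  of the gene count and ``f`` the relative fluctuation (default 50%).
* ``lin_moret`` — same topologies with exponentially distributed edge
  weights rescaled so the largest leaf-to-leaf expected-event path equals
  ``diameter * n``, giving the deliberately unbalanced edge lengths of
  Lin-Moret-style birth-death trees.

Gene orders evolve by inversions only: the root carries the identity
circular genome and each edge applies ``round(edge weight)`` inversions
with endpoints drawn uniformly over positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .genomes import Genome, apply_inversion
from .trees import PhyloTree

__all__ = ["SimConfig", "SimulatedDataset", "random_tree", "evolve", "simulate"]


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset.

    ``rate_per_edge`` and ``diameter`` are fractions/multiples of the gene
    count ``n`` (a rate of 0.12 on 100 genes means 12 expected inversions
    per edge).
    """

    n: int = 100
    leaves: int = 10
    model: Literal["uniform", "lin_moret"] = "uniform"
    rate_per_edge: float = 0.12
    fluctuation: float = 0.5
    diameter: float = 2.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.leaves < 3:
            raise ValueError("need at least 3 leaves")
        if not 0 <= self.fluctuation < 1:
            raise ValueError("fluctuation must be in [0, 1)")
        if self.rate_per_edge < 0 or self.diameter <= 0:
            raise ValueError("rates must be nonnegative, diameter positive")
        if self.model not in ("uniform", "lin_moret"):
            raise ValueError(f"unknown tree model {self.model!r}")


@dataclass
class SimulatedDataset:
    """A model tree plus the true gene order at every node."""

    tree: PhyloTree
    true_genomes: dict[str, Genome]
    config: SimConfig

    @property
    def leaf_genomes(self) -> dict[str, Genome]:
        return {u: self.true_genomes[u] for u in self.tree.leaves()}

    @property
    def internal_genomes(self) -> dict[str, Genome]:
        return {u: self.true_genomes[u] for u in self.tree.internal_nodes()}


def random_tree(cfg: SimConfig, rng: np.random.Generator) -> PhyloTree:
    """Draw a tree topology and per-edge expected event counts.

    The topology is built by attaching each new leaf to a uniformly chosen
    existing edge, which yields the uniform distribution over unrooted
    binary leaf-labelled topologies.
    """
    adjacency: dict[str, dict[str, float]] = {
        "A1": {"L1": 0.0, "L2": 0.0, "L3": 0.0},
        "L1": {"A1": 0.0},
        "L2": {"A1": 0.0},
        "L3": {"A1": 0.0},
    }
    edges = [("A1", "L1"), ("A1", "L2"), ("A1", "L3")]
    for m in range(4, cfg.leaves + 1):
        u, v = edges[rng.integers(len(edges))]
        mid, leaf = f"A{m - 2}", f"L{m}"
        del adjacency[u][v], adjacency[v][u]
        adjacency[mid] = {u: 0.0, v: 0.0, leaf: 0.0}
        adjacency[u][mid] = adjacency[v][mid] = 0.0
        adjacency[leaf] = {mid: 0.0}
        edges.remove((u, v))
        edges.extend([(u, mid), (mid, v), (mid, leaf)])

    if cfg.model == "uniform":
        lo = cfg.rate_per_edge * cfg.n * (1 - cfg.fluctuation)
        hi = cfg.rate_per_edge * cfg.n * (1 + cfg.fluctuation)
        weights = {e: float(rng.uniform(lo, hi)) for e in edges}
    else:  # lin_moret
        weights = {e: float(rng.exponential(1.0)) for e in edges}
        tmp = PhyloTree(
            {
                u: {v: weights.get((u, v), weights.get((v, u))) for v in nb}
                for u, nb in adjacency.items()
            }
        )
        lvs = tmp.leaves()
        dia = max(
            tmp.path_length(a, b)
            for i, a in enumerate(lvs)
            for b in lvs[i + 1 :]
        )
        scale = cfg.diameter * cfg.n / dia
        weights = {e: w * scale for e, w in weights.items()}

    for (u, v), w in weights.items():
        adjacency[u][v] = adjacency[v][u] = w
    return PhyloTree(adjacency)


def _random_inversion(g: Genome, rng: np.random.Generator) -> Genome:
    i = int(rng.integers(1, g.n + 1))
    j = int(rng.integers(1, g.n + 1))
    if i > j:
        i, j = j, i
    return apply_inversion(g, i, j)


def evolve(
    tree: PhyloTree, cfg: SimConfig, rng: np.random.Generator
) -> SimulatedDataset:
    """Run inversion evolution down the tree from an identity root genome."""
    root = tree.root
    genomes: dict[str, Genome] = {
        root: Genome(tuple(range(1, cfg.n + 1)), name=root)
    }
    order = [(node, parent) for node, parent in tree.postorder()][::-1]
    for node, parent in order:
        if parent is None:
            continue
        k = int(round(tree.edge_length(parent, node)))
        g = genomes[parent]
        for _ in range(k):
            g = _random_inversion(g, rng)
        genomes[node] = Genome(g.genes, name=node)
    return SimulatedDataset(tree=tree, true_genomes=genomes, config=cfg)


def simulate(cfg: SimConfig, rng: np.random.Generator | None = None) -> SimulatedDataset:
    """Draw one dataset: tree + true gene orders everywhere."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    tree = random_tree(cfg, rng)
    return evolve(tree, cfg, rng)
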