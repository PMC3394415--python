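"""Binary phylogenies carrying gene-order data on their leaves.

The tree is stored unrooted (every internal node has degree 3); a ``root``
attribute merely orients traversals.  Edge lengths are expected rearrangement
events along the edge, in events (not events per gene).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import dendropy

from .genomes import Genome

__all__ = ["PhyloTree", "TreeError", "reroot"]


class TreeError(ValueError):
    pass


@dataclass
class PhyloTree:
    """Unrooted binary tree over labelled nodes with per-edge event counts.

    Parameters
    ----------
    adjacency :
        ``{node: {neighbor: edge_length}}``, symmetric.
    leaf_genomes :
        Genome observed at each leaf; may be empty before data are attached.
    root :
        Node used to orient rooted traversals (any node; default: first
        internal node in sorted order).
    """

    adjacency: dict[str, dict[str, float]]
    leaf_genomes: dict[str, Genome] = field(default_factory=dict)
    root: str | None = None

    def __post_init__(self) -> None:
        for u, nbrs in self.adjacency.items():
            for v, w in nbrs.items():
                if self.adjacency.get(v, {}).get(u) != w:
                    raise TreeError(f"asymmetric edge ({u}, {v})")
                if w < 0:
                    raise TreeError(f"negative edge length on ({u}, {v})")
        degs = {u: len(nbrs) for u, nbrs in self.adjacency.items()}
        if any(d not in (1, 3) for d in degs.values()):
            bad = {u: d for u, d in degs.items() if d not in (1, 3)}
            raise TreeError(f"tree is not unrooted-binary; degrees {bad}")
        for leaf, g in self.leaf_genomes.items():
            if degs.get(leaf) != 1:
                raise TreeError(f"genome attached to non-leaf node {leaf!r}")
        if self.root is None:
            internals = self.internal_nodes()
            self.root = internals[0] if internals else sorted(self.adjacency)[0]

    # -- structure ---------------------------------------------------------

    def leaves(self) -> list[str]:
        return sorted(u for u, nbrs in self.adjacency.items() if len(nbrs) == 1)

    def internal_nodes(self) -> list[str]:
        return sorted(u for u, nbrs in self.adjacency.items() if len(nbrs) == 3)

    def neighbors(self, node: str) -> list[str]:
        return sorted(self.adjacency[node])

    def edge_length(self, u: str, v: str) -> float:
        return self.adjacency[u][v]

    def edges(self) -> list[tuple[str, str, float]]:
        out = []
        for u in sorted(self.adjacency):
            for v, w in sorted(self.adjacency[u].items()):
                if u < v:
                    out.append((u, v, w))
        return out

    def copy(self) -> "PhyloTree":
        return PhyloTree(
            {u: dict(nbrs) for u, nbrs in self.adjacency.items()},
            dict(self.leaf_genomes),
            self.root,
        )

    @property
    def n_genes(self) -> int:
        if not self.leaf_genomes:
            raise TreeError("no leaf genomes attached")
        sizes = {g.n for g in self.leaf_genomes.values()}
        if len(sizes) != 1:
            raise TreeError(f"leaf genomes have mixed gene counts {sizes}")
        return sizes.pop()

    # -- traversal ---------------------------------------------------------

    def postorder(self, root: str | None = None) -> Iterator[tuple[str, str | None]]:
        """Yield ``(node, parent)`` pairs, children before parents."""
        root = root if root is not None else self.root
        stack = [(root, None)]
        out = []
        while stack:
            node, parent = stack.pop()
            out.append((node, parent))
            for child in self.neighbors(node):
                if child != parent:
                    stack.append((child, node))
        return iter(reversed(out))

    def path_length(self, a: str, b: str) -> float:
        """Sum of edge lengths along the unique path between two nodes."""
        parent = {a: None}
        stack = [a]
        while stack:
            u = stack.pop()
            if u == b:
                break
            for v in self.adjacency[u]:
                if v not in parent:
                    parent[v] = u
                    stack.append(v)
        if b not in parent:
            raise TreeError(f"{b!r} not reachable from {a!r}")
        total, u = 0.0, b
        while parent[u] is not None:
            total += self.adjacency[u][parent[u]]
            u = parent[u]
        return total

    # -- Newick ------------------------------------------------------------

    @classmethod
    def from_newick(
        cls, newick: str, leaf_genomes: dict[str, Genome] | None = None
    ) -> "PhyloTree":
        """Parse a Newick string; a bifurcating root is suppressed."""
        dt = dendropy.Tree.get(data=newick, schema="newick")
        dt.deroot()
        adjacency: dict[str, dict[str, float]] = {}
        counter = [0]

        def label(nd) -> str:
            if nd.taxon is not None and nd.taxon.label:
                return nd.taxon.label
            if nd.label:
                return nd.label
            counter[0] += 1
            nd.label = f"A{counter[0]}"
            return nd.label

        for nd in dt.preorder_node_iter():
            adjacency.setdefault(label(nd), {})
        for nd in dt.preorder_node_iter():
            if nd.parent_node is not None:
                u, v = label(nd.parent_node), label(nd)
                w = float(nd.edge.length or 0.0)
                adjacency[u][v] = w
                adjacency[v][u] = w
        return cls(adjacency, leaf_genomes or {})

    def to_newick(self) -> str:
        root = self.root

        def render(node: str, parent: str | None) -> str:
            kids = [c for c in self.neighbors(node) if c != parent]
            if not kids:
                s = node
            else:
                s = "(" + ",".join(render(c, node) for c in kids) + ")" + node
            if parent is not None:
                s += f":{self.adjacency[node][parent]:g}"
            return s

        return render(root, None) + ";"


def reroot(tree: PhyloTree, target: str) -> PhyloTree:
    """Return a copy of the tree oriented so ``target`` roots traversals.

    The underlying unrooted topology and edge lengths are untouched, so all
    leaf-partition/edge-length pairs (and pairwise leaf path lengths) are
    preserved.
    """
    if target not in tree.adjacency:
        raise TreeError(f"unknown node {target!r}")
    if len(tree.adjacency[target]) == 1:
        raise TreeError(f"cannot root at leaf {target!r}")
    out = tree.copy()
    out.root = target
    return out
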