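"""Model/Results interface over the reconstruction pipeline.

:class:`AncestralGeneOrder` bundles the data (a binary tree with circular
gene orders on its leaves); :meth:`~AncestralGeneOrder.fit` runs one of the
three reconstruction methods and returns an :class:`AncestralReconstruction`
results object carrying the inferred genomes, the adjacency posteriors, the
converged tree score and a printable summary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd

from .genomes import Genome, adjacencies_of, dcj_distance, read_grappa, write_grappa
from .likelihood import adjacency_posteriors, estimate_edge_lengths
from .mixture import MixtureConfig, refine_tree, tree_score
from .trees import PhyloTree

__all__ = ["AncestralGeneOrder", "AncestralReconstruction"]


class AncestralGeneOrder:
    """Ancestral gene-order reconstruction on a fixed phylogeny.

    Parameters
    ----------
    tree :
        Unrooted binary tree; edge lengths are expected rearrangement
        events.  Leaf genomes may be attached to the tree or passed
        separately.
    leaf_genomes :
        Mapping leaf label -> :class:`~medmix.genomes.Genome`; overrides
        genomes already on the tree.

    Examples
    --------
    >>> model = AncestralGeneOrder.from_files("leaves.txt", "tree.nwk")
    >>> res = model.fit(method="mixture", seed=0)
    >>> print(res.summary())
    """

    def __init__(
        self,
        tree: PhyloTree,
        leaf_genomes: dict[str, Genome] | None = None,
    ):
        tree = tree.copy()
        if leaf_genomes is not None:
            tree.leaf_genomes = dict(leaf_genomes)
        missing = [u for u in tree.leaves() if u not in tree.leaf_genomes]
        if missing:
            raise ValueError(f"leaves without genomes: {missing}")
        tree.n_genes  # validates a single shared gene count
        self.tree = tree

    @classmethod
    def from_files(cls, genome_path, newick_path) -> "AncestralGeneOrder":
        """Read GRAPPA-style gene orders and a Newick topology."""
        genomes = {g.name: g for g in read_grappa(genome_path)}
        with open(newick_path) as fh:
            tree = PhyloTree.from_newick(fh.read())
        return cls(tree, {u: genomes[u] for u in tree.leaves()})

    def fit(
        self,
        method: str = "mixture",
        config: MixtureConfig | None = None,
        seed: int | None = None,
        estimate_lengths: bool | None = None,
    ) -> "AncestralReconstruction":
        """Reconstruct every internal node.

        ``method`` — ``"ml"`` (adjacency-posterior reconstruction only),
        ``"median"`` (iterative unconstrained medians) or ``"mixture"``
        (randomized adjacency fixing; the default).  ``estimate_lengths``
        refits edge lengths from pairwise leaf DCJ distances; by default
        this happens only when the tree carries no lengths at all.
        """
        cfg = config or MixtureConfig()
        if seed is not None:
            cfg = MixtureConfig(**{**vars(cfg), "seed": seed})
        tree = self.tree
        if estimate_lengths is None:
            estimate_lengths = all(w == 0 for _u, _v, w in tree.edges())
        if estimate_lengths:
            tree = estimate_edge_lengths(tree)
        ancestors, score, info = refine_tree(tree, cfg, method=method)
        posteriors = (
            {}
            if method == "median"
            else {u: adjacency_posteriors(tree, u) for u in tree.internal_nodes()}
        )
        return AncestralReconstruction(
            model=self,
            fitted_tree=tree,
            method=method,
            config=cfg,
            ancestors=ancestors,
            posteriors=posteriors,
            tree_score=score,
            diagnostics=info,
        )


@dataclass
class AncestralReconstruction:
    """Fitted ancestral genomes and their diagnostics."""

    model: AncestralGeneOrder
    fitted_tree: PhyloTree
    method: str
    config: MixtureConfig
    ancestors: dict[str, Genome]
    posteriors: dict[str, dict[tuple[int, int], float]]
    tree_score: int
    diagnostics: dict = field(default_factory=dict)

    def summary(self) -> str:
        tree = self.fitted_tree
        full = {**tree.leaf_genomes, **self.ancestors}
        rows = []
        for node in sorted(self.ancestors):
            nbrs = tree.neighbors(node)
            local = sum(dcj_distance(full[node], full[v]) for v in nbrs)
            post = self.posteriors.get(node, {})
            own = adjacencies_of(full[node])
            high = sum(1 for a in own if post.get(a, 0.0) > 0.9)
            rows.append(
                {
                    "node": node,
                    "neighbors": ",".join(nbrs),
                    "local score": local,
                    "high-posterior adjacencies": high if post else "-",
                }
            )
        frame = pd.DataFrame(rows).set_index("node")
        head = (
            f"Ancestral gene orders ({self.method}), "
            f"{tree.n_genes} genes, {len(tree.leaves())} leaves\n"
            f"tree score (sum of edge DCJ distances): {self.tree_score}\n"
            f"sweeps: {self.diagnostics.get('sweeps', 0)}\n"
        )
        return head + frame.to_string()

    def accuracy_against(self, truth: dict[str, Genome]) -> dict[str, float]:
        """Adjacency accuracy per internal node against known ancestors."""
        from .evaluate import adjacency_accuracy

        return {
            u: adjacency_accuracy(g, truth[u])
            for u, g in self.ancestors.items()
            if u in truth
        }

    def save(self, directory) -> None:
        """Write ancestors (GRAPPA), posteriors (TSV) and a JSON run log."""
        import os

        os.makedirs(directory, exist_ok=True)
        write_grappa(
            os.path.join(directory, "ancestors.txt"),
            [self.ancestors[u] for u in sorted(self.ancestors)],
        )
        with open(os.path.join(directory, "posteriors.tsv"), "w") as fh:
            fh.write("node\tu\tv\tposterior\n")
            for node in sorted(self.posteriors):
                for (u, v), p in sorted(self.posteriors[node].items()):
                    fh.write(f"{node}\t{u}\t{v}\t{p:.6g}\n")
        log = {
            "method": self.method,
            "tree_score": self.tree_score,
            "config": vars(self.config).copy(),
            "diagnostics": self.diagnostics,
        }
        with open(os.path.join(directory, "run.json"), "w") as fh:
            json.dump(log, fh, indent=2)
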