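"""Randomized adjacency fixing: the likelihood/median mixture pipeline.

The likelihood stage proposes an ancestral genome whose adjacencies are only
partly correct, and — apart from a small high-posterior subset — their
posteriors are too flat to tell correct from incorrect ones.  The mixture
stage sorts them out empirically: over many replicates, a random subset of
the proposed adjacencies is fixed in a constrained median computation, and
every *non-fixed* proposal that re-appears in the median output earns an
occurrence count.  Correct adjacencies tend to be re-derived by the median
no matter which subset was fixed, so occurrence rate separates them.  The
top-ranked fraction (the selection percentage) is then fixed in one final
median computation per node, and the whole tree is swept node by node until
the tree score (sum of DCJ distances over edges) stops decreasing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .genomes import Genome, adjacencies_of, dcj_distance
from .likelihood import adjacency_posteriors, assemble_ml_genome
from .median import MedianResult, solve_median
from .trees import PhyloTree

__all__ = [
    "MixtureConfig",
    "OccurrenceTable",
    "rank_adjacencies",
    "select_and_finalize",
    "refine_tree",
    "tree_score",
]

logger = logging.getLogger(__name__)


@dataclass
class MixtureConfig:
    """Tuning knobs of the randomized-fixing pipeline.

    fix_fraction :
        Fraction of the n proposed adjacencies fixed in each replicate
        (default 0.72, the middle of the workable 70-75% window).
    selection_percentage :
        Fraction kept after occurrence ranking for the final constrained
        median.  ``None`` selects automatically: 0.70 for closely related
        genomes (per-edge rate <= 24% of n, or tree diameter <= 3.0 n),
        0.75 beyond that.
    replicates :
        Number of randomized median replicates per node (default 100, past
        which the occurrence ranking is empirically stable).
    high_prob_threshold :
        Posterior above which a proposed adjacency is fixed in every
        replicate (default 0.90).
    node_budget :
        Branch-and-bound node limit per median call; exhausted replicates
        are kept but flagged in the log.
    """

    fix_fraction: float = 0.72
    selection_percentage: float | None = None
    replicates: int = 100
    high_prob_threshold: float = 0.90
    seed: int | None = None
    node_budget: int = 100_000
    max_sweeps: int = 20
    rank_once: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.fix_fraction <= 1:
            raise ValueError("fix_fraction must be in [0, 1]")
        sel = self.selection_percentage
        if sel is not None:
            if not 0 <= sel <= 1:
                raise ValueError("selection_percentage must be in [0, 1]")
            if not 0.65 <= sel <= 0.85:
                logger.warning(
                    "selection_percentage %.2f is outside the well-tested "
                    "0.65-0.85 range", sel,
                )

    def resolve_selection(
        self, rate: float | None = None, diameter: float | None = None
    ) -> float:
        if self.selection_percentage is not None:
            return self.selection_percentage
        if rate is not None and rate <= 0.24:
            return 0.70
        if diameter is not None and diameter <= 3.0:
            return 0.70
        if rate is None and diameter is None:
            return 0.70
        return 0.75


@dataclass
class OccurrenceTable:
    """Per-adjacency occurrence bookkeeping over the replicates.

    ``counts[a]`` — replicates in which ``a`` was *not* fixed yet showed up
    in the median output; ``eligible[a]`` — replicates in which it was not
    fixed at all.  Ranking uses the rate ``counts/eligible`` so that
    frequently fixed adjacencies are not penalized.
    """

    counts: dict[tuple[int, int], int] = field(default_factory=dict)
    eligible: dict[tuple[int, int], int] = field(default_factory=dict)
    budget_flagged: int = 0

    def rate(self, adj: tuple[int, int]) -> float:
        e = self.eligible.get(adj, 0)
        return self.counts.get(adj, 0) / e if e else 0.0


def _fix_quota(cfg: MixtureConfig, n: int) -> int:
    return int(round(cfg.fix_fraction * n))


def rank_adjacencies(
    neighbors: tuple[Genome, Genome, Genome],
    ml_genome: Genome,
    posteriors: dict[tuple[int, int], float],
    cfg: MixtureConfig,
    rng: np.random.Generator | None = None,
) -> OccurrenceTable:
    """Occurrence-rank the proposed adjacencies by randomized median runs.

    In each of ``cfg.replicates`` replicates the high-posterior proposals
    are fixed unconditionally, a uniform random sample of the remaining
    proposals tops the fixed set up to ``fix_fraction * n``, and a
    constrained median of the three neighbor genomes is solved.  Any subset
    of one genome's adjacencies is automatically a compatible partial
    matching, so no conflict resolution is needed for proposals.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    ml_adjs = sorted(adjacencies_of(ml_genome))
    always = [
        a for a in ml_adjs if posteriors.get(a, 0.0) > cfg.high_prob_threshold
    ]
    pool = [a for a in ml_adjs if a not in set(always)]
    quota = _fix_quota(cfg, ml_genome.n)
    table = OccurrenceTable()
    for _rep in range(cfg.replicates):
        k = min(max(quota - len(always), 0), len(pool))
        picked = [pool[i] for i in rng.choice(len(pool), size=k, replace=False)]
        fixed = always + picked
        res = solve_median(
            *neighbors,
            fixed=fixed,
            budget=cfg.node_budget,
            initial=[ml_genome],
        )
        if not res.optimal:
            table.budget_flagged += 1
            logger.info("median budget exhausted in a ranking replicate")
        med_adjs = adjacencies_of(res.median)
        fixed_set = set(fixed)
        for a in ml_adjs:
            if a in fixed_set:
                continue
            table.eligible[a] = table.eligible.get(a, 0) + 1
            if a in med_adjs:
                table.counts[a] = table.counts.get(a, 0) + 1
    return table


def select_and_finalize(
    table: OccurrenceTable,
    posteriors: dict[tuple[int, int], float],
    cfg: MixtureConfig,
    neighbors: tuple[Genome, Genome, Genome],
    ml_genome: Genome,
    selection_percentage: float | None = None,
) -> MedianResult:
    """Fix the top-ranked proposals and run the final constrained median.

    Proposals are sorted by occurrence rate (ties: higher posterior, then
    vertex ids); the top ``selection_percentage * n`` that remain mutually
    compatible are fixed.
    """
    sel = (
        selection_percentage
        if selection_percentage is not None
        else cfg.resolve_selection()
    )
    n = ml_genome.n
    ml_adjs = sorted(adjacencies_of(ml_genome))
    ranked = sorted(
        ml_adjs,
        key=lambda a: (-table.rate(a), -posteriors.get(a, 0.0), a),
    )
    k = int(round(sel * n))
    chosen: list[tuple[int, int]] = []
    used: set[int] = set()
    for a in ranked:
        if len(chosen) >= k:
            break
        if a[0] in used or a[1] in used:
            continue
        chosen.append(a)
        used.update(a)
    return solve_median(
        *neighbors, fixed=chosen, budget=cfg.node_budget, initial=[ml_genome]
    )


def tree_score(tree: PhyloTree, genomes: dict[str, Genome]) -> int:
    """Sum of DCJ distances over all tree edges under a full node labelling."""
    return sum(
        dcj_distance(genomes[u], genomes[v]) for u, v, _w in tree.edges()
    )


def _nearest_leaf_genome(tree: PhyloTree, node: str) -> Genome:
    # breadth-first: closest leaf by edge count, ties by label
    frontier = [node]
    seen = {node}
    while frontier:
        for u in frontier:
            if len(tree.adjacency[u]) == 1:
                return tree.leaf_genomes[u]
        nxt = []
        for u in frontier:
            for v in tree.neighbors(u):
                if v not in seen:
                    seen.add(v)
                    nxt.append(v)
        frontier = sorted(nxt)
    raise RuntimeError("tree has no leaves")  # pragma: no cover


def refine_tree(
    tree: PhyloTree,
    cfg: MixtureConfig,
    method: str = "mixture",
    rate: float | None = None,
    diameter: float | None = None,
) -> tuple[dict[str, Genome], int, dict]:
    """Iteratively update every internal node by (constrained) medians.

    ``method="mixture"`` initializes each internal node with its likelihood
    reconstruction and updates it with the randomized-fixing median;
    ``method="median"`` is the pure parsimony baseline: nearest-leaf
    initialization and unconstrained medians.  A node update is accepted
    only when it strictly lowers the node's local score (sum of distances
    to its three neighbors), so the tree score never increases; sweeps stop
    when a full sweep leaves the score unchanged.

    Returns ``(internal genomes, converged tree score, diagnostics)``.
    """
    if method not in ("mixture", "median", "ml"):
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(cfg.seed)
    internal = tree.internal_nodes()
    if len(tree.leaves()) < 3:
        raise ValueError("tree must have at least 3 leaves")

    estimates: dict[str, Genome] = dict(tree.leaf_genomes)
    ml_info: dict[str, tuple[Genome, dict]] = {}
    for node in internal:
        if method == "median":
            estimates[node] = _nearest_leaf_genome(tree, node)
        else:
            post = adjacency_posteriors(tree, node)
            g = assemble_ml_genome(post, tree.n_genes, name=node)
            ml_info[node] = (g, post)
            estimates[node] = g
    if method == "ml":
        score = tree_score(tree, estimates)
        return (
            {u: estimates[u] for u in internal},
            score,
            {"sweeps": 0, "scores": [score]},
        )

    score = tree_score(tree, estimates)
    scores = [score]
    tables: dict[str, OccurrenceTable] = {}
    non_optimal = 0
    for sweep in range(cfg.max_sweeps):
        improved = False
        for node in internal:
            nbrs = tuple(estimates[v] for v in tree.neighbors(node))
            local = sum(dcj_distance(estimates[node], g) for g in nbrs)
            if method == "median":
                res = solve_median(
                    *nbrs,
                    budget=cfg.node_budget,
                    initial=[estimates[node], *nbrs],
                )
            else:
                ml_genome, post = ml_info[node]
                if cfg.rank_once and node in tables:
                    table = tables[node]
                else:
                    table = rank_adjacencies(nbrs, ml_genome, post, cfg, rng)
                    tables[node] = table
                res = select_and_finalize(
                    table,
                    post,
                    cfg,
                    nbrs,
                    ml_genome,
                    selection_percentage=cfg.resolve_selection(rate, diameter),
                )
            if not res.optimal:
                non_optimal += 1
            if res.score < local:
                estimates[node] = Genome(res.median.genes, name=node)
                improved = True
        new_score = tree_score(tree, estimates)
        assert new_score <= score, "tree score increased during refinement"
        scores.append(new_score)
        if not improved or new_score == score:
            score = new_score
            break
        score = new_score
    else:
        logger.warning(
            "refinement did not converge within %d sweeps", cfg.max_sweeps
        )
    return (
        {u: estimates[u] for u in internal},
        score,
        {
            "sweeps": len(scores) - 1,
            "scores": scores,
            "non_optimal_medians": non_optimal,
        },
    )
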