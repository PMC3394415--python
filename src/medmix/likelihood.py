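"""Likelihood-based adjacency posteriors and ancestral genome assembly.

Each candidate adjacency evolves independently along the tree as a two-state
(present/absent) continuous-time Markov chain with the edge's expected event
count as its time.  One inversion on a circular n-gene genome breaks 2 of
its n adjacencies, so the loss rate is ``2/n`` per event; a broken junction
re-forms this particular adjacency by picking one partner among the ``2n-3``
available ends, giving a gain rate of ``2 / (n * (2n-3))`` per event.  The
stationary probability of "present" is therefore ``1/(2n-2)`` — each
extremity equally likely joined to any of the ``2n-2`` non-sibling
extremities — which is also the prior used at the root, and the limit every
transition row approaches on long edges.

The tree is rooted at the node being inferred, conditional likelihoods are
pruned from the leaves up (Felsenstein), and the root posterior is the
normalized prior-times-likelihood.  Adjacency independence is an
approximation; dependence enters only when the adjacencies are assembled
into a genome.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.optimize import nnls

from .genomes import Genome, adjacencies_of, genome_of, head, tail, dcj_distance
from .trees import PhyloTree, reroot

__all__ = [
    "adjacency_posteriors",
    "assemble_ml_genome",
    "ml_ancestor",
    "transition_matrix",
    "stationary_present",
    "estimate_edge_lengths",
]

logger = logging.getLogger(__name__)

_MIN_EDGE = 1e-9  # zero-length edges are floored so conflicting leaves
                  # resolve by majority weighting instead of 0/0


def stationary_present(n: int) -> float:
    """Stationary probability that a specific adjacency is present."""
    return 1.0 / (2 * n - 2)


def transition_matrix(t: float, n: int) -> np.ndarray:
    """2x2 transition matrix over states (present, absent) for ``t`` events.

    Closed form of ``expm(Q t)`` for the two-state chain with loss rate
    ``2/n`` and gain rate ``2/(n (2n-3))``: every entry relaxes toward the
    stationary distribution with total rate ``(2/n) (2n-2)/(2n-3)``.
    """
    t = max(float(t), _MIN_EDGE)
    pi = stationary_present(n)
    decay = np.exp(-(2.0 / n) * (2 * n - 2) / (2 * n - 3) * t)
    p_pp = pi + (1.0 - pi) * decay
    p_ap = pi * (1.0 - decay)
    return np.array([[p_pp, 1.0 - p_pp], [p_ap, 1.0 - p_ap]])


def adjacency_posteriors(
    tree: PhyloTree, target: str
) -> dict[tuple[int, int], float]:
    """Posterior presence probability at ``target`` for every adjacency
    observed in at least one leaf genome.

    Unobserved adjacencies all share one (small) posterior and are omitted;
    downstream assembly treats missing entries as ties below every observed
    candidate.
    """
    rtree = reroot(tree, target)
    n = rtree.n_genes
    leaf_adjs = {
        leaf: adjacencies_of(g) for leaf, g in rtree.leaf_genomes.items()
    }
    candidates = sorted(set().union(*leaf_adjs.values()))
    idx = {a: i for i, a in enumerate(candidates)}
    k = len(candidates)

    # conditional likelihoods, children before parents
    lik: dict[str, np.ndarray] = {}
    for node, parent in rtree.postorder():
        kids = [c for c in rtree.neighbors(node) if c != parent]
        if not kids:  # leaf
            arr = np.zeros((k, 2))
            present = np.fromiter(
                (a in leaf_adjs[node] for a in candidates), bool, k
            )
            arr[present, 0] = 1.0
            arr[~present, 1] = 1.0
        else:
            arr = np.ones((k, 2))
            for c in kids:
                P = transition_matrix(rtree.edge_length(node, c), n)
                arr *= lik[c] @ P.T
        lik[node] = arr

    pi = np.array([stationary_present(n), 1.0 - stationary_present(n)])
    joint = lik[target] * pi
    denom = joint.sum(axis=1)
    denom[denom == 0.0] = 1.0  # unreachable with floored edges; stay safe
    post = joint[:, 0] / denom
    return {a: float(post[idx[a]]) for a in candidates}


def assemble_ml_genome(
    posteriors: dict[tuple[int, int], float], n: int, name: str = "ml"
) -> Genome:
    """Greedy maximum-probability assembly of a single circular genome.

    Candidates are taken in order of decreasing posterior (ties by vertex
    ids); one is accepted iff both extremities are still free and it does
    not close a chromosome before all 2n extremities are matched (the final
    edge is exempt).  If the candidates strand some vertices, the genome is
    completed by lowest-id pairing and a warning is logged.
    """
    link = [0] * (2 * n + 1)
    for g in range(1, n + 1):
        link[tail(g)] = head(g)
        link[head(g)] = tail(g)
    free = [True] * (2 * n + 1)
    free[0] = False
    remaining = 2 * n
    chosen: list[tuple[int, int]] = []

    def accept(u: int, v: int) -> bool:
        nonlocal remaining
        if not (free[u] and free[v]) or u == v:
            return False
        if link[u] == v and remaining > 2:
            return False
        e1, e2 = link[u], link[v]
        link[e1], link[e2] = e2, e1
        free[u] = free[v] = False
        remaining -= 2
        chosen.append((u, v) if u < v else (v, u))
        return True

    ranked = sorted(posteriors.items(), key=lambda kv: (-kv[1], kv[0]))
    # the premature-cycle rule is order-dependent: an edge blocked early can
    # become acceptable after later fragments merge, so re-scan to fixpoint
    progress = True
    while progress and remaining:
        progress = False
        for (u, v), _p in ranked:
            if remaining == 0:
                break
            if accept(u, v):
                progress = True

    if remaining:
        logger.warning(
            "greedy assembly stranded %d extremities; completing by "
            "lowest-id pairing", remaining,
        )
        while remaining:
            u = next(x for x in range(1, 2 * n + 1) if free[x])
            for v in range(1, 2 * n + 1):
                if v != u and free[v] and (link[u] != v or remaining == 2):
                    accept(u, v)
                    break
    return genome_of(chosen, n, name=name)


def ml_ancestor(
    tree: PhyloTree, target: str, posteriors=None
) -> tuple[Genome, dict[tuple[int, int], float]]:
    """Maximum-likelihood ancestral genome at an internal node."""
    if posteriors is None:
        posteriors = adjacency_posteriors(tree, target)
    return (
        assemble_ml_genome(posteriors, tree.n_genes, name=target),
        posteriors,
    )


def estimate_edge_lengths(tree: PhyloTree) -> PhyloTree:
    """Fit edge event counts to pairwise leaf DCJ distances by least squares.

    Used when true per-edge rates are unknown: each leaf pair contributes
    the equation  sum of edge lengths on its path = DCJ distance, solved as
    a nonnegative least-squares problem.
    """
    leaves = tree.leaves()
    edges = [(u, v) for u, v, _w in tree.edges()]
    eidx = {e: i for i, e in enumerate(edges)}
    rows, rhs = [], []
    for i, a in enumerate(leaves):
        for b in leaves[i + 1 :]:
            row = np.zeros(len(edges))
            for u, v in _path_edges(tree, a, b):
                row[eidx[(u, v) if (u, v) in eidx else (v, u)]] = 1.0
            rows.append(row)
            rhs.append(
                dcj_distance(tree.leaf_genomes[a], tree.leaf_genomes[b])
            )
    sol, _ = nnls(np.array(rows), np.array(rhs, dtype=float))
    out = tree.copy()
    for (u, v), i in eidx.items():
        out.adjacency[u][v] = out.adjacency[v][u] = float(sol[i])
    return out


def _path_edges(tree: PhyloTree, a: str, b: str):
    parent: dict[str, str | None] = {a: None}
    stack = [a]
    while stack:
        u = stack.pop()
        for v in tree.adjacency[u]:
            if v not in parent:
                parent[v] = u
                stack.append(v)
    u = b
    while parent[u] is not None:
        yield parent[u], u
        u = parent[u]
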