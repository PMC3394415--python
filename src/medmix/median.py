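"""Exact DCJ median of three circular genomes by branch and bound.

The three genomes are superimposed on the shared extremity vertex set
{1..2n} as a multiple breakpoint graph (MBG): one perfect matching per
genome.  A median is a perfect matching M (itself describing a single
circular genome) maximizing the total number of alternating cycles it forms
with the three input matchings; the median score is ``3n - total_cycles``,
i.e. the sum of the three DCJ distances.

Search strategy
---------------
* **Adequate pairs.**  A vertex pair joined by >= 2 parallel input edges is
  committed to the median immediately and contracted out of the graph
  ("shrunk"), crediting one cycle per matching that contained the edge.
  Committing such a pair closes at least 2 cycles locally, which meets the
  3m/2 threshold for a 2-vertex (m = 1) adequate subgraph, so it belongs to
  an optimal completion; contraction shrinks the search space drastically
  when the genomes are close.
* **Adjacency fixing.**  Caller-supplied adjacencies are committed before
  the search starts by the same contraction, which is the edge surgery that
  removes (i, a), (j, b) and joins (a, b) in every matching lacking (i, j);
  the pair then behaves exactly like an adequate subgraph.
* **Branch and bound.**  Remaining vertices are matched by depth-first
  search: branch on the lowest free vertex, partners ordered by how many
  input matchings propose them.  The upper bound on additional cycles uses
  the triangle inequality of the cycle distance on matchings:
  ``c1 + c2 + c3 <= (3k + c12 + c13 + c23) / 2`` for k remaining vertex
  pairs.  Single-circle validity is enforced throughout: a median edge that
  would close a chromosome before all vertices are used is never taken.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .genomes import (
    Genome,
    GenomeError,
    adjacencies_of,
    count_cycles,
    genome_of,
    head,
    tail,
)

__all__ = [
    "MultipleBreakpointGraph",
    "MedianResult",
    "MedianError",
    "detect_adequate_pairs",
    "shrink",
    "fix_adjacency",
    "solve_median",
    "brute_force_median",
    "cycle_upper_bound",
]

DEFAULT_NODE_BUDGET = 10_000_000


class MedianError(ValueError):
    pass


class _BudgetExhausted(Exception):
    pass


class MultipleBreakpointGraph:
    """N >= 3 perfect matchings on the shared vertex set {1..2n}.

    After shrinking, the live vertex set may be a subset of {1..2n};
    vertex ids always keep their original meaning (gene i <-> 2i-1, 2i).
    """

    def __init__(
        self,
        n: int,
        matchings: Sequence[dict[int, int]],
        vertices: Iterable[int] | None = None,
    ):
        if len(matchings) < 3:
            raise MedianError("an MBG needs at least three matchings")
        self.n = n
        self.vertices = (
            frozenset(vertices)
            if vertices is not None
            else frozenset(range(1, 2 * n + 1))
        )
        for m in matchings:
            if set(m) != self.vertices:
                raise MedianError("matching does not cover the MBG vertex set")
            for u, v in m.items():
                if m.get(v) != u or u == v:
                    raise MedianError(f"not a perfect matching at ({u}, {v})")
        self.matchings = tuple(dict(m) for m in matchings)

    @classmethod
    def from_genomes(cls, *genomes: Genome) -> "MultipleBreakpointGraph":
        ns = {g.n for g in genomes}
        if len(ns) != 1:
            raise MedianError(f"genomes have mixed gene counts {ns}")
        n = ns.pop()
        matchings = []
        for g in genomes:
            m: dict[int, int] = {}
            for u, v in adjacencies_of(g):
                m[u] = v
                m[v] = u
            matchings.append(m)
        return cls(n, matchings)

    def edge_multiplicities(self) -> dict[tuple[int, int], int]:
        mult: dict[tuple[int, int], int] = {}
        for m in self.matchings:
            for u, v in m.items():
                if u < v:
                    mult[(u, v)] = mult.get((u, v), 0) + 1
        return mult


@dataclass(frozen=True)
class MedianResult:
    median: Genome
    score: int
    optimal: bool
    cycles: int = 0
    nodes: int = 0


def detect_adequate_pairs(
    mbg: MultipleBreakpointGraph,
) -> set[tuple[int, int]]:
    """Vertex pairs joined by >= 2 parallel edges (2-vertex adequate subgraphs).

    Overlapping candidates are resolved greedily: higher multiplicity first,
    ties by lowest vertex ids, later conflicting pairs dropped so the result
    is vertex-disjoint.
    """
    cands = [
        (-k, u, v) for (u, v), k in mbg.edge_multiplicities().items() if k >= 2
    ]
    cands.sort()
    used: set[int] = set()
    out: set[tuple[int, int]] = set()
    for _negk, u, v in cands:
        if u in used or v in used:
            continue
        used.update((u, v))
        out.add((u, v))
    return out


def shrink(
    mbg: MultipleBreakpointGraph, edge: tuple[int, int]
) -> tuple[MultipleBreakpointGraph, int]:
    """Contract median edge ``edge`` out of the MBG.

    A matching containing the edge is credited one alternating cycle and
    loses it; any other matching has its edges (u, a), (v, b) spliced into
    (a, b).  Returns the reduced MBG and the number of cycles credited.
    """
    u, v = edge
    if u not in mbg.vertices or v not in mbg.vertices:
        raise MedianError(f"edge ({u}, {v}) endpoints not in the MBG")
    gained = 0
    new_matchings = []
    for m in mbg.matchings:
        m = dict(m)
        if m[u] == v:
            gained += 1
        else:
            a, b = m[u], m[v]
            m[a], m[b] = b, a
        del m[u], m[v]
        new_matchings.append(m)
    return (
        MultipleBreakpointGraph(mbg.n, new_matchings, mbg.vertices - {u, v}),
        gained,
    )


def fix_adjacency(
    mbg: MultipleBreakpointGraph, adj: tuple[int, int]
) -> MultipleBreakpointGraph:
    """Force adjacency ``adj`` into every matching (edge surgery).

    Matchings already containing (i, j) are untouched; in every other one
    the incident edges (i, a), (j, b) are removed and (i, j), (a, b) added.
    Afterwards the pair is a 2-vertex adequate subgraph (all edges parallel).
    """
    i, j = adj
    if i not in mbg.vertices or j not in mbg.vertices:
        raise MedianError(f"adjacency ({i}, {j}) endpoints not in the MBG")
    if abs(i - j) == 1 and (min(i, j) + 1) // 2 == (max(i, j)) // 2 and min(i, j) % 2 == 1:
        raise MedianError(
            f"({i}, {j}) joins the two ends of one gene (1-gene circle)"
        )
    new_matchings = []
    for m in mbg.matchings:
        m = dict(m)
        if m[i] != j:
            a, b = m[i], m[j]
            m[a], m[b] = b, a
            m[i], m[j] = j, i
        new_matchings.append(m)
    return MultipleBreakpointGraph(mbg.n, new_matchings, mbg.vertices)


# ---------------------------------------------------------------------------
# branch and bound


class _Search:
    def __init__(self, n: int, matchings, budget: int, commit_multiplicity: int):
        self.n = n
        self.size = 2 * n + 1
        self.budget = budget
        self.commit_mult = commit_multiplicity
        self.nodes = 0
        self.best_cycles = -1
        self.best_edges: list[tuple[int, int]] | None = None
        self.ms0 = [self._as_array(m) for m in matchings]
        # link[v]: other endpoint of the open fragment (through gene edges and
        # chosen median edges) that v terminates; initially the gene edge.
        link = [0] * self.size
        for g in range(1, n + 1):
            link[tail(g)] = head(g)
            link[head(g)] = tail(g)
        self.link0 = link
        self._visited = bytearray(self.size)

    def _as_array(self, m: dict[int, int]) -> list[int]:
        arr = [0] * self.size
        for u, v in m.items():
            arr[u] = v
        return arr

    # -- state mutation ----------------------------------------------------

    @staticmethod
    def _commit(ms, link, alive, u, v) -> int:
        gained = 0
        for m in ms:
            if m[u] == v:
                gained += 1
            else:
                a, b = m[u], m[v]
                m[a], m[b] = b, a
            m[u] = m[v] = 0
        e1, e2 = link[u], link[v]
        link[e1], link[e2] = e2, e1
        link[u] = link[v] = 0
        alive[u] = alive[v] = False
        return gained

    def _eager_shrink(self, ms, link, alive, alive_count, cycles, chosen):
        m0, m1, m2 = ms
        need3 = self.commit_mult >= 3
        changed = True
        while changed:
            changed = False
            for u in range(1, self.size):
                if not alive[u]:
                    continue
                w0, w1, w2 = m0[u], m1[u], m2[u]
                if need3:
                    v = w0 if (w0 == w1 and w0 == w2) else 0
                else:
                    if w0 == w1 or w0 == w2:
                        v = w0
                    elif w1 == w2:
                        v = w1
                    else:
                        v = 0
                if v and (link[u] != v or alive_count == 2):
                    cycles += self._commit(ms, link, alive, u, v)
                    chosen.append((u, v) if u < v else (v, u))
                    alive_count -= 2
                    changed = True
        return alive_count, cycles

    # -- bound -------------------------------------------------------------

    def _pairwise_cycles(self, ma, mb, alive) -> int:
        vis = self._visited
        for u in range(1, self.size):
            vis[u] = 0
        cycles = 0
        for s in range(1, self.size):
            if not alive[s] or vis[s]:
                continue
            cycles += 1
            v, use_a = s, True
            while True:
                vis[v] = 1
                v = ma[v] if use_a else mb[v]
                use_a = not use_a
                if v == s and use_a:
                    break
                vis[v] = 1
        return cycles

    def _bound(self, ms, alive, alive_count, cycles) -> int:
        k = alive_count // 2
        cpair = (
            self._pairwise_cycles(ms[0], ms[1], alive)
            + self._pairwise_cycles(ms[0], ms[2], alive)
            + self._pairwise_cycles(ms[1], ms[2], alive)
        )
        return cycles + (3 * k + cpair) // 2

    # -- search ------------------------------------------------------------

    def greedy(self, ms, link, alive, alive_count, cycles, chosen):
        """One depth-first dive (highest multiplicity first): feasible median."""
        while True:
            alive_count, cycles = self._eager_shrink(
                ms, link, alive, alive_count, cycles, chosen
            )
            if alive_count == 0:
                return cycles, chosen
            u = next(x for x in range(1, self.size) if alive[x])
            cands = self._candidates(ms, link, alive, u)
            v = cands[0]
            cycles += self._commit(ms, link, alive, u, v)
            chosen.append((u, v) if u < v else (v, u))
            alive_count -= 2

    def _candidates(self, ms, link, alive, u) -> list[int]:
        banned = link[u]
        mult: dict[int, int] = {}
        for m in ms:
            w = m[u]
            mult[w] = mult.get(w, 0) + 1
        first = sorted(
            (w for w in mult if w != banned), key=lambda w: (-mult[w], w)
        )
        rest = [
            v
            for v in range(1, self.size)
            if alive[v] and v != u and v != banned and v not in mult
        ]
        return first + rest

    def search(self, ms, link, alive, alive_count, cycles, chosen):
        self.nodes += 1
        if self.nodes > self.budget:
            raise _BudgetExhausted
        alive_count, cycles = self._eager_shrink(
            ms, link, alive, alive_count, cycles, chosen
        )
        if alive_count == 0:
            if cycles > self.best_cycles:
                self.best_cycles = cycles
                self.best_edges = list(chosen)
            return
        if self._bound(ms, alive, alive_count, cycles) <= self.best_cycles:
            return
        u = next(x for x in range(1, self.size) if alive[x])
        for v in self._candidates(ms, link, alive, u):
            cms = [list(m) for m in ms]
            clink = list(link)
            calive = bytearray(alive)
            gained = self._commit(cms, clink, calive, u, v)
            self.search(
                cms,
                clink,
                calive,
                alive_count - 2,
                cycles + gained,
                chosen + [(u, v) if u < v else (v, u)],
            )


def _total_cycles(median: Genome, genomes: Sequence[Genome]) -> int:
    medge = adjacencies_of(median)
    return sum(count_cycles(medge, adjacencies_of(g)) for g in genomes)


def cycle_upper_bound(
    g1: Genome, g2: Genome, g3: Genome, fixed: Iterable[tuple[int, int]] = ()
) -> int:
    """Root-node upper bound on total median cycles (admissible).

    ``c1 + c2 + c3 <= (3k + c12 + c13 + c23) / 2`` by the triangle
    inequality of the cycle distance, evaluated after committing ``fixed``.
    """
    srch, ms, link, alive, alive_count, cycles = _prepare(
        g1, g2, g3, fixed, budget=1, commit_multiplicity=2
    )
    return srch._bound(ms, alive, alive_count, cycles)


def _prepare(g1, g2, g3, fixed, budget, commit_multiplicity):
    mbg = MultipleBreakpointGraph.from_genomes(g1, g2, g3)
    srch = _Search(mbg.n, mbg.matchings, budget, commit_multiplicity)
    ms = [list(m) for m in srch.ms0]
    link = list(srch.link0)
    alive = bytearray(srch.size)
    for v in range(1, srch.size):
        alive[v] = 1
    alive_count = 2 * mbg.n
    cycles = 0
    seen: set[int] = set()
    for u, v in fixed:
        if u in seen or v in seen or u == v:
            raise MedianError(f"fixed adjacencies reuse a vertex at ({u}, {v})")
        seen.update((u, v))
    for u, v in fixed:
        if not (1 <= u < srch.size and 1 <= v < srch.size):
            raise MedianError(f"fixed adjacency ({u}, {v}) out of range")
        if link[u] == v and alive_count > 2:
            raise MedianError(
                f"fixed adjacency ({u}, {v}) closes a premature circle"
            )
        cycles += srch._commit(ms, link, alive, u, v)
        alive_count -= 2
    return srch, ms, link, alive, alive_count, cycles


def solve_median(
    g1: Genome,
    g2: Genome,
    g3: Genome,
    fixed: Iterable[tuple[int, int]] = (),
    budget: int | None = None,
    initial: Iterable[Genome] = (),
    commit_multiplicity: int = 2,
) -> MedianResult:
    """Median genome of three circular genomes, optionally pre-constrained.

    Parameters
    ----------
    fixed :
        Extremity pairs forced into the median (must form a partial
        matching; must not close a chromosome prematurely).
    budget :
        Branch-and-bound node limit; on exhaustion the best median found so
        far is returned with ``optimal=False``.
    initial :
        Candidate genomes used to seed the incumbent (only those containing
        every fixed adjacency are eligible); a greedy dive always provides
        one feasible incumbent regardless.
    commit_multiplicity :
        Parallel-edge count at which a vertex pair is committed without
        branching (2 = all adequate pairs, 3 = only unanimous adjacencies).
    """
    fixed = [tuple(sorted(e)) for e in fixed]
    budget = DEFAULT_NODE_BUDGET if budget is None else budget
    srch, ms, link, alive, alive_count, cycles = _prepare(
        g1, g2, g3, fixed, budget, commit_multiplicity
    )
    genomes = (g1, g2, g3)
    n = g1.n
    fixed_set = set(fixed)

    best_edges: list[tuple[int, int]] | None = None
    best_cycles = -1
    for cand in initial:
        cedges = adjacencies_of(cand)
        if not fixed_set <= set(cedges):
            continue
        c = _total_cycles(cand, genomes)
        if c > best_cycles:
            best_cycles = c
            best_edges = sorted(cedges)

    # greedy dive for a guaranteed-feasible incumbent
    gcycles, gchosen = srch.greedy(
        [list(m) for m in ms], list(link), bytearray(alive), alive_count,
        cycles, list(fixed),
    )
    if gcycles > best_cycles:
        best_cycles, best_edges = gcycles, gchosen

    srch.best_cycles = best_cycles
    srch.best_edges = best_edges
    optimal = True
    try:
        srch.search(ms, link, alive, alive_count, cycles, list(fixed))
    except _BudgetExhausted:
        optimal = False

    median = genome_of(srch.best_edges, n, name="median")
    total = srch.best_cycles
    return MedianResult(
        median=median,
        score=3 * n - total,
        optimal=optimal,
        cycles=total,
        nodes=srch.nodes,
    )


def brute_force_median(
    g1: Genome,
    g2: Genome,
    g3: Genome,
    fixed: Iterable[tuple[int, int]] = (),
    max_n: int = 6,
) -> MedianResult:
    """Exact median by enumerating every circular signed permutation.

    Test oracle only; refuses n > ``max_n``.  Candidates are canonical
    (gene 1 first, positive), covering every distinct circular genome once.
    """
    from itertools import permutations, product

    n = g1.n
    if n > max_n:
        raise MedianError(f"brute force refuses n={n} > {max_n}")
    if {g.n for g in (g1, g2, g3)} != {n}:
        raise MedianError("genomes have mixed gene counts")
    genomes = (g1, g2, g3)
    fixed_set = {tuple(sorted(e)) for e in fixed}
    best: Genome | None = None
    best_cycles = -1
    count = 0
    for perm in permutations(range(2, n + 1)):
        for signs in product((1, -1), repeat=n - 1):
            cand = Genome((1,) + tuple(s * g for s, g in zip(signs, perm)))
            if fixed_set and not fixed_set <= {
                tuple(sorted(e)) for e in adjacencies_of(cand)
            }:
                continue
            count += 1
            c = _total_cycles(cand, genomes)
            if c > best_cycles:
                best_cycles = c
                best = cand
    if best is None:
        raise MedianError("no candidate satisfies the fixed adjacencies")
    return MedianResult(
        median=best, score=3 * n - best_cycles, optimal=True,
        cycles=best_cycles, nodes=count,
    )
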