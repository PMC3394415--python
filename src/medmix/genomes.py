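"""Signed circular gene orders and their breakpoint-graph encoding.

A genome over the gene set {1..n} is a circular signed permutation.  Gene ``i``
contributes two extremity vertices: its *tail* ``2i - 1`` and its *head* ``2i``.
An adjacency is an unordered pair of extremities belonging to different genes;
the n adjacencies of a circular genome form a perfect matching on {1..2n}
(the genome's breakpoint graph).  The DCJ distance between two genomes on the
same gene set is ``n - c`` where ``c`` counts the alternating cycles in the
union of their matchings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

__all__ = [
    "Genome",
    "GenomeError",
    "MultiCycleError",
    "adjacencies_of",
    "genome_of",
    "matching_cycles",
    "apply_inversion",
    "count_cycles",
    "dcj_distance",
    "read_grappa",
    "write_grappa",
    "head",
    "tail",
]


class GenomeError(ValueError):
    """Raised for invalid gene orders or adjacency sets."""


class MultiCycleError(GenomeError):
    """A matching decomposed into more than one circular chromosome.

    Attributes
    ----------
    cycles : list of tuple of int
        The signed gene orders of the individual circles.
    """

    def __init__(self, cycles):
        self.cycles = cycles
        super().__init__(
            f"matching decomposes into {len(cycles)} circular chromosomes"
        )


def head(gene: int) -> int:
    """Head extremity of (unsigned) gene ``gene``."""
    return 2 * gene


def tail(gene: int) -> int:
    """Tail extremity of (unsigned) gene ``gene``."""
    return 2 * gene - 1


def _right_end(g: int) -> int:
    # extremity at the 3' side of a signed gene in reading direction
    return head(g) if g > 0 else tail(-g)


def _left_end(g: int) -> int:
    # extremity at the 5' side of a signed gene in reading direction
    return tail(g) if g > 0 else head(-g)


def _canonical(genes: Sequence[int]) -> tuple[int, ...]:
    genes = tuple(genes)
    k = next(i for i, g in enumerate(genes) if abs(g) == 1)
    rotated = genes[k:] + genes[:k]
    if rotated[0] == -1:
        rotated = tuple(-g for g in reversed(rotated))
        k = rotated.index(1)
        rotated = rotated[k:] + rotated[:k]
    return rotated


@dataclass(frozen=True)
class Genome:
    """A circular signed permutation of the genes {1..n}.

    Two genomes are equal when one is a rotation, or the reflected
    sign-flipped rotation, of the other; equality and hashing go through the
    canonical form (rotate gene 1 to the front, reading direction chosen so
    it appears as ``+1``).
    """

    genes: tuple[int, ...]
    name: str = ""

    def __post_init__(self) -> None:
        genes = tuple(int(g) for g in self.genes)
        object.__setattr__(self, "genes", genes)
        n = len(genes)
        if n == 0:
            raise GenomeError("empty genome")
        seen: set[int] = set()
        for g in genes:
            if g == 0:
                raise GenomeError("gene 0 is not allowed")
            if abs(g) in seen:
                raise GenomeError(f"duplicate gene {abs(g)}")
            seen.add(abs(g))
        if seen != set(range(1, n + 1)):
            missing = sorted(set(range(1, n + 1)) - seen)
            raise GenomeError(f"missing gene(s) {missing}")

    @property
    def n(self) -> int:
        return len(self.genes)

    def canonical(self) -> "Genome":
        return Genome(_canonical(self.genes), self.name)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Genome):
            return NotImplemented
        return _canonical(self.genes) == _canonical(other.genes)

    def __hash__(self) -> int:
        return hash(_canonical(self.genes))

    def __str__(self) -> str:
        return " ".join(str(g) for g in self.genes)


def adjacencies_of(genome: Genome) -> frozenset[tuple[int, int]]:
    """Breakpoint-graph edge set of a circular genome.

    Consecutive genes ``g, h`` (including the wrap from last to first)
    contribute the unordered extremity pair joining the right end of ``g``
    to the left end of ``h``:  ``i, j -> (2i, 2j-1)``; ``i, -j -> (2i, 2j)``;
    ``-i, j -> (2i-1, 2j-1)``; ``-i, -j -> (2i-1, 2j)``.
    """
    genes = genome.genes
    edges = []
    for k, g in enumerate(genes):
        h = genes[(k + 1) % len(genes)]
        u, v = _right_end(g), _left_end(h)
        edges.append((u, v) if u < v else (v, u))
    return frozenset(edges)


def matching_cycles(
    edges: Iterable[tuple[int, int]], n: int
) -> list[tuple[int, ...]]:
    """Decompose a perfect matching on {1..2n} into circular chromosomes.

    Returns the signed gene order of each circle.  Edges of the form
    ``(2i-1, 2i)`` are tolerated here (they yield a single-gene circle);
    :func:`genome_of` rejects the resulting multi-circle decompositions.
    """
    partner = {}
    for u, v in edges:
        if u == v:
            raise GenomeError(f"self-loop on vertex {u}")
        if u in partner or v in partner:
            raise GenomeError(f"vertex reused in matching: ({u}, {v})")
        partner[u] = v
        partner[v] = u
    if set(partner) != set(range(1, 2 * n + 1)):
        raise GenomeError("edges are not a perfect matching on {1..2n}")

    unused = set(range(1, n + 1))
    cycles: list[tuple[int, ...]] = []
    while unused:
        start = min(unused)
        order = []
        g = start  # enter gene `start` in forward orientation
        while True:
            order.append(g)
            unused.discard(abs(g))
            nxt = partner[_right_end(g)]
            if nxt % 2 == 1:  # tail of gene (nxt+1)//2 -> forward
                g = (nxt + 1) // 2
            else:  # head -> reversed
                g = -(nxt // 2)
            if abs(g) == start:
                break
        cycles.append(tuple(order))
    return cycles


def genome_of(
    edges: Iterable[tuple[int, int]], n: int, name: str = ""
) -> Genome:
    """Reconstruct the genome whose adjacency set is ``edges``.

    Inverse of :func:`adjacencies_of` on canonical forms.  Raises
    :class:`MultiCycleError` (carrying the decomposition) when the matching
    describes more than one circular chromosome.
    """
    cycles = matching_cycles(edges, n)
    if len(cycles) != 1:
        raise MultiCycleError(cycles)
    return Genome(_canonical(cycles[0]), name)


def apply_inversion(genome: Genome, i: int, j: int) -> Genome:
    """Invert positions ``i..j`` (1-based, inclusive) of the written order.

    The segment is reversed and every sign in it flipped:
    ``1,..,i-1, -j', -(j-1)', .., -i', j+1, .., n`` in position terms.
    """
    n = genome.n
    if not (1 <= i <= j <= n):
        raise GenomeError(f"inversion positions ({i}, {j}) out of range 1..{n}")
    g = list(genome.genes)
    g[i - 1 : j] = [-x for x in reversed(g[i - 1 : j])]
    return Genome(tuple(g), genome.name)


def count_cycles(
    match_a: Iterable[tuple[int, int]], match_b: Iterable[tuple[int, int]]
) -> int:
    """Number of alternating cycles in the union of two perfect matchings."""
    pa: dict[int, int] = {}
    pb: dict[int, int] = {}
    for store, edges in ((pa, match_a), (pb, match_b)):
        for u, v in edges:
            store[u] = v
            store[v] = u
    if set(pa) != set(pb):
        raise GenomeError("matchings are on different vertex sets")
    seen: set[int] = set()
    cycles = 0
    for start in pa:
        if start in seen:
            continue
        cycles += 1
        v = start
        use_a = True
        while True:
            seen.add(v)
            v = pa[v] if use_a else pb[v]
            use_a = not use_a
            if v == start and use_a:
                break
            seen.add(v)
    return cycles


def dcj_distance(a: Genome, b: Genome) -> int:
    """DCJ (cycle) distance ``n - c`` between genomes on the same gene set."""
    if a.n != b.n:
        raise GenomeError(f"gene sets differ: n={a.n} vs n={b.n}")
    return a.n - count_cycles(adjacencies_of(a), adjacencies_of(b))


# ---------------------------------------------------------------------------
# GRAPPA-style flat-file I/O: "> name" header lines, one whitespace-separated
# signed permutation per genome.  All genomes are circular in this package.

def read_grappa(path) -> list[Genome]:
    genomes: list[Genome] = []
    name = None
    buf: list[int] = []

    def flush() -> None:
        nonlocal name, buf
        if name is not None:
            if not buf:
                raise GenomeError(f"genome {name!r} has no genes")
            genomes.append(Genome(tuple(buf), name))
        name, buf = None, []

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].strip()
            else:
                buf.extend(int(tok) for tok in line.replace("@", "").split())
    flush()
    return genomes


def write_grappa(path, genomes: Iterable[Genome]) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.name}\n")
            fh.write(" ".join(str(x) for x in g.canonical().genes) + "\n")
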