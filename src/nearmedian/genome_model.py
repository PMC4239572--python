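"""Signed circular genomes as adjacency matchings.

A genome over ``n`` signed genes is modelled by the set of its gene
*adjacencies*: unordered pairs of gene extremities (the head and tail of
each gene) that are consecutive on a chromosome.  A fully circular genome
has exactly ``n`` adjacencies, which form a perfect matching on the ``2n``
gene ends.  The breakpoint distance between two such genomes is
``D = n - a`` where ``a`` is the number of adjacencies they share.

Only circular chromosomes are supported: every genome carries exactly
``n`` adjacencies and no telomeres.  Same-gene adjacencies
``{g.head, g.tail}`` are permitted and decode as single-gene circular
chromosomes.
"""

from __future__ import annotations

import re
from typing import Iterable, Iterator, NamedTuple, Sequence

HEAD = "h"
TAIL = "t"
_SIDES = (HEAD, TAIL)

_END_RE = re.compile(r"^(\d+)([hHtT])$")


class GenomeError(ValueError):
    """Raised for structurally invalid genomes or adjacency sets."""


class GeneEnd(NamedTuple):
    """One of the two extremities of a signed gene.

    Canonical total order is by gene id, then side, with head < tail
    (``"h" < "t"`` lexicographically), which the tuple order provides.
    """

    gene: int
    side: str

    def __str__(self) -> str:
        return f"{self.gene}{self.side}"

    @property
    def mate(self) -> "GeneEnd":
        """The opposite extremity of the same gene."""
        return GeneEnd(self.gene, TAIL if self.side == HEAD else HEAD)


def head(gene: int) -> GeneEnd:
    return GeneEnd(gene, HEAD)


def tail(gene: int) -> GeneEnd:
    return GeneEnd(gene, TAIL)


def parse_end(token: str) -> GeneEnd:
    """Parse an end token like ``"12h"`` (case-insensitive on the side)."""
    m = _END_RE.match(token.strip())
    if m is None:
        raise GenomeError(f"unparsable gene-end token {token!r}")
    return GeneEnd(int(m.group(1)), m.group(2).lower())


def all_ends(n: int) -> list[GeneEnd]:
    """The 2n gene ends of the universe 1..n, in canonical order."""
    return [GeneEnd(g, s) for g in range(1, n + 1) for s in _SIDES]


class _AdjacencyBase(NamedTuple):
    first: GeneEnd
    second: GeneEnd


class Adjacency(_AdjacencyBase):
    """An unordered pair of two distinct gene ends, stored canonically.

    Equality and hashing ignore the orientation of the pair: the lesser
    end (canonical order) is always stored first.
    """

    __slots__ = ()

    def __new__(cls, first, second):
        if not isinstance(first, GeneEnd):
            first = GeneEnd(*first)
        if not isinstance(second, GeneEnd):
            second = GeneEnd(*second)
        if first == second:
            raise GenomeError(f"adjacency requires two distinct ends, got {first} twice")
        if second < first:
            first, second = second, first
        return super().__new__(cls, first, second)

    def __str__(self) -> str:
        return f"{self.first}-{self.second}"

    @property
    def ends(self) -> tuple[GeneEnd, GeneEnd]:
        return (self.first, self.second)

    def other(self, end: GeneEnd) -> GeneEnd:
        if end == self.first:
            return self.second
        if end == self.second:
            return self.first
        raise GenomeError(f"end {end} not in adjacency {self}")


class AdjacencySet:
    """A compatible (end-disjoint) set of adjacencies over genes 1..n.

    Compatibility — no gene end occurring in more than one adjacency —
    is enforced on every insertion; a violating ``add`` raises
    :class:`GenomeError` and leaves the set unchanged.
    """

    __slots__ = ("n", "_by_end")

    def __init__(self, n: int, adjacencies: Iterable[Adjacency] = ()) -> None:
        if int(n) < 1:
            raise GenomeError(f"gene universe size must be >= 1, got {n}")
        self.n = int(n)
        self._by_end: dict[GeneEnd, Adjacency] = {}
        for adj in adjacencies:
            self.add(adj)

    def add(self, adj) -> None:
        if not isinstance(adj, Adjacency):
            adj = Adjacency(*adj)
        for end in adj.ends:
            if not (1 <= end.gene <= self.n) or end.side not in _SIDES:
                raise GenomeError(f"gene end {end} outside universe 1..{self.n}")
        for end in adj.ends:
            if end in self._by_end:
                raise GenomeError(f"gene end {end} already covered; cannot add {adj}")
        self._by_end[adj.first] = adj
        self._by_end[adj.second] = adj

    @property
    def adjacencies(self) -> frozenset[Adjacency]:
        return frozenset(self._by_end.values())

    def __len__(self) -> int:
        return len(self._by_end) // 2

    def __iter__(self) -> Iterator[Adjacency]:
        """Iterate in canonical (sorted) order."""
        return iter(sorted(set(self._by_end.values())))

    def __contains__(self, adj: Adjacency) -> bool:
        return self._by_end.get(adj.first) == adj

    def __eq__(self, other) -> bool:
        if not isinstance(other, AdjacencySet):
            return NotImplemented
        return self.n == other.n and self.adjacencies == other.adjacencies

    __hash__ = None  # mutable

    def __repr__(self) -> str:
        return f"{type(self).__name__}(n={self.n}, |adjacencies|={len(self)})"

    def covers(self, end: GeneEnd) -> bool:
        return end in self._by_end

    def adjacency_at(self, end: GeneEnd) -> Adjacency | None:
        return self._by_end.get(end)

    def free_ends(self) -> list[GeneEnd]:
        """All gene ends not covered by any adjacency, in canonical order."""
        return [e for e in all_ends(self.n) if e not in self._by_end]

    def copy(self) -> "AdjacencySet":
        fresh = AdjacencySet(self.n)
        fresh._by_end = dict(self._by_end)
        return fresh


class Genome(AdjacencySet):
    """A full genome: a perfect matching on all 2n gene ends.

    With exactly ``n`` adjacencies over ``n`` genes there are no telomeres,
    so the genome decomposes into circular chromosomes only.  Instances are
    immutable after construction.
    """

    __slots__ = ("label", "_frozen")

    def __init__(self, n: int, adjacencies: Iterable[Adjacency], label: str = "") -> None:
        self._frozen = False
        super().__init__(n, adjacencies)
        if len(self) != self.n:
            raise GenomeError(
                f"genome over {self.n} genes needs {self.n} adjacencies, got {len(self)}"
            )
        self.label = label
        self._frozen = True

    def add(self, adj) -> None:
        if getattr(self, "_frozen", False):
            raise GenomeError("genomes are immutable; copy to an AdjacencySet to edit")
        super().add(adj)

    def __repr__(self) -> str:
        return f"Genome(n={self.n}, label={self.label!r})"


def breakpoint_distance(a: Genome, b: Genome) -> int:
    """Breakpoint distance ``D = n - a`` with ``a`` the shared-adjacency count."""
    if a.n != b.n:
        raise GenomeError(f"incomparable gene universes: n={a.n} vs n={b.n}")
    return a.n - len(a.adjacencies & b.adjacencies)


def score(candidate: Genome, inputs: Sequence[Genome]) -> float:
    """Normalized distance sum ``(1/n) * sum_G D(candidate, G)`` over the inputs."""
    if not inputs:
        raise GenomeError("score requires at least one input genome")
    return sum(breakpoint_distance(candidate, g) for g in inputs) / candidate.n


def free_ends(partial: AdjacencySet) -> list[GeneEnd]:
    """Gene ends of the universe not covered by ``partial``, canonically ordered."""
    return partial.free_ends()


def chromosomes(g: Genome) -> list[list[int]]:
    """Decode a genome into its circular chromosomes as signed gene orders.

    Each cycle of the matching is reported in canonical form: rotated to
    start at its smallest gene id, with that gene oriented positively.
    """
    seen: set[int] = set()
    out: list[list[int]] = []
    for start in range(1, g.n + 1):
        if start in seen:
            continue
        chrom: list[int] = []
        gene, sign = start, 1
        while True:
            seen.add(gene)
            chrom.append(sign * gene)
            exit_end = head(gene) if sign > 0 else tail(gene)
            partner = g.adjacency_at(exit_end).other(exit_end)
            if partner.gene == start:
                break
            gene = partner.gene
            sign = 1 if partner.side == TAIL else -1
        out.append(chrom)
    return out


def _right_end(signed_gene: int) -> GeneEnd:
    return head(signed_gene) if signed_gene > 0 else tail(-signed_gene)


def _left_end(signed_gene: int) -> GeneEnd:
    return tail(signed_gene) if signed_gene > 0 else head(-signed_gene)


def genome_from_chromosomes(
    chroms: Sequence[Sequence[int]], n: int | None = None, label: str = ""
) -> Genome:
    """Inverse of :func:`chromosomes`: encode signed circular gene orders.

    Every chromosome is circular (the last gene wraps around to the first).
    Genes must be exactly 1..n, each appearing once across all chromosomes.
    """
    genes = [abs(g) for chrom in chroms for g in chrom]
    if n is None:
        n = len(genes)
    if sorted(genes) != list(range(1, n + 1)):
        raise GenomeError(
            f"chromosomes must contain each gene of 1..{n} exactly once, got {sorted(genes)}"
        )
    adjs = []
    for chrom in chroms:
        for prev, nxt in zip(chrom, list(chrom[1:]) + [chrom[0]]):
            adjs.append(Adjacency(_right_end(prev), _left_end(nxt)))
    return Genome(n, adjs, label=label)
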