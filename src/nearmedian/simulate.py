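"""Seeded genome simulators.

Two generative models are provided:

* :func:`random_genome` — a uniform draw over all ``(2n-1)!!`` perfect
  matchings on the 2n gene ends, the "random genome" null model.  Two
  independent draws share, in expectation, ``n/(2n-1)`` adjacencies —
  about one half, regardless of n.
* :func:`random_genomes_shared` — k genomes with a prescribed shared
  structure: a fraction ``psi`` of adjacencies common to all k, plus (for
  k = 3) pairwise fractions ``omega[i, j]`` shared by each pair and no
  third genome.  A compatible "core" of ``floor(psi * n)`` adjacencies is
  drawn first and placed in every genome, then the pairwise extras are
  drawn on ends free in both members of the pair, and finally each genome
  is completed independently by a uniform matching of its remaining free
  ends.  Realized sharing counts are therefore *at least* the prescribed
  counts; coincidental extra overlaps (O(1) in expectation) are not
  rejected, since rejection would bias the distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .genome_model import Adjacency, GenomeError, Genome, all_ends


@dataclass(frozen=True)
class SharingSpec:
    """Prescribed shared-adjacency structure for k simulated genomes.

    ``psi`` is the fraction of adjacencies shared by all k genomes;
    ``omega`` maps genome-index pairs (1-based, e.g. ``(1, 2)``) to the
    additional fraction shared by exactly that pair.  Pairwise sharing is
    supported for k = 3 only.  Counts are realized as ``floor(frac * n)``.
    """

    k: int = 3
    psi: float = 0.0
    omega: Mapping[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self):
        if self.k < 3:
            raise GenomeError(f"sharing spec needs k >= 3 genomes, got {self.k}")
        if not 0.0 <= self.psi <= 1.0:
            raise GenomeError(f"psi must lie in [0, 1], got {self.psi}")
        norm: dict[tuple[int, int], float] = {}
        for (i, j), v in dict(self.omega).items():
            if i == j or not (1 <= i <= self.k and 1 <= j <= self.k):
                raise GenomeError(f"invalid genome pair ({i}, {j}) for k={self.k}")
            if v < 0:
                raise GenomeError(f"omega[{i},{j}] must be >= 0, got {v}")
            key = (min(i, j), max(i, j))
            norm[key] = norm.get(key, 0.0) + v
        if norm and self.k != 3:
            raise GenomeError("pairwise omega sharing is unsupported for k != 3")
        object.__setattr__(self, "omega", norm)
        for i in range(1, self.k + 1):
            tot = self.psi + sum(v for (a, b), v in norm.items() if i in (a, b))
            if tot > 1.0 + 1e-12:
                raise GenomeError(
                    f"genome {i}: psi + its pairwise omegas = {tot:.4f} exceeds 1"
                )

    @property
    def omega_sum(self) -> float:
        """Total pairwise-shared fraction, summed over unordered pairs."""
        return sum(self.omega.values())


def _match_consecutive(ends, n: int) -> list[Adjacency]:
    return [Adjacency(ends[i], ends[i + 1]) for i in range(0, len(ends), 2)]


def random_genome(n: int, rng: np.random.Generator, label: str = "") -> Genome:
    """Uniform random genome: shuffle the 2n ends and pair consecutive entries."""
    if n < 1:
        raise GenomeError(f"n must be >= 1, got {n}")
    ends = all_ends(n)
    order = rng.permutation(2 * n)
    return Genome(n, _match_consecutive([ends[i] for i in order], n), label=label)


def random_genomes_shared(
    n: int, spec: SharingSpec, rng: np.random.Generator
) -> list[Genome]:
    """Draw k genomes with at least the sharing structure prescribed by ``spec``."""
    core_count = int(math.floor(spec.psi * n + 1e-9))
    pair_counts = {
        pair: int(math.floor(v * n + 1e-9)) for pair, v in sorted(spec.omega.items())
    }
    # The core and all pairwise extras must be realizable as end-disjoint
    # sets (each pair of extra-sets shares a genome in which both live,
    # hence they may not collide on any end).
    if core_count + sum(pair_counts.values()) > n:
        raise GenomeError(
            f"infeasible sharing spec: floor(psi*n) + sum floor(omega*n) = "
            f"{core_count + sum(pair_counts.values())} exceeds n = {n}"
        )
    ends = all_ends(n)
    used: list[set] = [set() for _ in range(spec.k)]
    shared: list[list[Adjacency]] = [[] for _ in range(spec.k)]

    order = [ends[i] for i in rng.permutation(2 * n)]
    core = _match_consecutive(order[: 2 * core_count], n)
    for i in range(spec.k):
        shared[i].extend(core)
        used[i].update(e for adj in core for e in adj.ends)

    for (i, j), count in pair_counts.items():
        if count == 0:
            continue
        a, b = i - 1, j - 1
        avail = [e for e in ends if e not in used[a] and e not in used[b]]
        order = rng.permutation(len(avail))
        extras = _match_consecutive([avail[x] for x in order[: 2 * count]], n)
        for idx in (a, b):
            shared[idx].extend(extras)
            used[idx].update(e for adj in extras for e in adj.ends)

    genomes = []
    for i in range(spec.k):
        free = [e for e in ends if e not in used[i]]
        order = rng.permutation(len(free))
        fill = _match_consecutive([free[x] for x in order], n)
        genomes.append(Genome(n, shared[i] + fill, label=f"G{i + 1}"))
    return genomes


def count_shared(a: Genome, b: Genome) -> int:
    """Number of adjacencies two genomes have in common (the ``a`` in ``D = n - a``)."""
    if a.n != b.n:
        raise GenomeError(f"incomparable gene universes: n={a.n} vs n={b.n}")
    return len(a.adjacencies & b.adjacencies)
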