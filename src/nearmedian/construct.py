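"""The two-stage near-median construction.

Stage 1 samples ``floor(theta * n)`` adjacencies from each of the k input
genomes in input order, always restricted to adjacencies whose two ends
are still free; adjacencies shared by two or more inputs may be included
outright beforehand.  The sampled set is then optionally enlarged by a
supplementary stage that collects every residual input adjacency with two
free ends and resolves conflicts among them by exact maximum matching.
Finally the remaining free ends are paired arbitrarily to reach a full
genome.  The result draws near-equally on every input and its normalized
score is bounded by ``k * (1 - theta)`` whenever stage 1 succeeds; the
supplementary stage lowers the k = 3 random-genome score from 2.25 to
about 2.13.

A brute-force breakpoint-median solver over all ``(2n-1)!!`` matchings is
included as a test oracle for tiny n.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np

from .genome_model import (
    AdjacencySet,
    Adjacency,
    GenomeError,
    Genome,
    all_ends,
    breakpoint_distance,
)
from .simulate import SharingSpec
from .theory import theta_max, theta_max_general, theta_max_shared


class Stage1Error(RuntimeError):
    """Stage-1 sampling found fewer two-free-end adjacencies than required."""

    def __init__(self, genome_index: int, needed: int, available: int):
        self.genome_index = genome_index
        self.needed = needed
        self.available = available
        super().__init__(
            f"genome {genome_index + 1}: needed {needed} two-free-end "
            f"adjacencies, only {available} available"
        )


class ConstructionError(RuntimeError):
    """Stage 1 remained infeasible after all retries and fallback is disabled."""


@dataclass
class ConstructionConfig:
    """Tunable knobs of :func:`near_median`.

    ``theta`` may be a fraction or ``"auto"``, in which case the maximal
    feasible value for the declared ``sharing`` structure is used (minus
    ``safety_margin``).  Sharing is never estimated from the data; see
    :func:`observed_sharing` for a descriptive helper.  On stage-1
    failure the construction retries with fresh derived seeds up to
    ``max_retries`` times, then (if ``fallback``) takes all available
    adjacencies for the deficient genome, recording the shortfall.
    """

    theta: float | str = "auto"
    safety_margin: float = 0.0
    supplement: bool = True
    shared_first: bool = True
    sharing: SharingSpec | None = None
    max_retries: int = 20
    fallback: bool = True
    seed: int = 0
    randomize_filler: bool = False


@dataclass
class Stage1Result:
    partial: AdjacencySet
    counts: list[int]
    shared_included: int
    shortfall: list[int]
    sources: dict


@dataclass
class ConstructionResult:
    """A constructed genome plus per-stage diagnostics."""

    genome: Genome
    theta_used: float
    stage1_counts: list[int]
    shared_included: int
    supplementary_candidates: int
    supplementary_added: int
    filler_added: int
    per_genome_distance: list[int]
    normalized_score: float
    seed: int
    retries: int = 0
    stage1_shortfall: list[int] = field(default_factory=list)

    @property
    def stage1_success(self) -> bool:
        """True when every genome contributed its full stage-1 quota."""
        return not any(self.stage1_shortfall)


def _validate_inputs(genomes: Sequence[Genome], k_min: int = 3) -> int:
    if len(genomes) < k_min:
        raise GenomeError(f"need at least {k_min} input genomes, got {len(genomes)}")
    ns = {g.n for g in genomes}
    if len(ns) != 1:
        raise GenomeError(f"input genomes disagree on n: {sorted(ns)}")
    return ns.pop()


def stage1_sample(
    genomes: Sequence[Genome],
    theta: float,
    rng: np.random.Generator,
    *,
    shared_first: bool = True,
    allow_shortfall: bool = False,
) -> Stage1Result:
    """Equal sampling of ``floor(theta*n)`` two-free-end adjacencies per genome.

    With ``shared_first``, every adjacency occurring in at least two
    inputs is placed into the partial set beforehand (mutually
    conflicting shared adjacencies — possible only through coincidental
    overlaps — are resolved first-come in canonical order).  A genome
    whose own adjacencies are already fully absorbed into the partial set
    owes correspondingly fewer samples; a genome that is merely *blocked*
    (fewer free candidates than owed) triggers :class:`Stage1Error`, or,
    with ``allow_shortfall``, contributes everything it has.
    """
    n = _validate_inputs(genomes)
    m = int(theta * n + 1e-9)
    partial = AdjacencySet(n)
    sources: dict[Adjacency, object] = {}
    shared_included = 0
    if shared_first:
        multiplicity: Counter = Counter()
        for g in genomes:
            multiplicity.update(g.adjacencies)
        for adj in sorted(a for a, c in multiplicity.items() if c >= 2):
            if not partial.covers(adj.first) and not partial.covers(adj.second):
                partial.add(adj)
                sources[adj] = "shared"
                shared_included += 1
    counts: list[int] = []
    shortfall: list[int] = []
    for idx, g in enumerate(genomes):
        remaining = [adj for adj in g if adj not in partial]
        target = min(m, len(remaining))
        candidates = [
            adj
            for adj in remaining
            if not partial.covers(adj.first) and not partial.covers(adj.second)
        ]
        if len(candidates) < target:
            if not allow_shortfall:
                raise Stage1Error(idx, target, len(candidates))
            chosen = candidates
        elif target == 0:
            chosen = []
        else:
            picked = rng.choice(len(candidates), size=target, replace=False)
            chosen = [candidates[i] for i in sorted(picked)]
        for adj in chosen:
            partial.add(adj)
            sources[adj] = idx
        counts.append(len(chosen))
        shortfall.append(target - len(chosen))
    return Stage1Result(partial, counts, shared_included, shortfall, sources)


def supplementary_sample(
    genomes: Sequence[Genome], current: AdjacencySet
) -> list[Adjacency]:
    """All residual input adjacencies whose two ends are free in ``current``.

    De-duplicated across genomes and returned in canonical order; the
    candidates may conflict with one another (share an end).
    """
    seen: set[Adjacency] = set()
    for g in genomes:
        for adj in g.adjacencies:
            if (
                adj not in seen
                and adj not in current
                and not current.covers(adj.first)
                and not current.covers(adj.second)
            ):
                seen.add(adj)
    return sorted(seen)


def max_compatible_subset(candidates: Sequence[Adjacency], n: int) -> AdjacencySet:
    """Maximum-cardinality compatible subset of conflicting candidates.

    Exact maximum matching (blossom algorithm) on the graph whose
    vertices are the involved gene ends and whose edges are the
    candidates — not a greedy approximation.
    """
    graph = nx.Graph()
    graph.add_edges_from((a.first, a.second) for a in sorted(set(candidates)))
    matching = nx.max_weight_matching(graph, maxcardinality=True)
    return AdjacencySet(n, (Adjacency(u, v) for u, v in matching))


def complete_genome(
    partial: AdjacencySet, rng: np.random.Generator | None = None, label: str = ""
) -> Genome:
    """Pair the free ends of a partial set into filler adjacencies.

    Deterministic by default (consecutive pairs in canonical end order)
    so that fixed seeds give bit-identical genomes; pass ``rng`` for a
    randomized pairing.
    """
    free = partial.free_ends()
    if rng is not None:
        free = [free[i] for i in rng.permutation(len(free))]
    filler = [Adjacency(free[i], free[i + 1]) for i in range(0, len(free), 2)]
    return Genome(partial.n, list(partial) + filler, label=label)


def _resolve_theta(config: ConstructionConfig, k: int) -> float:
    if config.theta == "auto":
        sharing = config.sharing
        if sharing is None:
            t = theta_max(k)
        else:
            if sharing.k != k:
                raise GenomeError(
                    f"sharing spec is for k={sharing.k} but {k} genomes were given"
                )
            if sharing.omega_sum > 0:
                t = theta_max_general(sharing.psi, sharing.omega_sum)
            else:
                t = theta_max_shared(k, sharing.psi)
        t = max(t - config.safety_margin, 0.0)
    else:
        t = float(config.theta)
        if not 0.0 <= t <= 0.5:
            raise GenomeError(f"theta must lie in [0, 0.5], got {t}")
    return t


def near_median(
    genomes: Sequence[Genome], config: ConstructionConfig | None = None
) -> ConstructionResult:
    """Build a near-median genome from k >= 3 inputs over the same genes."""
    config = config or ConstructionConfig()
    k = len(genomes)
    n = _validate_inputs(genomes)
    theta = _resolve_theta(config, k)

    # One derived child seed per attempt, plus one for the fallback pass
    # and one for an (optional) randomized filler.
    children = np.random.SeedSequence(config.seed).spawn(config.max_retries + 3)
    stage1 = None
    retries = 0
    for attempt in range(config.max_retries + 1):
        rng = np.random.default_rng(children[attempt])
        try:
            stage1 = stage1_sample(
                genomes, theta, rng, shared_first=config.shared_first
            )
            break
        except Stage1Error:
            retries += 1
    if stage1 is None:
        if not config.fallback:
            raise ConstructionError(
                f"stage 1 infeasible at theta={theta:.4f} after "
                f"{config.max_retries + 1} attempts"
            )
        rng = np.random.default_rng(children[config.max_retries + 1])
        stage1 = stage1_sample(
            genomes, theta, rng, shared_first=config.shared_first, allow_shortfall=True
        )

    partial = stage1.partial
    supplementary_candidates = 0
    supplementary_added = 0
    if config.supplement:
        candidates = supplementary_sample(genomes, partial)
        supplementary_candidates = len(candidates)
        for adj in max_compatible_subset(candidates, n):
            partial.add(adj)
            supplementary_added += 1

    filler_rng = (
        np.random.default_rng(children[config.max_retries + 2])
        if config.randomize_filler
        else None
    )
    before = len(partial)
    genome = complete_genome(partial, rng=filler_rng, label="near_median")
    distances = [breakpoint_distance(genome, g) for g in genomes]
    return ConstructionResult(
        genome=genome,
        theta_used=theta,
        stage1_counts=stage1.counts,
        shared_included=stage1.shared_included,
        supplementary_candidates=supplementary_candidates,
        supplementary_added=supplementary_added,
        filler_added=n - before,
        per_genome_distance=distances,
        normalized_score=sum(distances) / n,
        seed=config.seed,
        retries=retries,
        stage1_shortfall=stage1.shortfall,
    )


def observed_sharing(genomes: Sequence[Genome]) -> dict:
    """Descriptive shared-adjacency counts (all-k core and per-pair totals).

    A reporting helper only: the construction never estimates psi/omega
    from data, since observed counts conflate the two.
    """
    n = _validate_inputs(genomes)
    core = set(genomes[0].adjacencies)
    for g in genomes[1:]:
        core &= g.adjacencies
    pairs = {
        (i + 1, j + 1): len(genomes[i].adjacencies & genomes[j].adjacencies)
        for i in range(len(genomes))
        for j in range(i + 1, len(genomes))
    }
    return {"n": n, "all_shared": len(core), "pairwise_shared": pairs}


_DOUBLE_FACTORIAL_LIMIT = 7


def brute_force_median(genomes: Sequence[Genome]) -> tuple[Genome, float]:
    """Exact breakpoint median by enumerating all (2n-1)!! perfect matchings.

    A test oracle: refuses n > 7.  Ties are broken toward the
    canonically smallest matching.
    """
    n = _validate_inputs(genomes, k_min=1)
    if n > _DOUBLE_FACTORIAL_LIMIT:
        raise ValueError(
            f"brute-force median enumerates (2n-1)!! matchings; n={n} > "
            f"{_DOUBLE_FACTORIAL_LIMIT} refused"
        )
    ends = all_ends(n)
    two_n = 2 * n
    multiplicity: Counter = Counter()
    for g in genomes:
        multiplicity.update(g.adjacencies)
    weight = [[0] * two_n for _ in range(two_n)]
    for u in range(two_n):
        for v in range(u + 1, two_n):
            weight[u][v] = multiplicity.get(Adjacency(ends[u], ends[v]), 0)

    best_shared = -1
    best_pairs: tuple[tuple[int, int], ...] = ()
    used = [False] * two_n
    pairs: list[tuple[int, int]] = []

    def recurse(lo: int, shared: int) -> None:
        nonlocal best_shared, best_pairs
        u = lo
        while u < two_n and used[u]:
            u += 1
        if u == two_n:
            if shared > best_shared:  # first maximum found is lexicographically least
                best_shared = shared
                best_pairs = tuple(pairs)
            return
        used[u] = True
        row = weight[u]
        for v in range(u + 1, two_n):
            if used[v]:
                continue
            used[v] = True
            pairs.append((u, v))
            recurse(u + 1, shared + row[v])
            pairs.pop()
            used[v] = False
        used[u] = False

    recurse(0, 0)
    genome = Genome(
        n, (Adjacency(ends[u], ends[v]) for u, v in best_pairs), label="median"
    )
    return genome, (len(genomes) * n - best_shared) / n
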