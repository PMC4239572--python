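import itertools

import numpy as np
import pytest

from nearmedian import (
    Adjacency,
    AdjacencySet,
    ConstructionConfig,
    ConstructionError,
    GenomeError,
    SharingSpec,
    Stage1Error,
    brute_force_median,
    complete_genome,
    count_shared,
    head,
    max_compatible_subset,
    near_median,
    observed_sharing,
    random_genome,
    random_genomes_shared,
    score,
    stage1_sample,
    supplementary_sample,
    tail,
)
from nearmedian.construct import _validate_inputs


def _trio(n, seed):
    rng = np.random.default_rng(seed)
    return [random_genome(n, rng, label=f"G{i}") for i in range(3)]


class TestStage1:
    def test_identical_genomes_saturate_via_shared_stage(self, make_genome):
        g = make_genome([1, 2, 3, 4])
        result = stage1_sample([g, g, g], 0.25, np.random.default_rng(0))
        assert result.shared_included == 4
        assert result.counts == [0, 0, 0]
        assert result.shortfall == [0, 0, 0]
        assert result.partial.adjacencies == g.adjacencies

    def test_equal_quota_per_genome_on_success(self):
        genomes = _trio(1000, seed=3)
        for attempt in range(50):  # scan seeds for a feasible stage-1 draw
            try:
                result = stage1_sample(
                    genomes, 0.25, np.random.default_rng(attempt), shared_first=False
                )
                break
            except Stage1Error:
                continue
        assert result.counts == [250, 250, 250]
        assert len(result.partial) == 750
        assert set(result.sources.values()) == {0, 1, 2}

    def test_insufficient_candidates_raise_with_context(self, make_genome):
        # Genomes II and III are end-for-end conflicting with genome I's
        # sampled half, so a large theta must fail downstream.
        genomes = _trio(20, seed=0)
        with pytest.raises((Stage1Error,)) as info:
            for s in range(200):
                stage1_sample(genomes, 1 / 3, np.random.default_rng(s), shared_first=False)
        assert info.value.available < info.value.needed

    def test_success_frequency_tracks_normal_approximation(self):
        # At theta = theta* = 1/4 the predicted stage-1 success probability
        # is 0.4854 (n=1000); check the empirical rate at modest depth.
        runs, succ = 120, 0
        ss = np.random.SeedSequence(2026)
        for child in ss.spawn(runs):
            rng = np.random.default_rng(child)
            genomes = [random_genome(1000, rng) for _ in range(3)]
            try:
                stage1_sample(genomes, 0.25, rng, shared_first=False)
                succ += 1
            except Stage1Error:
                pass
        ci = 2.576 * np.sqrt(0.4854 * (1 - 0.4854) / runs)
        assert abs(succ / runs - 0.4854) < ci

    def test_fewer_than_three_genomes_rejected(self, rng):
        with pytest.raises(GenomeError, match="at least 3"):
            stage1_sample([random_genome(5, rng)] * 2, 0.25, rng)


class TestSupplementarySample:
    def test_full_genome_yields_no_candidates(self, make_genome):
        g = make_genome([1, 2, 3, 4])
        assert supplementary_sample([g, g, g], g.copy()) == []

    def test_single_residual_candidate_toy(self, make_genome):
        # A' covers genes 1-3; genome III holds {4h,4t}, untouched by A'.
        inputs = [
            make_genome([1, 2, 3, 4]),
            make_genome([1, -2, -3, 4]),
            make_genome([1, 2, 3], [4]),
        ]
        partial = AdjacencySet(
            4,
            [
                Adjacency(head(1), tail(2)),
                Adjacency(head(2), tail(3)),
                Adjacency(head(3), tail(1)),
            ],
        )
        assert supplementary_sample(inputs, partial) == [Adjacency(head(4), tail(4))]

    def test_candidate_volume_matches_expectation(self):
        # After a successful stage 1 the residual two-free-end supply is
        # about (31/192) n adjacencies.
        n, total, runs = 2000, 0.0, 8
        done = 0
        for s in range(100):
            genomes = _trio(n, seed=1000 + s)
            try:
                s1 = stage1_sample(
                    genomes, 0.25, np.random.default_rng(s), shared_first=False
                )
            except Stage1Error:
                continue
            total += len(supplementary_sample(genomes, s1.partial))
            done += 1
            if done == runs:
                break
        assert done == runs
        assert total / runs == pytest.approx(31 / 192 * n, rel=0.10)


def _max_compatible_by_enumeration(candidates):
    best = 0
    for r in range(len(candidates), 0, -1):
        for subset in itertools.combinations(candidates, r):
            ends = [e for adj in subset for e in adj.ends]
            if len(ends) == len(set(ends)):
                return r
    return best


class TestMaxCompatibleSubset:
    def test_path_conflict_selects_two(self):
        a, b, c, d = head(1), tail(1), head(2), tail(2)
        cands = [Adjacency(a, b), Adjacency(b, c), Adjacency(c, d)]
        assert len(max_compatible_subset(cands, 2)) == 2

    def test_empty_input(self):
        assert len(max_compatible_subset([], 4)) == 0

    def test_equals_exhaustive_enumeration(self):
        rng = np.random.default_rng(77)
        ends = [head(g) for g in range(1, 7)] + [tail(g) for g in range(1, 7)]
        for _ in range(200):
            m = int(rng.integers(1, 13))
            cands = set()
            while len(cands) < m:
                i, j = rng.choice(len(ends), size=2, replace=False)
                cands.add(Adjacency(ends[i], ends[j]))
            cands = sorted(cands)
            exact = _max_compatible_by_enumeration(cands)
            chosen = max_compatible_subset(cands, 6)
            assert len(chosen) == exact
            assert set(chosen.adjacencies) <= set(cands)


class TestCompleteGenome:
    def test_already_full_unchanged(self, make_genome):
        g = make_genome([1, 2, 3])
        assert complete_genome(g.copy()) == g

    def test_empty_partial_n2(self):
        g = complete_genome(AdjacencySet(2))
        assert len(g) == 2

    def test_always_perfect_matching(self, rng):
        for _ in range(20):
            partial = AdjacencySet(9)
            g = random_genome(9, rng)
            for adj in list(g)[:4]:
                partial.add(adj)
            assert len(complete_genome(partial)) == 9

    def test_deterministic_by_default_random_with_rng(self):
        partial = AdjacencySet(6)
        a = complete_genome(partial)
        b = complete_genome(partial)
        assert a == b
        c = complete_genome(partial, rng=np.random.default_rng(1))
        assert len(c) == 6


class TestNearMedian:
    def test_reproducible_for_fixed_seed(self):
        genomes = _trio(200, seed=5)
        cfg = ConstructionConfig(seed=17)
        r1, r2 = near_median(genomes, cfg), near_median(genomes, cfg)
        assert r1.genome == r2.genome
        assert r1.normalized_score == r2.normalized_score
        assert r1.stage1_counts == r2.stage1_counts

    def test_diagnostic_counts_sum_to_n(self):
        genomes = _trio(500, seed=8)
        res = near_median(genomes, ConstructionConfig(seed=1))
        assert (
            res.shared_included
            + sum(res.stage1_counts)
            + res.supplementary_added
            + res.filler_added
            == 500
        )
        assert res.normalized_score == pytest.approx(
            sum(res.per_genome_distance) / 500
        )

    def test_score_bounded_without_supplement_on_success(self):
        genomes = _trio(1000, seed=12)
        res = near_median(
            genomes,
            ConstructionConfig(theta=0.25, supplement=False, shared_first=False, seed=2),
        )
        if res.stage1_success:
            assert res.normalized_score <= 2.25 + 3 / 1000

    def test_supplement_only_adds_input_adjacencies(self):
        genomes = _trio(600, seed=21)
        off = near_median(
            genomes, ConstructionConfig(supplement=False, seed=4, theta=0.25)
        )
        on = near_median(genomes, ConstructionConfig(supplement=True, seed=4, theta=0.25))
        pool = set().union(*(g.adjacencies for g in genomes))
        extra = on.genome.adjacencies - off.genome.adjacencies
        # the supplementary additions (stage-1 part is seed-identical) all
        # come from the input genomes
        stage1_adjs = off.genome.adjacencies & on.genome.adjacencies
        added = [a for a in extra if a in pool]
        assert on.supplementary_added > 0
        assert len(added) >= on.supplementary_added
        assert on.normalized_score <= off.normalized_score

    def test_auto_theta_uses_sharing_spec(self):
        spec = SharingSpec(k=3, psi=0.625)
        genomes = random_genomes_shared(400, spec, np.random.default_rng(3))
        res = near_median(genomes, ConstructionConfig(sharing=spec, seed=0))
        assert res.theta_used == pytest.approx(0.0625)
        assert res.normalized_score <= 0.9375 + 3 / 400

    def test_sharing_spec_k_mismatch_rejected(self, rng):
        genomes = [random_genome(30, rng) for _ in range(4)]
        with pytest.raises(GenomeError, match="k=3"):
            near_median(genomes, ConstructionConfig(sharing=SharingSpec(k=3)))

    def test_strict_mode_raises_when_infeasible(self):
        # trio seed 31 / config seed 0 is a deterministic stage-1 failure
        # at theta = theta* (the critical point, where failure has
        # probability ~1/2 per attempt).
        genomes = _trio(300, seed=31)
        with pytest.raises(ConstructionError, match="infeasible"):
            near_median(
                genomes,
                ConstructionConfig(
                    theta=0.25, fallback=False, max_retries=0, shared_first=False,
                    seed=0, supplement=False,
                ),
            )

    def test_fallback_records_shortfall_and_completes(self):
        genomes = _trio(300, seed=31)
        res = near_median(
            genomes,
            ConstructionConfig(
                theta=0.25, max_retries=0, shared_first=False, seed=0, supplement=False
            ),
        )
        assert len(res.genome) == 300
        assert not res.stage1_success
        assert res.retries == 1
        assert sum(res.stage1_shortfall) > 0
        assert (
            sum(res.stage1_counts) + res.filler_added + res.shared_included == 300
        )

    def test_mismatched_universes_rejected(self, rng):
        genomes = [random_genome(5, rng), random_genome(5, rng), random_genome(6, rng)]
        with pytest.raises(GenomeError, match="disagree"):
            near_median(genomes)


class TestObservedSharing:
    def test_reports_core_and_pairwise_counts(self, make_genome):
        g = make_genome([1, 2, 3, 4])
        rep = observed_sharing([g, g, g])
        assert rep["all_shared"] == 4
        assert rep["pairwise_shared"] == {(1, 2): 4, (1, 3): 4, (2, 3): 4}


class TestBruteForceMedian:
    def test_identical_trio_is_its_own_median(self, make_genome):
        g = make_genome([1, 2, 3])
        median, value = brute_force_median([g, g, g])
        assert median == g and value == 0.0

    def test_repeated_genome_wins_at_n2(self, make_genome):
        a = make_genome([1, 2])
        b = make_genome([1, -2])
        median, value = brute_force_median([a, a, b])
        assert median == a
        assert value == pytest.approx(
            (2 * 0 + (2 - count_shared(a, b))) / 2
        )

    def test_refuses_large_n(self, rng):
        with pytest.raises(ValueError, match="n=8"):
            brute_force_median([random_genome(8, rng) for _ in range(3)])

    def test_never_beaten_by_construction(self):
        rng = np.random.default_rng(404)
        for trial in range(25):
            n = int(rng.integers(4, 8))
            genomes = [random_genome(n, rng) for _ in range(3)]
            _, opt = brute_force_median(genomes)
            res = near_median(genomes, ConstructionConfig(seed=trial))
            assert res.normalized_score >= opt - 1e-12
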