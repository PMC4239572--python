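# Methods

## Model

A genome is a signed circular gene order over genes `1..n`, represented by
its adjacency set: a perfect matching on the `2n` gene extremities
(`g.head`, `g.tail`). The model is circular-only — exactly `n` adjacencies,
no telomeres — because the linear/circular and uni-/multichromosomal
variants differ only at `o(n)` and the circular encoding keeps every
operation a statement about matchings. Same-gene adjacencies
`{g.head, g.tail}` are permitted (they decode as single-gene circular
chromosomes): the space of adjacencies is all `C(2n, 2)` end pairs, and a
uniform random genome is a uniform perfect matching over all `(2n−1)!!`
of them. Excluding self-adjacencies would change expectations only at
`o(1)`; a uniform matching over all pairs is the cleaner null model and is
what the closed forms below assume.

Breakpoint distance is `D(A, B) = n − |adj(A) ∩ adj(B)|`. It is symmetric,
zero on identical genomes, and bounded by `n`; no triangle inequality is
asserted or used. The score of a candidate genome against inputs
`G_1..G_k` is `(1/n) Σ_i D(candidate, G_i)`.

## The two-stage construction

**Stage 1.** Process the inputs in their given order. For each genome, the
candidate pool is its adjacencies not already in the partial set `A′` and
with both ends free; `m = ⌊θn⌋` of them are drawn uniformly without
replacement. Within one genome all candidates are mutually compatible (a
genome is itself a matching), so a per-genome draw never conflicts with
itself. The floor means the realized bound is `k − k⌊θn⌋/n ≤ k(1−θ) + k/n`;
tests and the acceptance checks allow exactly this `k/n` slack.

With `shared_first` (the default), every adjacency occurring in ≥ 2 inputs
is placed into `A′` beforehand. Shared adjacencies arising from a declared
sharing structure are mutually compatible; coincidental overlaps between
random genomes (O(1) of them) may conflict, in which case they are admitted
first-come in canonical order. A genome whose own adjacencies are already
absorbed into `A′` owes correspondingly fewer stage-1 samples (its quota is
`min(m, #adjacencies not yet in A′)`): this makes degenerate inputs such as
k identical genomes well-defined — the shared stage saturates `A′` and no
sampling is required — without masking genuine infeasibility, which is a
*blocked* genome (fewer two-free-end candidates than owed).

**Failure policy.** At `θ = θ*` stage 1 succeeds with probability only
≈ 0.49 (see the phase change below), so failure is an expected event, not
an error. The construction retries with fresh derived seeds up to
`max_retries` (default 20) times; if every attempt fails it falls back to
taking all available candidates for the deficient genome and records the
shortfall in the diagnostics. The fallback pass also draws a fresh seed, so
it doubles as one final retry before degrading; a fallback pass that
happens to meet the quota is reported as a clean success. θ-backoff was
rejected as the default because it silently changes the advertised bound;
callers who want hard failure set `fallback=False` (CLI `--strict`,
exit 3).

**Stage 2.** The supplementary scan collects, across *all* k inputs, every
adjacency not in `A′` with both ends free, de-duplicated. For k = 3 theory
predicts `(31/192)n ≈ 0.161n` such candidates from genomes I and II and
none from genome III in expectation; scanning genome III as well is a
superset of that procedure — at finite n genome III retains a few
(≈ 10 at n = 1000, the positive part of its binomial surplus), which can
only lower the score. Conflicts among candidates (shared ends) are resolved
exactly: the candidates are edges of a graph on the free ends, and a
maximum-cardinality matching (blossom algorithm, via networkx, on instances
of only ~0.16n edges) gives the largest compatible subset. Simulation at
n = 1000 keeps ≈ 3/4 of the candidates, reproducing the reported mean score
of ≈ 2.13 against the stage-1 guarantee of 2.25.

**Completion.** Remaining free ends are paired consecutively in canonical
order — deterministic, so a fixed seed yields a bit-identical genome; a
randomized pairing is available behind a flag. Filler adjacencies
generally belong to no input and contribute `k` to the distance sum each,
which is what the score bound already assumes.

## Closed forms

With `s = ψ + Σ_{i≠j} ω_{i,j}` the total declared shared fraction:

| quantity | expression |
|---|---|
| `theta_max(k)` | `(2k−1−√(4k−3)) / (2(k−1)²)`, root of `(1−(k−1)θ)² = θ` |
| `score_bound(k)` | `k(1−θ*)` → `k−1` |
| `theta_max_shared(k, ψ)` | `(2k+2ψ−2kψ−1−√(4(k+ψ−kψ)−3)) / (2(k−1)²)` |
| `score_bound_shared(k, ψ)` | `k(1−(θ*+ψ))` |
| `median_score_shared(k, ψ)` | `(k−1)(1−ψ)` |
| `theta_max_general(ψ, Σω)` (k=3) | `(5−4s−√(9−8s))/8` = `theta_max_shared(3, s)` |

`theta_max_general` is the root of `4θ² + θ(4s−5) + (1−s)² = 0`; a test
asserts this residual at 1e−12. All shared-case forms reduce to the random
case at `s = 0` (asserted to 1e−12).

**Success probabilities.** The two-free-end count in the last genome is
modelled as `X ~ Binomial(n, p_θ)` with `p_θ = (1−2θ)²` (k = 3). The exact
success probability is the upper tail `P(X ≥ ⌈θn⌉)` (integer threshold,
computed by `scipy.stats.binom.sf` and cross-checked against term-by-term
summation to 1e−12 for n ≤ 30). The normal approximation uses
`Z = (θn + 0.5 − np_θ)/√(np_θ(1−p_θ))` and reports `1 − Φ(Z)`, with two
deliberate conventions: the continuity correction enters as **+0.5**, and
the required count `m = θn` is left **real-valued**. This pair of choices
reproduces the published 4-decimal probability grid across n = 5..10000 and
θ = 0.10..1/3 (two grid cells are internally inconsistent with the defining
formula under every correction convention and are frozen in the tests at
the formula's value). Degenerate variances (θ = 0) return the appropriate
0/1 limit. The grid exhibits the phase change at θ* = 1/4: success
probability → 1 for θ < 1/4, → 0 for θ > 1/4, and ≈ 0.49 at θ = 1/4.

The binomial is itself an approximation — the true count is a statistic of
a random matching with slightly dependent trials — and empirically the
stage-1 success rate at θ = 1/4, n = 1000 runs a little above the predicted
0.4854 (≈ 0.52 over 400 runs), well within the sampling tolerance the
validation tests use.

## Simulators

`random_genome` shuffles the 2n ends and pairs consecutive entries —
uniform over matchings, O(n). `random_genomes_shared` realizes a sharing
specification (ψ, ω) by: (1) drawing a core of `⌊ψn⌋` adjacencies placed in
every genome; (2) for each pair (i, j), drawing `⌊ω_{i,j}n⌋` further
adjacencies on ends free in both members; (3) completing each genome
independently with a uniform matching of its own free ends. Fractions are
floored, matching the integer counts the theory manipulates. The scheme
guarantees *at least* the prescribed sharing; coincidental extra overlap
(O(1) in expectation) is not rejected, because rejection sampling would
bias the marginal distribution. Feasibility requires the core and all
pairwise extras to be end-disjoint, i.e. `⌊ψn⌋ + Σ_pairs ⌊ωn⌋ ≤ n` — this
total condition is strictly stronger than the per-genome budget
`ψ + ω_{i,j} + ω_{i,h} ≤ 1` (e.g. ψ = 0, all ω = 0.5 satisfies every
per-genome budget yet is unrealizable), and mirrors the stronger constraint
`θ + ψ + Σω ≤ 1` the theory itself imposes. Pairwise ω is supported for
k = 3 only, exactly the case the closed forms cover.

What the simulators do *not* emulate: real genomes evolve by inversions,
translocations and losses along a tree, producing correlated, clustered
adjacency sharing and unequal genome sizes; the generators here produce
exchangeable, uniformly scattered sharing with a fixed gene universe.
Passing tests therefore validate the construction and its combinatorial
theory under the stated null models — not rearrangement-realism.

## Problem sizes and numerical choices

Validation runs use the sizes the theory's own tables address: n = 1000
constructions (200 basic runs for the bound and success frequency, 50
successful runs for the supplemented mean score, 50 shared-structure runs),
n = 100 × 2000 pairs for the shared-adjacency constant, and n = 2000 for
the candidate-supply check; the whole suite completes in well under a
minute of simulation time. The brute-force median oracle enumerates all
`(2n−1)!!` matchings with incremental shared counts and refuses n > 7
(135135 matchings); ties break toward the canonically smallest matching,
which the lexicographic enumeration yields for free. Statistical assertions
use wide, pre-stated windows (99% binomial CI for the success frequency;
4 standard errors for means; ±10% for the candidate supply; the `k/n` floor
slack on score bounds). Canonical ordering of ends (gene, then head < tail)
makes every iteration, sampling pool, matching input and written file
deterministic for a fixed seed.

## Limitations

- The score guarantee is conditional on stage-1 success; after the
  take-all fallback only the diagnostics (recorded shortfall), not the
  bound, describe the result.
- `theta = "auto"` trusts the declared sharing specification; it is never
  estimated from the data, since observed counts conflate ψ and ω
  (`observed_sharing` reports raw counts for the user to judge).
- The exact median value of random genomes (k−1) is a reference constant
  here, not a computed quantity, except at n ≤ 7 via the brute-force
  oracle.
- Unsigned genomes, linear chromosomes, unequal gene content and other
  distances (DCJ, inversion) are out of scope.
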