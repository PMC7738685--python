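# Methods

## Problem and scores

The package models driver-pathway discovery as an optimization problem
over a PPI network `G = (V, E)` and per-gene mutated-sample sets `S_g`.
A module `M` is scored by `MS(M) = COV(M) × MEX(M)`, where coverage is the
fraction of all covered cohort samples hit by the module and mutual
exclusivity is the union-over-sum ratio of its per-gene sample sets
(1 exactly when no sample carries two module mutations). The product form
makes the two goals multiplicative: a module can only score highly by
being good at both. The objective over a module set, `ODMSS`, is the plain
sum of per-module scores, so modules contribute independently and shared
genes are rewarded once per module that uses them — this is what allows
(but does not force) overlapping output.

Constraints on a solution set: induced connectivity of every module,
pairwise distinctness, per-module minimum size `δ_m`, and summed size
exactly `δ_s` (the *sum* over modules, so overlaps effectively relax the
unique-gene budget).

**Coverage denominator.** The universe `V` is fixed once per run as the
network genes that survive the mutation-frequency filter; its covered-
sample union is cached as one integer. Genes present in mutation data but
absent from the network therefore do not dilute COV, and genes in a module
but missing from the profile contribute empty sets (scoring arbitrary
reference pathways with the same code path stays legal). Genes absent from
the filtered profile can seed nothing; an all-empty module has undefined
MEX and is treated as score 0 only inside the exact solver, where
zero-score padding may be needed to hit `δ_s` exactly.

## Greedy discovery

Seeds are the filtered genes ranked by `MS(N_e(g))`, the score of the
closed neighborhood — a measure of immediate growth potential. Ties break
by descending mutation count, then lexicographically, so rankings are
deterministic across processes.

Growth from a seed alternates between the best single-gene addition from
the candidate set `CS(M)` and the best legal removal, committing whichever
strictly improves `MS(M)` more (ties go to addition, biasing toward
coverage). `CS(M)` admits a neighbor `g` of `M` when

1. `|∪_{k∈M∪{g}} S_k| / Σ_{k∈M} |S_k| > t` — the enlarged union, relative
   to the current sum of set sizes, must exceed `t`; equivalently the new
   coverage must exceed `t ×` (old coverage / old exclusivity); and
2. `deg(g, M) / mean_deg(g) > 1/d` — `g` must be at least `1/d` times as
   connected to `M` as it is, on average, to the modules that already
   contain it.

Genes belonging to no earlier module pass rule 2 vacuously: the rule
exists to throttle reuse of already-placed genes, and a fresh gene has
nothing to compare against. Membership in earlier modules is explicitly
*not* disqualifying — that is the mechanism of overlap.

Design choices where the procedure is underdetermined:

* **Tied maximizers.** All candidates tied for the best single-gene
  `MS(M ∪ {g})` are added in one step (the addition variant is their
  union); removals mirror this. Candidates are evaluated in sorted order,
  with an absolute tie tolerance of 1e-15.
* **Seed anchoring.** The seed is never removable, and a removal that
  would disconnect the module is not a legal variant; if a tied removal
  group would jointly disconnect the module, only its first gene is
  removed. These conservative rules keep every intermediate module
  connected and anchored.
* **Monotone termination.** Committed steps strictly increase MS, which
  bounds the loop (finitely many reachable modules); the property is
  asserted at runtime, not assumed.
* **Budget stop.** Modules below `δ_m` or duplicating an earlier module
  are discarded with their seed consumed. Construction stops once summed
  sizes reach `δ_s`; the final module is kept whole, so the total may
  overshoot by at most `|last| − 1`. Truncating it instead would break the
  no-improving-move fixed point. Module sizes are not hard-capped at
  `2δ_m − 1`: `t` regulates size with more flexibility.

**Growth dynamics worth knowing.** When a module's genes are perfectly
exclusive, rule 1's left side is `1 + new/union`, which exceeds 1 whenever
the candidate brings any new sample — so at `t ≤ 1` nothing brakes growth
and a module expands to its whole connected mutated component. Larger `t`
demands proportionally larger coverage gains and halts growth near the
natural pathway boundary. This is why `t` controls module size, why `d`
(which only matters once genes belong to earlier modules) controls
overlap only in the regime where `t` brakes, and why the automatic ODMSS
search tends to select `t > 1` on structured data.

## (t, d) selection

`optimize_params` evaluates complete discovery runs at points of the
`t × d` box and returns the evaluated point maximizing ODMSS. The default
strategy is a compact Bayesian optimizer written against scikit-learn: a
Matérn-5/2 Gaussian-process surrogate on inputs scaled to the unit box,
expected-improvement acquisition maximized over 256 seeded uniform
candidates, one third of the 30-evaluation budget spent on seeded random
initialization. Failed evaluations score −∞ (and enter the surrogate at
one below the worst finite value). A deterministic grid strategy with the
same interface exists for exhaustive small searches. Both are pure
functions of `rng_seed`; two runs with the same seed produce byte-identical
output files.

## Exact solver

For small instances the optimum is computable: enumerate every induced
connected subgraph with size in a window (node-anchored extension — each
subgraph is generated exactly once from its smallest vertex; a configurable
cap, default 10⁶ entries, guards against misuse on large networks), then
run a 0/1 knapsack DP `c[i][j] = max(c[i−1][j], c[i−1][j−|M_i|] + MS(M_i))`
with exact capacity `δ_s`, unreachable cells marked infeasible, and
backpointer reconstruction. Each distinct gene set is usable at most once,
which makes the distinctness constraint automatic. Infeasibility is a
typed return value, not an exception (the CLI maps it to exit code 3).

The default window `[δ_m, 2δ_m)` rests on a structural property: an
optimum solution generally needs no module of size `≥ 2δ_m`, because such
a module could be split into in-window connected pieces without losing
score. `verify_lemma_window` checks this empirically by solving with and
without the window. **Known limitation:** the property is not universal —
splitting an oversized module can collide with the distinctness
constraint when a fragment duplicates another module already in the
optimum. A frozen counterexample lives in `tests/test_exact.py`; in random
7–8-node instances the windowed and unwindowed optima disagree in roughly
1% of cases. Analyses that need the guaranteed optimum should pass
`enforce_lemma_window=False` (CLI `--no-lemma-window`).

## Evaluation measures

Similarity between a predicted module and a reference pathway is one of:
overlap score `|M ∩ R|² / (|M||R|)`; `−log10` of the Benjamini–Hochberg
q-value of the one-sided (upper-tail) hypergeometric enrichment test,
zeroed when `q > 0.05` (the boundary `q = 0.05` is kept significant;
q-values underflowing to 0 are clamped to the smallest positive double
before the log); or the Jaccard similarity of level-standardized GO term
unions. BH correction pools all module × pathway tests into a single
family. The hypergeometric universe defaults to the analyzed network's
gene set and is configurable; reference pathways are intersected with the
universe before testing.

**GO standardization.** Term depth is the length of the *shortest* `is_a`
path to the namespace root (`part_of` edges are ignored); terms at the
target level are kept, deeper terms are replaced by all their ancestors at
that level, shallower and obsolete or unknown terms are dropped. Shortest-
path depth and all-namespace usage are our conventions; the operation is
idempotent at a fixed level.

**Matching.** The module–pathway bipartite graph is complete — zero-weight
edges included — and the maximum-weight maximum-cardinality matching is
computed by `scipy`'s rectangular linear-sum assignment (the test suite
cross-checks it against permutation enumeration). MMR divides the matched
weight by the matching cardinality `min(#modules, #pathways)`; dropping
zero edges first would let one perfect module among `k` score 1.0 instead
of the honest `1/k`. Best-match tables give per-module row maxima
(precision side) and per-pathway column maxima (recall side); F1 is the
*product* of the two averages, not a harmonic mean.

**Gene-level ROC.** Modules are accumulated in rank order until the
unique-gene count first reaches each cutoff; TPR and FPR are computed
against a reference driver list restricted to a declared background. A
cutoff beyond the available genes yields a point at the achievable maximum
with a warning.

## Synthetic benchmark

The generator plants `n_modules` connected modules (random spanning tree
plus Bernoulli(`p_in`) densification; background pairs wired at `p_bg`)
and gives each a dedicated block of cohort samples, every block sample
mutating exactly one module gene chosen uniformly. Pre-noise, each planted
module therefore has MEX exactly 1 and coverage equal to its block's share
of covered samples — closed forms the scoring tests exploit. Passenger
mutations are independent Bernoulli(`passenger_rate`) over all gene ×
sample pairs. Everything is a pure function of the seed.

Default conditions: 60 genes, 300 samples, 5 planted modules of 4–6 genes,
disjoint blocks of 60 samples (covering the cohort), `p_in = 0.8`,
`p_bg = 0.02`, 1% passenger rate. Planted modules are disjoint by default;
`overlap_genes = k` makes consecutive modules share exactly `k` genes.
The `noiseless` variant (passengers and background edges zeroed) isolates
the planted structure: there, each planted module is its own connected
component and discovery at `(t = 1, d = 3)` recovers it exactly. The
planted-clique family (two disjoint 3-cliques among 10 genes, 40 samples)
is small enough for the exact solver and anchors the greedy-vs-optimal
quality guard (ratio ≥ 0.8, observed 1.0).

Benchmark regimes used by the test suite, chosen from the growth-dynamics
analysis above: the overlap-recovery check plants one shared gene, pins
`d = 5`, and lets the method's own ODMSS maximization pick `t` over
[0.8, 1.2] (a 5-point grid); the size-vs-`t` tendency is measured at
`d = 3` and the overlap-vs-`d` tendency at `t = 1.2`, the braking regime
in which `d` can matter at all.

What passing these benchmarks does *not* show: real cohorts have
heterogeneous mutation rates, hypermutators, copy-number events and
far-from-perfect exclusivity, and real interactomes have hubs and degree
bias that the Bernoulli background does not emulate. The benchmarks
validate the machinery (scores, admission rules, solvers, matching), not
clinical performance.

## Numerical conventions

All scores in double precision; test equalities use absolute tolerance
1e-12 (1e-9 for solver comparisons). Strict inequalities follow the
definitions exactly: the confidence filter drops edges with confidence
`< threshold`, the frequency filter drops genes with `|S_g| <
fraction × cohort`, admission rule 1 and MS improvements are strict.
Problem sizes throughout (60-gene benchmarks, ≤ 8-node exact instances,
10-seed batteries) were chosen so the full suite and the acceptance script
run in seconds while still exercising every code path.
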