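"""Seed ranking, candidate admission, greedy growth and the (t,d) search."""

import itertools

import pytest

from driveways.discovery import (
    DriveWaysParams,
    build_module_set,
    candidate_set,
    grow_module,
    optimize_params,
    rank_seeds,
)
from driveways.errors import DriveWaysError
from driveways.io_formats import MutationProfile, PPINetwork
from driveways.scoring import Module, ModuleScorer, ModuleSet
from driveways.synthetic import (
    default_benchmark_spec,
    generate,
    planted_clique_spec,
)

P = DriveWaysParams


class TestRankSeeds:
    def test_star_hub_with_disjoint_leaves_ranks_first(self):
        net = PPINetwork.from_edges([("h", f"l{i}") for i in range(1, 5)])
        prof = MutationProfile(
            {"h": {"s0"}, **{f"l{i}": {f"s{i}"} for i in range(1, 5)}},
            {f"s{i}" for i in range(5)},
        )
        ranking = rank_seeds(net, prof, P(delta_s=3))
        assert ranking.entries[0] == ("h", pytest.approx(1.0))
        assert len(ranking) == 5

    def test_isolated_gene_scores_its_own_coverage(self):
        net = PPINetwork.from_edges([("a", "b")])
        net.graph.add_node("g")
        prof = MutationProfile(
            {
                "g": {"s0"},
                "a": {f"s{i}" for i in range(1, 6)},
                "b": {f"s{i}" for i in range(6, 10)},
            },
            {f"s{i}" for i in range(10)},
        )
        scores = dict(rank_seeds(net, prof, P(delta_s=3)).entries)
        assert scores["g"] == pytest.approx(0.1)

    def test_equal_scores_break_ties_deterministically(self):
        net = PPINetwork.from_edges([("a", "x"), ("b", "y")])
        prof = MutationProfile(
            {"a": {"s1"}, "b": {"s2"}, "x": {"s3"}, "y": {"s4"}},
            {"s1", "s2", "s3", "s4"},
        )
        first = rank_seeds(net, prof, P(delta_s=3))
        for _ in range(3):
            assert rank_seeds(net, prof, P(delta_s=3)).entries == first.entries
        # all extended neighborhoods score identically -> lexicographic order
        assert [g for g, _ in first.entries] == ["a", "b", "x", "y"]

    def test_disjoint_network_and_profile_is_an_error(self):
        net = PPINetwork.from_edges([("a", "b")])
        prof = MutationProfile({"z": {"s1"}}, {"s1"})
        with pytest.raises(DriveWaysError):
            rank_seeds(net, prof, P(delta_s=3))


class TestCandidateSet:
    def _setting(self, s_c):
        net = PPINetwork.from_edges([("a", "b"), ("b", "c")])
        prof = MutationProfile(
            {"a": {"s1"}, "b": {"s2"}, "c": set(s_c)}, {"s1", "s2", "s3"}
        )
        return net, prof

    def test_coverage_gain_admits_neighbor(self):
        net, prof = self._setting({"s3"})
        cs = candidate_set(
            frozenset({"a", "b"}), ModuleSet([]), net, prof, P(t=1.0, delta_s=3)
        )
        assert cs == {"c"}  # LHS = 3/2 > 1

    def test_boundary_is_strict(self):
        net, prof = self._setting({"s1"})
        cs = candidate_set(
            frozenset({"a", "b"}), ModuleSet([]), net, prof, P(t=1.0, delta_s=3)
        )
        assert cs == frozenset()  # LHS = 2/2, not > 1

    def test_gene_in_no_prior_module_passes_connectivity_vacuously(self):
        # candidate 'c' has degree 1 into M; with no prior module holding c,
        # rule (2) cannot fire regardless of d
        net, prof = self._setting({"s3"})
        cs = candidate_set(
            frozenset({"a", "b"}), ModuleSet([]), net, prof,
            P(t=1.0, d=0.0001, delta_s=3),
        )
        assert "c" in cs

    def test_gene_in_prior_module_must_be_relatively_well_connected(self):
        # c sits in a prior module where it had 2 neighbors; toward M it has 1
        net = PPINetwork.from_edges(
            [("a", "b"), ("b", "c"), ("c", "x"), ("c", "y"), ("x", "y")]
        )
        prof = MutationProfile(
            {g: {f"s_{g}"} for g in "abcxy"}, {f"s_{g}" for g in "abcxy"}
        )
        prior = ModuleSet([Module({"c", "x", "y"})])
        # deg(c, M)=1, mean_deg(c)=2 -> ratio 0.5: admitted iff 1/d < 0.5
        admitted = candidate_set(
            frozenset({"a", "b"}), prior, net, prof, P(t=0.5, d=3.0, delta_s=3)
        )
        rejected = candidate_set(
            frozenset({"a", "b"}), prior, net, prof, P(t=0.5, d=1.5, delta_s=3)
        )
        assert "c" in admitted and "c" not in rejected


class TestGrowModule:
    def test_triangle_grows_to_full_module(self, triangle):
        net, prof = triangle
        module = grow_module("a", ModuleSet([]), net, prof, P(t=1.0, d=3.0, delta_s=3))
        assert module.genes == {"a", "b", "c"}
        # exhaustive check: no connected superset/subset scores better
        scorer = ModuleScorer(prof, net.nodes)
        best = max(
            scorer.ms(set(combo))
            for r in (1, 2, 3)
            for combo in itertools.combinations("abc", r)
            if net.is_connected_subset(set(combo))
        )
        assert scorer.ms(module.genes) == pytest.approx(best)

    def test_redundant_neighbor_is_never_added(self):
        net = PPINetwork.from_edges([("a", "b")])
        prof = MutationProfile({"a": {"s1"}, "b": {"s1"}}, {"s1"})
        module = grow_module("a", ModuleSet([]), net, prof, P(t=0.5, d=3.0, delta_s=3))
        assert module.genes == {"a"}

    def test_removal_can_win_and_ms_rises_monotonically(self):
        # b carries a huge overlapping set: growth may pass through b, but
        # the final module must beat every intermediate MS
        net = PPINetwork.from_edges([("a", "b"), ("b", "c"), ("a", "c")])
        prof = MutationProfile(
            {
                "a": {"s1", "s2"},
                "b": {"s1", "s2", "s3", "s4", "s5"},
                "c": {"s3", "s4"},
            },
            {f"s{i}" for i in range(1, 6)},
        )
        scorer = ModuleScorer(prof, net.nodes)
        module = grow_module("a", ModuleSet([]), net, prof, P(t=0.1, d=5.0, delta_s=3))
        assert scorer.ms(module.genes) >= scorer.ms({"a"})

    def test_module_always_contains_its_seed(self, triangle):
        net, prof = triangle
        for seed in "abc":
            m = grow_module(seed, ModuleSet([]), net, prof, P(delta_s=3))
            assert seed in m.genes and m.seed == seed


class TestBuildModuleSet:
    def test_delta_s_equal_to_first_module_stops_after_one(self, triangle):
        net, prof = triangle
        modules, scores = build_module_set(net, prof, P(t=1.0, d=3.0, delta_m=3, delta_s=3))
        assert len(modules) == 1 and modules[0].genes == {"a", "b", "c"}
        assert scores[0].ms == pytest.approx(1.0)

    def test_two_disjoint_planted_cliques_recovered_exactly(self):
        from driveways.exact import solve_exact

        spec = planted_clique_spec(3)
        net, prof, truth = generate(spec)
        params = P(t=1.0, d=3.0, delta_m=3, delta_s=truth.total_size(), min_mut_fraction=0.0)
        modules, scores = build_module_set(net, prof, params)
        assert {m.genes for m in modules} == set(truth.modules)
        exact = solve_exact(net, prof, 3, truth.total_size(),
                            universe_genes=net.nodes & prof.genes)
        assert sum(s.ms for s in scores) == pytest.approx(exact.odmss)

    def test_overlapping_planted_modules_reuse_hub_gene(self):
        spec = default_benchmark_spec(2, noiseless=True)
        spec.overlap_genes = 1
        net, prof, truth = generate(spec)
        params = P(t=1.2, d=5.0, delta_m=truth.min_size(),
                   delta_s=truth.total_size(), min_mut_fraction=0.0)
        modules, _ = build_module_set(net, prof, params)
        counts = {}
        for m in modules:
            for g in m.genes:
                counts[g] = counts.get(g, 0) + 1
        assert any(c >= 2 for c in counts.values())

    def test_output_satisfies_all_structural_constraints(self):
        spec = default_benchmark_spec(5)  # noisy default conditions
        net, prof, truth = generate(spec)
        params = P(t=1.0, d=3.0, delta_m=3, delta_s=truth.total_size(), min_mut_fraction=0.01)
        from driveways.io_formats import filter_low_frequency_genes

        prof = filter_low_frequency_genes(prof, params.min_mut_fraction)
        modules, _ = build_module_set(net, prof, params)
        seen = set()
        for m in modules:
            assert len(m) >= params.delta_m
            assert net.is_connected_subset(m.genes)
            assert m.seed in m.genes
            assert m.genes not in seen
            seen.add(m.genes)
        total = modules.total_size()
        assert params.delta_s <= total <= params.delta_s + len(modules[-1]) - 1


class TestOptimizeParams:
    def test_degenerate_grid_equals_fixed_run(self, triangle):
        net, prof = triangle
        base = P(t=1.0, d=3.0, delta_m=3, delta_s=3, optimizer="search",
                 search_strategy="grid", n_evaluations=1,
                 t_range=(1.0, 1.0), d_range=(3.0, 3.0))
        best, modules, _ = optimize_params(net, prof, base)
        fixed_modules, _ = build_module_set(net, prof, P(t=1.0, d=3.0, delta_m=3, delta_s=3))
        assert (best.t, best.d) == (1.0, 3.0)
        assert [m.genes for m in modules] == [m.genes for m in fixed_modules]

    def test_returned_odmss_is_argmax_over_evaluated_grid(self):
        spec = default_benchmark_spec(1, noiseless=True)
        spec.overlap_genes = 1
        net, prof, truth = generate(spec)
        base = P(delta_m=truth.min_size(), delta_s=truth.total_size(),
                 min_mut_fraction=0.0, optimizer="search", search_strategy="grid",
                 n_evaluations=9, rng_seed=0)
        best, modules, breakdowns = optimize_params(net, prof, base)
        got = sum(sb.ms for sb in breakdowns)
        scorer = ModuleScorer(prof, net.nodes & prof.genes)
        for t in (base.t_range[0] + (base.t_range[1] - base.t_range[0]) / 2,):
            for d in (base.d_range[0] + (base.d_range[1] - base.d_range[0]) / 2,):
                mid, _ = build_module_set(
                    net, prof,
                    P(t=t, d=d, delta_m=base.delta_m, delta_s=base.delta_s,
                      min_mut_fraction=0.0),
                )
                assert got >= scorer.odmss(mid) - 1e-9

    def test_same_seed_gives_identical_search_outcome(self):
        spec = default_benchmark_spec(4)
        net, prof, truth = generate(spec)
        base = P(delta_m=3, delta_s=truth.total_size(), min_mut_fraction=0.0,
                 optimizer="search", search_strategy="bayes",
                 n_evaluations=8, rng_seed=11)
        r1 = optimize_params(net, prof, base)
        r2 = optimize_params(net, prof, base)
        assert (r1[0].t, r1[0].d) == (r2[0].t, r2[0].d)
        assert [m.genes for m in r1[1]] == [m.genes for m in r2[1]]
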