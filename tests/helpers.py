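"""Independent brute-force oracles shared by unit and acceptance tests.

These deliberately avoid the package's own algorithms: connectivity is
checked by naive subset traversal, the module-set optimum by exhaustive
combination search, matchings by permutation enumeration, and
hypergeometric tails by literally enumerating draws.
"""

import itertools
import random

import networkx as nx

from driveways.io_formats import MutationProfile, PPINetwork


def random_instance(seed, n_nodes=7, p_edge=0.35, n_samples=8, max_muts=4):
    """A seeded random network + profile; every gene carries >=1 mutation."""
    rng = random.Random(seed)
    g = nx.gnp_random_graph(n_nodes, p_edge, seed=seed)
    net = PPINetwork.from_edges([(f"g{a}", f"g{b}") for a, b in g.edges])
    net.graph.add_nodes_from(f"g{i}" for i in range(n_nodes))
    samples = [f"s{i}" for i in range(n_samples)]
    prof = MutationProfile(
        {
            f"g{i}": frozenset(rng.sample(samples, rng.randint(1, max_muts)))
            for i in range(n_nodes)
        },
        frozenset(samples),
    )
    return net, prof


def naive_connected_subsets(net: PPINetwork, min_size, max_size):
    """All connected vertex subsets by powerset + traversal check."""
    nodes = sorted(net.nodes)
    out = []
    for r in range(min_size, max_size + 1):
        for combo in itertools.combinations(nodes, r):
            sub = set(combo)
            # breadth-first traversal from one vertex, restricted to sub
            start = combo[0]
            seen = {start}
            frontier = [start]
            while frontier:
                v = frontier.pop()
                for w in net.graph.neighbors(v):
                    if w in sub and w not in seen:
                        seen.add(w)
                        frontier.append(w)
            if seen == sub:
                out.append(frozenset(sub))
    return out


def brute_force_ms(genes, profile: MutationProfile, universe):
    """MS by direct set arithmetic; 0 when no gene is mutated."""
    union = set()
    total = 0
    for g in genes:
        s = profile.sample_set(g)
        union |= s
        total += len(s)
    denom = set()
    for g in universe:
        denom |= profile.sample_set(g)
    if total == 0:
        return 0.0
    return (len(union) / len(denom)) * (len(union) / total)


def brute_force_optimum(net, profile, delta_m, delta_s):
    """Best ODMSS over all sets of distinct connected modules with sizes in
    [delta_m, delta_s] summing exactly to delta_s; None if infeasible."""
    subs = naive_connected_subsets(net, delta_m, delta_s)
    scored = [(s, brute_force_ms(s, profile, net.nodes)) for s in subs]
    best = [None]

    def recurse(i, total, value):
        if total == delta_s:
            if best[0] is None or value > best[0]:
                best[0] = value
            return
        if i >= len(scored) or total > delta_s:
            return
        recurse(i + 1, total, value)
        genes, ms = scored[i]
        if total + len(genes) <= delta_s:
            recurse(i + 1, total + len(genes), value + ms)

    recurse(0, 0, 0.0)
    return best[0]


def brute_force_matching(values):
    """Max total weight over all injections of the smaller side into the
    larger, by explicit permutation enumeration (matrices up to ~7x7)."""
    n_rows, n_cols = len(values), len(values[0])
    transposed = n_rows > n_cols
    if transposed:
        values = [list(col) for col in zip(*values)]
        n_rows, n_cols = n_cols, n_rows
    best = None
    for perm in itertools.permutations(range(n_cols), n_rows):
        w = sum(values[i][perm[i]] for i in range(n_rows))
        if best is None or w > best:
            best = w
    return best


def hypergeom_tail_by_enumeration(N, K, n, k):
    """P[|draw & successes| >= k] by enumerating all C(N, n) draws."""
    universe = list(range(N))
    successes = set(range(K))
    hits = 0
    total = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        if len(successes.intersection(draw)) >= k:
            hits += 1
    return hits / total
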