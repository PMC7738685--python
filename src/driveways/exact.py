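"""Exact pseudo-polynomial solver for small instances.

The size-constrained module-set problem (maximize ODMSS over possibly
overlapping connected modules with per-module minimum size delta_m and
summed size exactly delta_s) admits an exact solution on small networks:
enumerate every induced connected subgraph in an allowed size window, then
run a 0/1-knapsack dynamic program over the enumeration, where each
subgraph is an item of weight |M| and value MS(M), usable at most once
(which makes module uniqueness automatic) and the capacity delta_s must be
met exactly.

A structural fact about optima justifies restricting the window to
[delta_m, 2*delta_m): some optimum solution uses only modules strictly
smaller than 2*delta_m.  :func:`verify_lemma_window` checks this property
empirically on a given instance by solving with and without the window.

This module is the ground-truth oracle for the greedy heuristic on small
instances; it is not meant for genome-scale networks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

from .errors import ConfigurationError, ResourceLimitError
from .io_formats import MutationProfile, PPINetwork
from .scoring import Module, ModuleScorer, ModuleSet

logger = logging.getLogger("driveways")

__all__ = [
    "SubgraphCatalog",
    "ExactResult",
    "LemmaWindowReport",
    "enumerate_connected_subgraphs",
    "solve_exact",
    "verify_lemma_window",
]

_DEFAULT_CATALOG_CAP = 10**6


@dataclass
class SubgraphCatalog:
    """All induced connected subgraphs of a network within a size window."""

    entries: list  # list of frozensets, each inducing a connected subgraph
    size_window: tuple  # (min_size, max_size), inclusive

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class ExactResult:
    """Outcome of the exact solver; infeasibility is a value, not an error."""

    feasible: bool
    modules: Optional[ModuleSet]
    odmss: Optional[float]


@dataclass
class LemmaWindowReport:
    windowed: ExactResult
    unwindowed: ExactResult

    @property
    def agree(self) -> bool:
        if self.windowed.feasible != self.unwindowed.feasible:
            return False
        if not self.windowed.feasible:
            return True
        return abs(self.windowed.odmss - self.unwindowed.odmss) <= 1e-9


def enumerate_connected_subgraphs(
    network: PPINetwork,
    min_size: int,
    max_size: int,
    cap: int = _DEFAULT_CATALOG_CAP,
) -> SubgraphCatalog:
    """Enumerate every vertex set of size in [min_size, max_size] whose
    induced subgraph is connected, each exactly once.

    Uses node-anchored extension: a set is generated only from its
    smallest vertex (in sorted order), extending with strictly larger
    vertices, so no duplicates arise.
    """
    if not 1 <= min_size <= max_size:
        raise ConfigurationError(
            f"need 1 <= min_size <= max_size, got [{min_size}, {max_size}]"
        )
    order = {g: i for i, g in enumerate(sorted(network.nodes))}
    adj = {g: set(network.neighbors(g)) for g in network.nodes}
    entries: list = []

    def extend(subset: set, frontier: set, banned: set, anchor_rank: int):
        if len(subset) >= min_size:
            entries.append(frozenset(subset))
            if len(entries) > cap:
                raise ResourceLimitError(
                    f"connected-subgraph catalog exceeds cap {cap}; "
                    "use a smaller instance or size window"
                )
        if len(subset) == max_size:
            return
        # visit frontier vertices in deterministic order; each vertex is
        # either taken now or banned for the rest of this branch
        local_banned = set(banned)
        for v in sorted(frontier, key=order.get):
            if order[v] <= anchor_rank or v in local_banned:
                continue
            new_frontier = (frontier | adj[v]) - subset - {v} - local_banned
            subset.add(v)
            extend(subset, new_frontier, local_banned, anchor_rank)
            subset.remove(v)
            local_banned.add(v)

    for g in sorted(network.nodes, key=order.get):
        extend({g}, set(adj[g]), set(), order[g])
    return SubgraphCatalog(entries=entries, size_window=(min_size, max_size))


def solve_exact(
    network: PPINetwork,
    profile: MutationProfile,
    delta_m: int,
    delta_s: int,
    enforce_lemma_window: bool = True,
    universe_genes=None,
) -> ExactResult:
    """Maximize ODMSS over module sets with total size exactly delta_s.

    Modules are drawn from the catalog of induced connected subgraphs with
    sizes in [delta_m, 2*delta_m) (or [delta_m, delta_s] when the window is
    disabled); each distinct gene set is usable at most once.  The knapsack
    DP is c[i][j] = max(c[i-1][j], c[i-1][j - |M_i|] + MS(M_i)) with exact
    capacity, infeasible cells marked None.
    """
    if delta_s < delta_m:
        return ExactResult(feasible=False, modules=None, odmss=None)
    if enforce_lemma_window:
        max_size = min(2 * delta_m - 1, delta_s)
    else:
        max_size = delta_s
    catalog = enumerate_connected_subgraphs(network, delta_m, max_size)
    universe = frozenset(universe_genes) if universe_genes is not None else network.nodes
    scorer = ModuleScorer(profile, universe)

    def safe_ms(genes) -> float:
        try:
            return scorer.ms(genes)
        except Exception:
            return 0.0  # no mutated gene: zero-score but still legal padding

    scored = [(e, safe_ms(e)) for e in catalog.entries]

    # c[j] over items processed so far; None marks an unreachable total size
    prev = [None] * (delta_s + 1)
    prev[0] = 0.0
    choice = []  # choice[i][j] True if item i is taken in the best fill of j
    for genes, ms in scored:
        w = len(genes)
        cur = list(prev)
        taken = [False] * (delta_s + 1)
        for j in range(w, delta_s + 1):
            if prev[j - w] is None:
                continue
            cand = prev[j - w] + ms
            if cur[j] is None or cand > cur[j]:
                cur[j] = cand
                taken[j] = True
        choice.append(taken)
        prev = cur
    if prev[delta_s] is None:
        return ExactResult(feasible=False, modules=None, odmss=None)

    # reconstruct
    modules = ModuleSet()
    j = delta_s
    for i in range(len(scored) - 1, -1, -1):
        if choice[i][j]:
            genes, _ = scored[i]
            modules.append(Module(genes))
            j -= len(genes)
    modules.modules.reverse()
    return ExactResult(feasible=True, modules=modules, odmss=prev[delta_s])


def verify_lemma_window(
    network: PPINetwork,
    profile: MutationProfile,
    delta_m: int,
    delta_s: int,
    universe_genes=None,
) -> LemmaWindowReport:
    """Solve with the [delta_m, 2*delta_m) window and without it; a correct
    implementation and the structural optimum property make the two optima
    agree on every feasible instance."""
    win = solve_exact(
        network, profile, delta_m, delta_s,
        enforce_lemma_window=True, universe_genes=universe_genes,
    )
    full = solve_exact(
        network, profile, delta_m, delta_s,
        enforce_lemma_window=False, universe_genes=universe_genes,
    )
    return LemmaWindowReport(windowed=win, unwindowed=full)
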