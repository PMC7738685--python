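"""Seeded generator of PPI networks and mutation profiles with planted,
possibly overlapping, mutually exclusive driver modules.

The generator emulates the statistical structure the method assumes:
modules are connected gene groups whose members are mutated in disjoint
patients.  Each planted module receives a dedicated, pairwise-disjoint
block of cohort samples; every sample of a block is mutated in exactly one
module gene chosen uniformly, so before noise MEX of each planted module
is exactly 1 and its coverage is its block share of the covered cohort.
Consecutive modules share a configurable number of genes, planting the
overlap structure the discovery step should recover.  Connectivity inside
a module is guaranteed by a random spanning tree before Bernoulli(p_in)
densification; gene pairs not inside a common module are wired with the
background probability p_bg.  Passenger noise adds independent
Bernoulli(passenger_rate) mutations over all gene/sample pairs.
Everything is a pure function of the rng seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .io_formats import MutationProfile, PPINetwork
from .scoring import ModuleSet, pairwise_overlap

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate",
    "recovery_score",
    "default_benchmark_spec",
    "planted_clique_spec",
]


@dataclass
class SyntheticSpec:
    """Study conditions of the synthetic benchmark.

    Defaults describe the standard benchmark: 5 disjoint planted modules
    of 4-6 genes among 60 genes, 300 samples split into per-module blocks
    of 60, module edges at 0.8, background edges at 0.02 and a 1%
    passenger mutation rate.  Setting ``overlap_genes`` > 0 makes
    consecutive planted modules share that many genes.
    """

    n_genes: int = 60
    n_samples: int = 300
    n_modules: int = 5
    module_size_range: tuple = (4, 6)
    overlap_genes: int = 0
    p_in: float = 0.8
    p_bg: float = 0.02
    samples_per_module: int = 60
    passenger_rate: float = 0.01
    rng_seed: int = 0

    def validate(self) -> None:
        lo, hi = self.module_size_range
        if not 1 <= lo <= hi:
            raise ConfigurationError("invalid module size range")
        if not self.p_in > self.p_bg:
            raise ConfigurationError("p_in must exceed p_bg")
        if self.overlap_genes >= lo:
            raise ConfigurationError("overlap_genes must be < min module size")
        if self.n_modules * self.samples_per_module > self.n_samples:
            raise ConfigurationError("sample blocks exceed the cohort size")
        # worst case every module takes hi fresh genes minus planted overlap
        worst = self.n_modules * hi - (self.n_modules - 1) * self.overlap_genes
        if worst > self.n_genes:
            raise ConfigurationError(
                f"n_genes={self.n_genes} cannot hold up to {worst} planted genes"
            )


@dataclass
class GroundTruth:
    """The planted modules and their disjoint sample blocks."""

    modules: list  # list of frozensets of genes
    sample_blocks: list  # list of frozensets of samples

    def as_module_set(self) -> ModuleSet:
        return ModuleSet(list(self.modules))

    def total_size(self) -> int:
        return sum(len(m) for m in self.modules)

    def min_size(self) -> int:
        return min(len(m) for m in self.modules)


def generate(spec: SyntheticSpec):
    """Build (PPINetwork, MutationProfile, GroundTruth) from a spec.

    Deterministic given ``spec.rng_seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    width = max(4, len(str(spec.n_genes)))
    genes = [f"G{i:0{width}d}" for i in range(spec.n_genes)]
    swidth = max(4, len(str(spec.n_samples)))
    samples = [f"S{i:0{swidth}d}" for i in range(spec.n_samples)]

    lo, hi = spec.module_size_range
    sizes = [int(rng.integers(lo, hi + 1)) for _ in range(spec.n_modules)]

    # allocate planted genes; consecutive modules share overlap_genes genes
    planted: list = []
    cursor = 0
    for i, size in enumerate(sizes):
        members: list = []
        if i > 0 and spec.overlap_genes:
            shared = rng.choice(
                sorted(planted[i - 1]), size=spec.overlap_genes, replace=False
            )
            members.extend(str(s) for s in shared)
        fresh = size - len(members)
        members.extend(genes[cursor:cursor + fresh])
        cursor += fresh
        planted.append(frozenset(members))

    # edges: spanning tree + Bernoulli(p_in) inside modules
    edges: set = set()

    def add_edge(a, b):
        if a != b:
            edges.add((a, b) if a < b else (b, a))

    for members in planted:
        order = sorted(members)  # fixed order before shuffling: rng-only layout
        rng.shuffle(order)
        for j in range(1, len(order)):
            add_edge(order[j], order[int(rng.integers(0, j))])
        for j in range(len(order)):
            for k in range(j + 1, len(order)):
                if rng.random() < spec.p_in:
                    add_edge(order[j], order[k])

    in_common_module = set(edges)  # tree+dense edges are all intra-module
    if spec.p_bg > 0:
        for j in range(spec.n_genes):
            for k in range(j + 1, spec.n_genes):
                pair = (genes[j], genes[k])
                if pair in in_common_module:
                    continue
                if any(genes[j] in m and genes[k] in m for m in planted):
                    continue
                if rng.random() < spec.p_bg:
                    add_edge(*pair)

    graph_nodes = set(genes)
    network = PPINetwork.from_edges(sorted(edges))
    network.graph.add_nodes_from(sorted(graph_nodes))

    # mutations: disjoint sample blocks, one module gene per block sample
    samples_by_gene: dict = {}
    blocks: list = []
    pos = 0
    for members in planted:
        block = samples[pos:pos + spec.samples_per_module]
        pos += spec.samples_per_module
        blocks.append(frozenset(block))
        ordered = sorted(members)
        for s in block:
            g = ordered[int(rng.integers(0, len(ordered)))]
            samples_by_gene.setdefault(g, set()).add(s)

    if spec.passenger_rate > 0:
        noise = rng.random((spec.n_genes, spec.n_samples)) < spec.passenger_rate
        for j, g in enumerate(genes):
            hit = np.nonzero(noise[j])[0]
            if hit.size:
                samples_by_gene.setdefault(g, set()).update(
                    samples[i] for i in hit
                )

    profile = MutationProfile(samples_by_gene, frozenset(samples))
    return network, profile, GroundTruth(modules=planted, sample_blocks=blocks)


def recovery_score(found: ModuleSet, truth: GroundTruth) -> float:
    """Mean over planted modules of the best overlap score against any
    found module; 1 means every planted module was recovered exactly."""
    if not len(found) or not truth.modules:
        raise ConfigurationError("recovery_score needs non-empty inputs")
    total = 0.0
    for planted in truth.modules:
        total += max(pairwise_overlap(planted, m.genes) for m in found)
    return total / len(truth.modules)


def default_benchmark_spec(seed: int = 0, noiseless: bool = False) -> SyntheticSpec:
    """The standard benchmark; ``noiseless`` zeroes passengers and
    background edges for closed-form checks."""
    spec = SyntheticSpec(rng_seed=seed)
    if noiseless:
        spec.passenger_rate = 0.0
        spec.p_bg = 0.0
    return spec


def planted_clique_spec(seed: int = 0) -> SyntheticSpec:
    """A small noiseless instance with two planted disjoint cliques,
    small enough for the exact solver to serve as ground truth."""
    return SyntheticSpec(
        n_genes=10,
        n_samples=40,
        n_modules=2,
        module_size_range=(3, 3),
        overlap_genes=0,
        p_in=1.0,
        p_bg=0.0,
        samples_per_module=20,
        passenger_rate=0.0,
        rng_seed=seed,
    )
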