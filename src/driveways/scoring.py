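"""Module scoring: coverage, mutual exclusivity, and their product.

The central objects of the method live here.  A *module* M is a gene set
(usually inducing a connected subgraph of the PPI network).  Its quality is
measured against a cohort mutation profile by

    COV(M) = |union_{g in M} S_g| / |union_{g in V} S_g|
    MEX(M) = |union_{g in M} S_g| / sum_{g in M} |S_g|
    MS(M)  = COV(M) * MEX(M)

where S_g is the set of samples in which gene g is mutated and V is the gene
universe fixed for the analysis (the mutated genes of the network under
study).  Coverage rewards modules perturbed in many patients; mutual
exclusivity rewards modules whose genes hit disjoint patients, the classic
signature of genes acting in one pathway.  The objective over a module set D
is additive: ODMSS(D) = sum_{M in D} MS(M).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from .errors import DriveWaysError

__all__ = [
    "Module",
    "ModuleSet",
    "ScoreBreakdown",
    "ModuleScorer",
    "coverage",
    "mutual_exclusivity",
    "module_score",
    "odmss",
    "pairwise_overlap",
    "average_pairwise_overlap",
]


@dataclass(frozen=True)
class Module:
    """A gene set, optionally remembering the seed it was grown from."""

    genes: frozenset
    seed: Optional[str] = None

    def __post_init__(self):
        object.__setattr__(self, "genes", frozenset(self.genes))
        if not self.genes:
            raise DriveWaysError("a module must contain at least one gene")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def sorted_genes(self) -> list:
        return sorted(self.genes)


@dataclass
class ModuleSet:
    """An ordered collection of modules; order is rank/construction order."""

    modules: list = field(default_factory=list)

    def __post_init__(self):
        self.modules = [
            m if isinstance(m, Module) else Module(frozenset(m)) for m in self.modules
        ]

    def __iter__(self) -> Iterator[Module]:
        return iter(self.modules)

    def __len__(self) -> int:
        return len(self.modules)

    def __getitem__(self, i):
        return self.modules[i]

    def append(self, module: Module) -> None:
        self.modules.append(module)

    def total_size(self) -> int:
        return sum(len(m) for m in self.modules)

    def gene_union(self) -> frozenset:
        out = set()
        for m in self.modules:
            out |= m.genes
        return frozenset(out)

    def gene_sets(self) -> list:
        return [m.genes for m in self.modules]


@dataclass(frozen=True)
class ScoreBreakdown:
    """COV, MEX and their product MS for one module."""

    cov: float
    mex: float
    ms: float


def _union_and_sum(genes: Iterable[str], profile) -> tuple[frozenset, int]:
    union = set()
    total = 0
    for g in genes:
        s = profile.sample_set(g)
        union |= s
        total += len(s)
    return frozenset(union), total


def coverage(module, profile, universe_genes) -> float:
    """Fraction of all covered cohort samples hit by the module.

    ``universe_genes`` fixes the denominator: the union of mutated-sample
    sets over every gene of the analysis universe V.  Genes missing from the
    profile contribute empty sets.
    """
    genes = module.genes if isinstance(module, Module) else module
    denom_union, _ = _union_and_sum(universe_genes, profile)
    if not denom_union:
        raise DriveWaysError("coverage undefined: no gene in the universe is mutated")
    num_union, _ = _union_and_sum(genes, profile)
    return len(num_union) / len(denom_union)


def mutual_exclusivity(module, profile) -> float:
    """Union-over-sum ratio of the per-gene mutated-sample sets.

    Equals 1 exactly when no sample is mutated in two module genes.
    """
    genes = module.genes if isinstance(module, Module) else module
    union, total = _union_and_sum(genes, profile)
    if total == 0:
        raise DriveWaysError(
            "mutual exclusivity undefined: all sample sets empty (0/0)"
        )
    return len(union) / total


def module_score(module, profile, universe_genes) -> ScoreBreakdown:
    """COV, MEX and MS = COV * MEX for one module."""
    cov = coverage(module, profile, universe_genes)
    mex = mutual_exclusivity(module, profile)
    return ScoreBreakdown(cov=cov, mex=mex, ms=cov * mex)


def odmss(module_set: ModuleSet, profile, universe_genes) -> float:
    """Sum of MS over the modules of the set (the ODMIC objective)."""
    return sum(
        module_score(m, profile, universe_genes).ms for m in module_set
    )


def pairwise_overlap(a, b) -> float:
    """Overlap score |a & b|^2 / (|a| * |b|); 1 iff equal, 0 iff disjoint."""
    a, b = frozenset(a), frozenset(b)
    if not a or not b:
        raise DriveWaysError("pairwise overlap undefined for an empty gene set")
    inter = len(a & b)
    return inter * inter / (len(a) * len(b))


def average_pairwise_overlap(module_set: ModuleSet) -> float:
    """Mean overlap score over all unordered pairs of modules."""
    sets_ = module_set.gene_sets()
    n = len(sets_)
    if n < 2:
        raise DriveWaysError("average pairwise overlap needs at least two modules")
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            total += pairwise_overlap(sets_[i], sets_[j])
    return total / (n * (n - 1) / 2)


class ModuleScorer:
    """Score modules against a fixed profile and universe, caching the
    coverage denominator (a single integer per analysis run)."""

    def __init__(self, profile, universe_genes):
        self.profile = profile
        self.universe_genes = frozenset(universe_genes)
        denom_union, _ = _union_and_sum(self.universe_genes, profile)
        if not denom_union:
            raise DriveWaysError(
                "coverage undefined: no gene in the universe is mutated"
            )
        self._denominator = len(denom_union)

    @property
    def denominator(self) -> int:
        return self._denominator

    def breakdown(self, genes) -> ScoreBreakdown:
        genes = genes.genes if isinstance(genes, Module) else genes
        union, total = _union_and_sum(genes, self.profile)
        if total == 0:
            raise DriveWaysError(
                "mutual exclusivity undefined: all sample sets empty (0/0)"
            )
        cov = len(union) / self._denominator
        mex = len(union) / total
        return ScoreBreakdown(cov=cov, mex=mex, ms=cov * mex)

    def ms(self, genes) -> float:
        return self.breakdown(genes).ms

    def odmss(self, module_set: ModuleSet) -> float:
        return sum(self.ms(m) for m in module_set)
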