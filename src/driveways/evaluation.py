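"""Quality measures for predicted module sets.

Modularity-aware evaluation compares a set of predicted modules
{M_1..M_m} against a set of reference pathways {R_1..R_n} through a
complete bipartite similarity matrix built from one of three measures:

* overlap:  |M & R|^2 / (|M| |R|)
* qvalue:   -log10 of the BH-adjusted upper-tail hypergeometric enrichment
            p-value, zeroed when q > 0.05 (non-significant match);
* go:       Jaccard similarity of level-standardized GO term unions.

From the matrix we compute the Maximum Weighted Maximum Cardinality
Matching and its mean matched-edge weight (MMR).  Zero-weight edges stay
in the bipartite graph: dropping them would let a method with one perfect
module and otherwise useless output score a perfect MMR.  Best-match
tables give a precision side (per-module row maxima) and a recall side
(per-pathway column maxima); F1 is the product of the two averages.

Gene-level evaluation ignores modularity: modules are accumulated in rank
order until a unique-gene cutoff is reached and TPR/FPR are computed
against a reference driver-gene list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, DriveWaysError
from .io_formats import GeneList, ReferencePathwaySet
from .scoring import ModuleSet, pairwise_overlap

logger = logging.getLogger("driveways")

__all__ = [
    "SimilarityMatrix",
    "MatchResult",
    "GOAnnotationMap",
    "hypergeom_pvalues",
    "hypergeom_qvalues",
    "similarity_matrix",
    "standardize_go",
    "go_term_depths",
    "mmr",
    "best_match_tables",
    "roc_points",
]


@dataclass
class SimilarityMatrix:
    """Complete module x pathway weight matrix (zeros included)."""

    values: pd.DataFrame  # rows: module ids, cols: pathway names
    measure: str

    @property
    def shape(self):
        return self.values.shape


@dataclass
class MatchResult:
    """A maximum-cardinality matching, its edge weights and the MMR."""

    matching: list  # list of (module_id, pathway_name)
    weights: list  # aligned matched-edge weights
    mmr: float


@dataclass
class GOAnnotationMap:
    """Per-gene standardized GO terms, all sitting at one DAG level."""

    terms_by_gene: dict
    level: int

    def terms_for_set(self, genes) -> frozenset:
        out = set()
        for g in genes:
            out |= self.terms_by_gene.get(g, frozenset())
        return frozenset(out)


# ---------------------------------------------------------------------------
# Hypergeometric enrichment
# ---------------------------------------------------------------------------

def _check_universe(modules: ModuleSet, pathways: ReferencePathwaySet, universe):
    universe = frozenset(universe)
    for i, m in enumerate(modules):
        if not m.genes <= universe:
            raise DriveWaysError(
                f"module {i + 1} contains genes outside the universe"
            )
    return universe


def hypergeom_pvalues(
    modules: ModuleSet, pathways: ReferencePathwaySet, universe
) -> pd.DataFrame:
    """Upper-tail hypergeometric p-values for every module x pathway pair.

    p = P[X >= |M & R|] with X ~ Hypergeom(N=|universe|, K=|R|, n=|M|).
    Pathways are intersected with the universe first.
    """
    universe = _check_universe(modules, pathways, universe)
    N = len(universe)
    rows = {}
    for i, m in enumerate(modules, start=1):
        n = len(m.genes)
        row = {}
        for name in pathways.names:
            ref = pathways[name] & universe
            k = len(m.genes & ref)
            row[name] = float(hypergeom.sf(k - 1, N, len(ref), n))
        rows[f"M{i}"] = row
    return pd.DataFrame.from_dict(rows, orient="index", columns=pathways.names)


def hypergeom_qvalues(
    modules: ModuleSet, pathways: ReferencePathwaySet, universe
) -> pd.DataFrame:
    """Benjamini-Hochberg q-values, correcting over all pairs jointly."""
    p = hypergeom_pvalues(modules, pathways, universe)
    flat = p.to_numpy().ravel()
    _, q, _, _ = multipletests(flat, method="fdr_bh")
    return pd.DataFrame(
        q.reshape(p.shape), index=p.index, columns=p.columns
    )


# ---------------------------------------------------------------------------
# GO standardization
# ---------------------------------------------------------------------------

def _is_a_parents(dag: nx.MultiDiGraph, term: str) -> list:
    out = []
    for _, parent, key in dag.out_edges(term, keys=True):
        if key == "is_a":
            out.append(parent)
    return out


def go_term_depths(dag: nx.MultiDiGraph) -> dict:
    """Depth of every term: length of the shortest is_a path to the root
    of its namespace (roots are terms with no is_a parent)."""
    parents = {t: _is_a_parents(dag, t) for t in dag.nodes}
    children: dict = {t: [] for t in dag.nodes}
    for t, ps in parents.items():
        for p in ps:
            children[p].append(t)
    depths: dict = {}
    frontier = [t for t, ps in parents.items() if not ps]
    for t in frontier:
        depths[t] = 0
    while frontier:
        nxt = []
        for t in frontier:
            for c in children[t]:
                if c not in depths:
                    depths[c] = depths[t] + 1
                    nxt.append(c)
        frontier = nxt
    return depths


def _ancestors_at_depth(
    term: str, level: int, dag: nx.MultiDiGraph, depths: dict
) -> frozenset:
    out = set()
    stack = [term]
    seen = {term}
    while stack:
        t = stack.pop()
        for p in _is_a_parents(dag, t):
            if p in seen:
                continue
            seen.add(p)
            if depths.get(p) == level:
                out.add(p)
            stack.append(p)
    return frozenset(out)


def standardize_go(
    dag: nx.MultiDiGraph, raw_annotations: dict, level: int = 5
) -> GOAnnotationMap:
    """Standardize annotations to one level of the GO DAG.

    Terms exactly at ``level`` are kept; deeper terms are replaced by ALL
    their is_a ancestors at ``level``; shallower terms are dropped, as are
    terms absent from the DAG.  Idempotent at a fixed level.
    """
    if level < 1:
        raise ConfigurationError("GO level must be >= 1")
    depths = go_term_depths(dag)
    out: dict = {}
    for gene, terms in raw_annotations.items():
        std = set()
        for term in terms:
            if term not in depths:
                logger.warning("GO term %s absent from the DAG; dropped", term)
                continue
            d = depths[term]
            if d == level:
                std.add(term)
            elif d > level:
                std |= _ancestors_at_depth(term, level, dag, depths)
            # d < level: higher-level annotation, ignored
        out[gene] = frozenset(std)
    return GOAnnotationMap(terms_by_gene=out, level=level)


# ---------------------------------------------------------------------------
# Similarity matrices
# ---------------------------------------------------------------------------

def similarity_matrix(
    modules: ModuleSet,
    pathways: ReferencePathwaySet,
    measure: str,
    universe=None,
    annotations: GOAnnotationMap = None,
) -> SimilarityMatrix:
    """Complete module x pathway similarity matrix under one measure."""
    index = [f"M{i}" for i in range(1, len(modules) + 1)]
    if measure == "overlap":
        data = [
            [pairwise_overlap(m.genes, pathways[name]) for name in pathways.names]
            for m in modules
        ]
    elif measure == "qvalue":
        if universe is None:
            raise ConfigurationError("qvalue measure needs a gene universe")
        q = hypergeom_qvalues(modules, pathways, universe)
        tiny = np.finfo(float).tiny
        arr = q.to_numpy()
        data = np.where(arr > 0.05, 0.0, -np.log10(np.maximum(arr, tiny)))
    elif measure == "go":
        if annotations is None:
            raise ConfigurationError("go measure needs a GOAnnotationMap")
        data = []
        for m in modules:
            tm = annotations.terms_for_set(m.genes)
            row = []
            for name in pathways.names:
                tr = annotations.terms_for_set(pathways[name])
                union = tm | tr
                row.append(len(tm & tr) / len(union) if union else 0.0)
            data.append(row)
    else:
        raise ConfigurationError(f"unknown similarity measure {measure!r}")
    df = pd.DataFrame(data, index=index, columns=pathways.names, dtype=float)
    return SimilarityMatrix(values=df, measure=measure)


# ---------------------------------------------------------------------------
# Matching and best-match scores
# ---------------------------------------------------------------------------

def mmr(sim: SimilarityMatrix) -> MatchResult:
    """Maximum-weight maximum-cardinality matching and its mean edge weight.

    The bipartite graph is complete, so every maximum matching has
    cardinality min(m, n); zero-weight edges are counted in the average.
    """
    values = sim.values.to_numpy(dtype=float)
    if values.size == 0:
        raise DriveWaysError("cannot match an empty similarity matrix")
    if np.any(values < 0):
        raise DriveWaysError("similarity weights must be non-negative")
    rows, cols = linear_sum_assignment(values, maximize=True)
    matching = [
        (sim.values.index[r], sim.values.columns[c]) for r, c in zip(rows, cols)
    ]
    weights = [float(values[r, c]) for r, c in zip(rows, cols)]
    cardinality = min(values.shape)
    assert len(matching) == cardinality
    return MatchResult(
        matching=matching, weights=weights, mmr=sum(weights) / cardinality
    )


def best_match_tables(sim: SimilarityMatrix):
    """Per-module and per-pathway best-match scores, and the F1 product.

    Precision side: each module's best pathway match (row maxima).  Recall
    side: each pathway's best module match (column maxima).  F1 is the
    product of the two averages (not a harmonic mean).
    """
    df = sim.values
    if df.size == 0:
        raise DriveWaysError("empty similarity matrix")
    per_module = df.max(axis=1)
    per_pathway = df.max(axis=0)
    f1 = float(per_module.mean()) * float(per_pathway.mean())
    return per_module, per_pathway, f1


# ---------------------------------------------------------------------------
# Gene-level ROC
# ---------------------------------------------------------------------------

def roc_points(
    ranked_modules: ModuleSet,
    reference: GeneList,
    background,
    cutoffs,
) -> list:
    """TPR/FPR at unique-gene cutoffs over rank-accumulated modules.

    For each cutoff, modules are taken in rank order until the number of
    unique genes first reaches the cutoff; then
    TPR = |top & reference| / |reference & background| and
    FPR = |top - reference| / |background - reference|.
    """
    background = frozenset(background)
    union = ranked_modules.gene_union()
    if not union <= background:
        raise DriveWaysError("background must contain every module gene")
    ref = reference.as_set() & background
    if not ref:
        raise DriveWaysError("reference is empty after background restriction")
    neg = background - reference.as_set()
    cutoffs = list(cutoffs)
    if cutoffs != sorted(cutoffs):
        raise ConfigurationError("cutoffs must be ascending")
    # prefix unique-gene sets
    prefixes = []
    acc: set = set()
    for m in ranked_modules:
        acc |= m.genes
        prefixes.append(frozenset(acc))
    out = []
    for cutoff in cutoffs:
        chosen = None
        for pref in prefixes:
            if len(pref) >= cutoff:
                chosen = pref
                break
        if chosen is None:
            chosen = prefixes[-1] if prefixes else frozenset()
            logger.warning(
                "cutoff %d exceeds the %d available unique genes; "
                "point emitted at the achievable maximum",
                cutoff, len(chosen),
            )
        tpr = len(chosen & ref) / len(ref)
        fpr = len(chosen - reference.as_set()) / len(neg) if neg else 0.0
        out.append((cutoff, tpr, fpr))
    return out
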