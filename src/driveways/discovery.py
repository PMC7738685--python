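"""The DriveWays heuristic: seed ranking, greedy add/remove module growth,
module-set assembly, and automatic (t, d) parameter selection.

The heuristic builds possibly overlapping, connected modules one seed at a
time.  Genes surviving the mutation-frequency filter are ranked by the
module score of their extended neighborhood, MS(N_e(g)).  A module is
initialized with the best unused seed and grown greedily: in each step a
candidate set CS(M) of neighboring genes is formed from the two admission
rules

    (1)  |union_{k in M+{g}} S_k| / sum_{k in M} |S_k|  >  t
    (2)  deg(g, M) / mean_deg(g)                        >  1 / d

where rule (1) demands that the enlarged module's coverage exceed t times
the ratio of the old coverage to the old mutual exclusivity, and rule (2)
demands that g be better connected to M than it is, on average, to the
modules that already contain it (genes in no prior module pass it
vacuously).  The best single-gene addition and the best legal removal
compete on MS improvement; the better strictly-improving move is committed,
and growth stops at the first step with no improving move.  Module
construction continues down the seed ranking until the summed module sizes
reach the total-size budget delta_s.

t indirectly controls module sizes (larger t, smaller modules); d controls
the amount of overlap between modules (larger d, more gene reuse).  Both
can be tuned automatically by maximizing ODMSS over [0.8, 1.2] x [2, 5]
with a seeded Bayesian optimizer (Gaussian-process surrogate, expected
improvement, 30 evaluations by default) or a deterministic grid.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.stats import norm

from .errors import ConfigurationError, DriveWaysError
from .io_formats import MutationProfile, PPINetwork
from .scoring import Module, ModuleScorer, ModuleSet

logger = logging.getLogger("driveways")

__all__ = [
    "DriveWaysParams",
    "SeedRanking",
    "rank_seeds",
    "candidate_set",
    "grow_module",
    "build_module_set",
    "optimize_params",
]


@dataclass
class DriveWaysParams:
    """Tunable parameters of the heuristic.

    t: coverage-ratio admission threshold of rule (1).
    d: connectivity laxness of rule (2); larger d admits sparser links.
    delta_m: minimum module size (default 3).
    delta_s: total-size budget (sum of output module sizes).
    min_mut_fraction: mutation-frequency filter (default 1% of the cohort).
    optimizer: 'fixed' runs at (t, d); 'search' tunes them.
    """

    t: float = 1.0
    d: float = 3.0
    delta_m: int = 3
    delta_s: int = 30
    min_mut_fraction: float = 0.01
    optimizer: str = "fixed"
    n_evaluations: int = 30
    t_range: tuple = (0.8, 1.2)
    d_range: tuple = (2.0, 5.0)
    search_strategy: str = "bayes"
    rng_seed: int = 42

    def __post_init__(self):
        if self.delta_m < 1:
            raise ConfigurationError("delta_m must be >= 1")
        if self.delta_s < self.delta_m:
            raise ConfigurationError("delta_s must be >= delta_m")
        if self.t_range[0] <= 0 or self.t_range[0] > self.t_range[1]:
            raise ConfigurationError("t_range must be a positive interval")
        if self.d_range[0] <= 0 or self.d_range[0] > self.d_range[1]:
            raise ConfigurationError("d_range must be a positive interval")
        if self.optimizer not in ("fixed", "search"):
            raise ConfigurationError(f"unknown optimizer mode {self.optimizer!r}")
        if self.search_strategy not in ("bayes", "grid"):
            raise ConfigurationError(
                f"unknown search strategy {self.search_strategy!r}"
            )


@dataclass
class SeedRanking:
    """Genes ordered by MS(N_e(g)), scores non-increasing."""

    entries: list  # list of (gene, score)

    def __iter__(self):
        return iter(self.entries)

    def __len__(self):
        return len(self.entries)

    def genes(self) -> list:
        return [g for g, _ in self.entries]


def analysis_universe(network: PPINetwork, profile: MutationProfile) -> frozenset:
    """V for scoring: network genes that survived the frequency filter."""
    return network.nodes & profile.genes


def rank_seeds(
    network: PPINetwork, profile: MutationProfile, params: DriveWaysParams,
    scorer: Optional[ModuleScorer] = None,
) -> SeedRanking:
    """Rank the surviving network genes by MS of their extended neighborhood.

    ``profile`` must already be frequency-filtered.  Ties are broken by
    descending |S_g|, then lexicographically, so the ranking is
    deterministic.
    """
    universe = analysis_universe(network, profile)
    if not universe:
        raise DriveWaysError(
            "no gene is shared between the network and the mutation profile"
        )
    if scorer is None:
        scorer = ModuleScorer(profile, universe)
    entries = []
    for gene in universe:
        score = scorer.ms(network.extended_neighborhood(gene))
        entries.append((gene, score))
    entries.sort(key=lambda e: (-e[1], -len(profile.sample_set(e[0])), e[0]))
    return SeedRanking(entries)


def _mean_deg(gene: str, module_set_so_far: ModuleSet, network: PPINetwork):
    """Mean of deg(g, M_q) over existing modules M_q containing g, or None
    when g belongs to no prior module."""
    degs = [
        network.degree_within(gene, m.genes)
        for m in module_set_so_far
        if gene in m.genes
    ]
    if not degs:
        return None
    return sum(degs) / len(degs)


def candidate_set(
    current: frozenset,
    module_set_so_far: ModuleSet,
    network: PPINetwork,
    profile: MutationProfile,
    params: DriveWaysParams,
) -> frozenset:
    """CS(M): neighbors of M admissible under rules (1) and (2).

    Membership in a previously built module does not exclude a gene; this
    is what lets output modules overlap.
    """
    union_m = set()
    sum_m = 0
    for g in current:
        s = profile.sample_set(g)
        union_m |= s
        sum_m += len(s)
    if sum_m == 0:
        return frozenset()
    out = set()
    for gene in network.neighborhood_of_set(current) - current:
        # rule (1): strict coverage-gain threshold
        lhs = len(union_m | profile.sample_set(gene)) / sum_m
        if not lhs > params.t:
            continue
        # rule (2): relative connectivity; vacuous for genes in no module
        mean_deg = _mean_deg(gene, module_set_so_far, network)
        if mean_deg is not None:
            deg_here = network.degree_within(gene, current)
            if not deg_here / mean_deg > 1.0 / params.d:
                continue
        out.add(gene)
    return frozenset(out)


def _best_addition(
    current: frozenset, candidates: frozenset, scorer: ModuleScorer
) -> Optional[tuple]:
    """M_a: union of M with all tied maximizers of MS(M + {g}).

    Returns (new_gene_set, ms_of_new_set) or None when no candidate exists.
    """
    if not candidates:
        return None
    best_single = -math.inf
    best_genes: list = []
    for gene in sorted(candidates):
        ms = scorer.ms(current | {gene})
        if ms > best_single + 1e-15:
            best_single, best_genes = ms, [gene]
        elif abs(ms - best_single) <= 1e-15:
            best_genes.append(gene)
    new = frozenset(current | set(best_genes))
    return new, scorer.ms(new)


def _best_removal(
    current: frozenset, seed: str, network: PPINetwork, scorer: ModuleScorer
) -> Optional[tuple]:
    """M_r: M minus all tied maximizers of MS(M - {g}).

    Removal candidates are non-seed genes whose single removal keeps the
    module connected and non-empty.  If the joint removal of a tie group
    would disconnect the module, only the lexicographically first gene of
    the group is removed.
    """
    removable = [
        g
        for g in sorted(current)
        if g != seed
        and len(current) > 1
        and network.is_connected_subset(current - {g})
    ]
    if not removable:
        return None
    best_single = -math.inf
    best_genes: list = []
    for gene in removable:
        try:
            ms = scorer.ms(current - {gene})
        except DriveWaysError:
            continue  # removal leaves no mutated gene; not a legal variant
        if ms > best_single + 1e-15:
            best_single, best_genes = ms, [gene]
        elif abs(ms - best_single) <= 1e-15:
            best_genes.append(gene)
    if not best_genes:
        return None
    new = frozenset(current - set(best_genes))
    if not new or not network.is_connected_subset(new):
        new = frozenset(current - {best_genes[0]})
    try:
        return new, scorer.ms(new)
    except DriveWaysError:
        return None


def grow_module(
    seed: str,
    module_set_so_far: ModuleSet,
    network: PPINetwork,
    profile: MutationProfile,
    params: DriveWaysParams,
    scorer: Optional[ModuleScorer] = None,
) -> Module:
    """Grow a module from a seed by competing add/remove moves.

    MS strictly increases across committed steps (asserted), which bounds
    the iteration count; growth stops when neither the best addition M_a
    nor the best removal M_r improves on MS(M).
    """
    if scorer is None:
        scorer = ModuleScorer(profile, analysis_universe(network, profile))
    current = frozenset({seed})
    current_ms = scorer.ms(current)
    while True:
        cs = candidate_set(current, module_set_so_far, network, profile, params)
        add = _best_addition(current, cs, scorer)
        rem = _best_removal(current, seed, network, scorer)
        add_gain = add[1] - current_ms if add is not None else -math.inf
        rem_gain = rem[1] - current_ms if rem is not None else -math.inf
        if add_gain <= 1e-15 and rem_gain <= 1e-15:
            break
        # tie between addition and removal goes to addition
        new, new_ms = add if add_gain >= rem_gain else rem
        if not new_ms > current_ms:  # runtime guard for the monotone invariant
            raise AssertionError("committed growth step did not increase MS")
        logger.debug(
            "grow %s: %s -> %s (MS %.6f -> %.6f)",
            seed, sorted(current), sorted(new), current_ms, new_ms,
        )
        current, current_ms = new, new_ms
    return Module(current, seed=seed)


def build_module_set(
    network: PPINetwork,
    profile: MutationProfile,
    params: DriveWaysParams,
) -> tuple[ModuleSet, list]:
    """Assemble the output module set D under the total-size budget.

    Seeds are consumed in rank order; a grown module is kept only if it has
    at least delta_m genes and duplicates no earlier module.  Construction
    stops once the summed sizes reach delta_s (the final module is kept
    whole, so the total may overshoot by at most |last module| - 1).
    Returns the module set and the aligned per-module score breakdowns.
    """
    universe = analysis_universe(network, profile)
    scorer = ModuleScorer(profile, universe)
    ranking = rank_seeds(network, profile, params, scorer=scorer)
    modules = ModuleSet()
    seen: set = set()
    total = 0
    for seed, _score in ranking:
        if total >= params.delta_s:
            break
        if any(seed in m.genes for m in modules):
            continue
        module = grow_module(
            seed, modules, network, profile, params, scorer=scorer
        )
        if len(module) < params.delta_m:
            logger.debug("seed %s: module below delta_m, discarded", seed)
            continue
        if module.genes in seen:
            logger.debug("seed %s: duplicate module, discarded", seed)
            continue
        modules.append(module)
        seen.add(module.genes)
        total += len(module)
    if total < params.delta_s:
        logger.warning(
            "seeds exhausted at total size %d < delta_s=%d; returning partial set",
            total, params.delta_s,
        )
    breakdowns = [scorer.breakdown(m) for m in modules]
    return modules, breakdowns


# ---------------------------------------------------------------------------
# (t, d) search
# ---------------------------------------------------------------------------

def _grid_points(params: DriveWaysParams) -> list:
    n = max(1, params.n_evaluations)
    n_t = max(1, int(math.sqrt(n)))
    n_d = max(1, n // n_t)
    ts = np.linspace(params.t_range[0], params.t_range[1], n_t)
    ds = np.linspace(params.d_range[0], params.d_range[1], n_d)
    return [(float(t), float(d)) for t in ts for d in ds]


def _expected_improvement(mu, sigma, best):
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (mu - best) / sigma
        ei = (mu - best) * norm.cdf(z) + sigma * norm.pdf(z)
    ei[sigma <= 0] = 0.0
    return ei


def _bayes_points(params: DriveWaysParams, objective) -> list:
    """Sequential GP/EI maximization over the (t, d) box; returns the list
    of ((t, d), score) evaluations.  Fully determined by params.rng_seed."""
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import ConstantKernel, Matern

    rng = np.random.default_rng(params.rng_seed)
    lo = np.array([params.t_range[0], params.d_range[0]])
    hi = np.array([params.t_range[1], params.d_range[1]])
    span = np.where(hi > lo, hi - lo, 1.0)
    n_calls = max(1, params.n_evaluations)
    n_init = min(n_calls, max(4, n_calls // 3))

    X: list = []
    y: list = []
    evals: list = []

    def probe(x):
        score = objective((float(x[0]), float(x[1])))
        X.append(np.asarray(x, dtype=float))
        y.append(score)
        evals.append(((float(x[0]), float(x[1])), score))

    for _ in range(n_init):
        probe(lo + rng.random(2) * (hi - lo))
    while len(evals) < n_calls:
        finite = [v for v in y if math.isfinite(v)]
        floor = (min(finite) - 1.0) if finite else 0.0
        ytr = np.array([v if math.isfinite(v) else floor for v in y])
        Xtr = (np.array(X) - lo) / span
        kernel = ConstantKernel(1.0) * Matern(
            length_scale=[0.3, 0.3], nu=2.5, length_scale_bounds=(1e-2, 1e2)
        )
        gp = GaussianProcessRegressor(
            kernel=kernel,
            alpha=1e-8,
            normalize_y=True,
            n_restarts_optimizer=1,
            random_state=int(rng.integers(2**31 - 1)),
        )
        try:
            gp.fit(Xtr, ytr)
            cand = lo + rng.random((256, 2)) * (hi - lo)
            mu, sigma = gp.predict((cand - lo) / span, return_std=True)
            ei = _expected_improvement(mu, sigma, ytr.max())
            probe(cand[int(np.argmax(ei))])
        except Exception:  # GP degenerate (e.g. constant objective)
            probe(lo + rng.random(2) * (hi - lo))
    return evals


def optimize_params(
    network: PPINetwork,
    profile: MutationProfile,
    params: DriveWaysParams,
) -> tuple[DriveWaysParams, ModuleSet, list]:
    """Pick the (t, d) among evaluated points that maximizes ODMSS(D).

    Returns the winning parameter setting together with the module set and
    score breakdowns it produced.  Failed evaluations score -inf and are
    never selected.  Deterministic given ``params.rng_seed``.
    """
    if params.optimizer != "search":
        raise ConfigurationError("optimize_params requires optimizer='search'")
    universe = analysis_universe(network, profile)
    scorer = ModuleScorer(profile, universe)
    cache: dict = {}

    def objective(td) -> float:
        try:
            run = replace(params, t=td[0], d=td[1], optimizer="fixed")
            modules, breakdowns = build_module_set(network, profile, run)
            score = sum(sb.ms for sb in breakdowns)
            cache[td] = (modules, breakdowns, score)
            return score
        except DriveWaysError:
            logger.warning("evaluation at t=%.4f d=%.4f failed", *td)
            return -math.inf

    if params.search_strategy == "grid":
        evals = [(td, objective(td)) for td in _grid_points(params)]
    else:
        evals = _bayes_points(params, objective)

    best_td, best_score = max(evals, key=lambda e: e[1])
    if not math.isfinite(best_score):
        raise DriveWaysError("every (t, d) evaluation failed")
    modules, breakdowns, _ = cache[best_td]
    logger.info(
        "parameter search: best t=%.4f d=%.4f ODMSS=%.6f over %d evaluations",
        best_td[0], best_td[1], best_score, len(evals),
    )
    best = replace(params, t=best_td[0], d=best_td[1])
    return best, modules, breakdowns
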