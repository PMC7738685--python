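"""Readers and writers for every on-disk format the tool touches.

Formats (all plain text, tab-separated unless noted):

* PPI network: ``geneA<TAB>geneB[<TAB>confidence]``, ``#`` comments allowed.
* Mutations, gene-major: ``GENE<TAB>s1,s2,...``; sample-major:
  ``SAMPLE<TAB>gene<TAB>gene...``.
* Pathway collections: standard GMT (name, description, genes...).
* Gene lists: one symbol per line.
* Module output: TSV with columns rank, MS, COV, MEX, size, genes.
* GO annotations: ``gene<TAB>GO:NNNNNNN`` two-column TSV.

Gene identity is the raw symbol string, case-sensitive; no alias
resolution is attempted.
"""

from __future__ import annotations

import logging
import os
import tempfile
from dataclasses import dataclass
from typing import Optional

import networkx as nx

from .errors import ConfigurationError, DriveWaysError, ParseError
from .scoring import Module, ModuleSet, ScoreBreakdown

logger = logging.getLogger("driveways")

__all__ = [
    "PPINetwork",
    "MutationProfile",
    "ReferencePathwaySet",
    "GeneList",
    "read_network",
    "read_mutations",
    "write_mutations",
    "filter_low_frequency_genes",
    "read_gmt",
    "write_gmt",
    "read_gene_list",
    "read_go_annotations",
    "write_modules",
    "read_modules",
    "atomic_write",
]


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass
class PPINetwork:
    """Undirected gene graph G = (V, E), backed by a networkx Graph.

    Invariants: no self-loops; every edge endpoint is a node.  Optional
    per-edge confidences live as the ``confidence`` edge attribute.
    """

    graph: nx.Graph

    @classmethod
    def from_edges(cls, edges, confidence: Optional[dict] = None) -> "PPINetwork":
        g = nx.Graph()
        for a, b in edges:
            if a == b:
                continue
            g.add_edge(a, b)
            if confidence is not None:
                key = (a, b) if (a, b) in confidence else (b, a)
                if key in confidence:
                    g[a][b]["confidence"] = confidence[key]
        return cls(g)

    @property
    def nodes(self) -> frozenset:
        return frozenset(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def has_node(self, gene: str) -> bool:
        return self.graph.has_node(gene)

    def neighbors(self, gene: str) -> frozenset:
        """N(g): the open neighborhood of a gene."""
        return frozenset(self.graph.neighbors(gene))

    def extended_neighborhood(self, gene: str) -> frozenset:
        """N_e(g) = N(g) plus g itself."""
        return self.neighbors(gene) | {gene}

    def neighborhood_of_set(self, genes) -> frozenset:
        """N(M): union of the open neighborhoods of a gene set."""
        out = set()
        for g in genes:
            out.update(self.graph.neighbors(g))
        return frozenset(out)

    def degree_within(self, gene: str, genes) -> int:
        """deg(g, M): number of neighbors of g inside the gene set M."""
        return sum(1 for n in self.graph.neighbors(gene) if n in genes)

    def is_connected_subset(self, genes) -> bool:
        """Whether the subgraph induced by ``genes`` is connected."""
        genes = set(genes)
        if not genes:
            return False
        sub = self.graph.subgraph(genes)
        if sub.number_of_nodes() != len(genes):
            return False  # some gene absent from the network
        return nx.is_connected(sub)


@dataclass
class MutationProfile:
    """Per-gene mutated-sample sets over a cohort sample universe."""

    samples_by_gene: dict
    sample_universe: frozenset

    def __post_init__(self):
        self.samples_by_gene = {
            g: frozenset(s) for g, s in self.samples_by_gene.items()
        }
        self.sample_universe = frozenset(self.sample_universe)
        for g, s in self.samples_by_gene.items():
            if not s <= self.sample_universe:
                raise DriveWaysError(
                    f"gene {g} carries samples outside the cohort universe"
                )

    @property
    def genes(self) -> frozenset:
        return frozenset(self.samples_by_gene)

    def sample_set(self, gene: str) -> frozenset:
        """S_g; genes absent from the profile yield the empty set."""
        return self.samples_by_gene.get(gene, frozenset())

    def n_samples(self) -> int:
        return len(self.sample_universe)

    def restricted_to(self, genes) -> "MutationProfile":
        """Profile restricted to ``genes``; the sample universe is kept."""
        keep = {g: s for g, s in self.samples_by_gene.items() if g in genes}
        return MutationProfile(keep, self.sample_universe)

    def __eq__(self, other):
        return (
            isinstance(other, MutationProfile)
            and self.samples_by_gene == other.samples_by_gene
            and self.sample_universe == other.sample_universe
        )


@dataclass
class ReferencePathwaySet:
    """Named gene sets (order-preserving), e.g. KEGG filtered to CGC genes."""

    pathways: dict
    provenance: str = ""

    def __post_init__(self):
        self.pathways = {n: frozenset(g) for n, g in self.pathways.items()}

    @property
    def names(self) -> list:
        return list(self.pathways)

    def __len__(self) -> int:
        return len(self.pathways)

    def __getitem__(self, name: str) -> frozenset:
        return self.pathways[name]

    def gene_union(self) -> frozenset:
        out = set()
        for g in self.pathways.values():
            out |= g
        return frozenset(out)

    def total_size(self) -> int:
        return sum(len(g) for g in self.pathways.values())


@dataclass
class GeneList:
    """An ordered, duplicate-free list of gene symbols."""

    genes: list
    label: str = ""

    def __post_init__(self):
        seen = set()
        out = []
        for g in self.genes:
            if g not in seen:
                seen.add(g)
                out.append(g)
        self.genes = out

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def as_set(self) -> frozenset:
        return frozenset(self.genes)


# ---------------------------------------------------------------------------
# Atomic writes
# ---------------------------------------------------------------------------

def atomic_write(path, text: str) -> None:
    """Write ``text`` to ``path`` atomically (temp file + rename)."""
    path = os.fspath(path)
    directory = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=directory, prefix=".driveways-", suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        try:
            os.unlink(tmp)
        except OSError:
            pass
        raise


# ---------------------------------------------------------------------------
# Network I/O
# ---------------------------------------------------------------------------

def read_network(path, confidence_threshold: Optional[float] = None) -> PPINetwork:
    """Read a tab-separated edge list, optionally filtering on confidence.

    Edges with confidence strictly below the threshold are removed;
    self-loops, duplicate edges and isolated nodes are dropped.  When a
    threshold is active, every data line must carry a confidence column.
    """
    if confidence_threshold is not None and not 0 <= confidence_threshold <= 1:
        raise ConfigurationError(
            f"confidence threshold must lie in [0, 1], got {confidence_threshold}"
        )
    edges = []
    confidence: dict = {}
    n_data_lines = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise ParseError(
                    f"expected at least two tab-separated columns, got {line!r}",
                    path=path,
                    line=lineno,
                )
            a, b = fields[0], fields[1]
            n_data_lines += 1
            conf = None
            if len(fields) >= 3 and fields[2] != "":
                try:
                    conf = float(fields[2])
                except ValueError as exc:
                    raise ParseError(
                        f"confidence column is not numeric: {fields[2]!r}",
                        path=path,
                        line=lineno,
                    ) from exc
            if confidence_threshold is not None:
                if conf is None:
                    if len(fields) < 3:
                        raise ConfigurationError(
                            f"{path}:{lineno}: confidence threshold given but "
                            "line has no confidence column"
                        )
                    logger.warning(
                        "%s:%d: missing confidence with active threshold; "
                        "edge %s-%s dropped",
                        path, lineno, a, b,
                    )
                    continue
                if conf < confidence_threshold:
                    continue
            if a == b:
                continue
            edges.append((a, b))
            if conf is not None:
                confidence[(a, b)] = conf
    if n_data_lines == 0:
        logger.warning("%s: empty network file", path)
    return PPINetwork.from_edges(edges, confidence or None)


# ---------------------------------------------------------------------------
# Mutation I/O
# ---------------------------------------------------------------------------

def read_mutations(path, dialect: str = "gene_major") -> MutationProfile:
    """Read a mutation file in either the gene-major or sample-major dialect.

    Both dialects yield identical profiles on equivalent content; the sample
    universe is the union of all sample identifiers observed.
    """
    if dialect not in ("gene_major", "sample_major"):
        raise ConfigurationError(f"unknown mutation dialect: {dialect!r}")
    samples_by_gene: dict = {}
    universe: set = set()
    n_data = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            n_data += 1
            if dialect == "gene_major":
                if len(fields) < 2:
                    raise ParseError(
                        "gene-major line needs GENE<TAB>samples",
                        path=path, line=lineno,
                    )
                gene = fields[0]
                samples = {s for s in fields[1].split(",") if s}
                universe |= samples
                if gene in samples_by_gene:
                    logger.warning(
                        "%s:%d: duplicate gene %s; sample sets unioned",
                        path, lineno, gene,
                    )
                    samples_by_gene[gene] = samples_by_gene[gene] | samples
                else:
                    samples_by_gene[gene] = samples
            else:
                if len(fields) < 2:
                    raise ParseError(
                        "sample-major line needs SAMPLE<TAB>gene...",
                        path=path, line=lineno,
                    )
                sample = fields[0]
                universe.add(sample)
                for gene in fields[1:]:
                    if not gene:
                        continue
                    samples_by_gene.setdefault(gene, set()).add(sample)
    if n_data == 0:
        raise ParseError("empty mutation file", path=path)
    return MutationProfile(samples_by_gene, frozenset(universe))


def write_mutations(profile: MutationProfile, path, dialect: str = "gene_major") -> None:
    """Serialize a profile in either dialect (deterministic, sorted order)."""
    if dialect == "gene_major":
        lines = [
            f"{g}\t{','.join(sorted(profile.samples_by_gene[g]))}"
            for g in sorted(profile.samples_by_gene)
            if profile.samples_by_gene[g]
        ]
    elif dialect == "sample_major":
        by_sample: dict = {}
        for g, ss in profile.samples_by_gene.items():
            for s in ss:
                by_sample.setdefault(s, set()).add(g)
        lines = [
            "\t".join([s] + sorted(by_sample[s])) for s in sorted(by_sample)
        ]
    else:
        raise ConfigurationError(f"unknown mutation dialect: {dialect!r}")
    atomic_write(path, "\n".join(lines) + ("\n" if lines else ""))


def filter_low_frequency_genes(
    profile: MutationProfile, min_fraction: float = 0.01
) -> MutationProfile:
    """Drop genes mutated in less than ``min_fraction`` of the cohort.

    The comparison is strict: a gene survives iff
    ``|S_g| >= min_fraction * |universe|``.  The sample universe is kept.
    """
    if not 0 <= min_fraction <= 1:
        raise ConfigurationError(
            f"min_fraction must lie in [0, 1], got {min_fraction}"
        )
    threshold = min_fraction * len(profile.sample_universe)
    keep = {
        g: s for g, s in profile.samples_by_gene.items() if not len(s) < threshold
    }
    return MutationProfile(keep, profile.sample_universe)


# ---------------------------------------------------------------------------
# Pathways and gene lists
# ---------------------------------------------------------------------------

def read_gmt(
    path, restrict_to: Optional[GeneList] = None, min_size: int = 1
) -> ReferencePathwaySet:
    """Read a GMT file, optionally intersecting each pathway with a gene
    list before dropping pathways smaller than ``min_size``."""
    restrict = restrict_to.as_set() if restrict_to is not None else None
    pathways: dict = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    "GMT line needs name, description and at least one gene",
                    path=path, line=lineno,
                )
            name = fields[0]
            if name in pathways:
                raise ParseError(
                    f"duplicate pathway name {name!r}", path=path, line=lineno
                )
            genes = frozenset(g for g in fields[2:] if g)
            if restrict is not None:
                genes &= restrict
            if len(genes) < min_size:
                continue
            pathways[name] = genes
    return ReferencePathwaySet(pathways, provenance=os.fspath(path))


def write_gmt(pathways: ReferencePathwaySet, path, description: str = "na") -> None:
    lines = [
        "\t".join([name, description] + sorted(pathways[name]))
        for name in pathways.names
    ]
    atomic_write(path, "\n".join(lines) + ("\n" if lines else ""))


def read_gene_list(path, label: str = "") -> GeneList:
    genes = []
    with open(path) as fh:
        for raw in fh:
            g = raw.strip()
            if g and not g.startswith("#"):
                genes.append(g)
    return GeneList(genes, label=label or os.fspath(path))


def read_go_annotations(path) -> dict:
    """Read a two-column gene<TAB>GO:NNNNNNN TSV into gene -> term set."""
    out: dict = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(
                    "annotation line needs gene<TAB>term", path=path, line=lineno
                )
            out.setdefault(fields[0], set()).add(fields[1])
    return {g: frozenset(t) for g, t in out.items()}


# ---------------------------------------------------------------------------
# Module tables
# ---------------------------------------------------------------------------

_MODULE_HEADER = ["rank", "MS", "COV", "MEX", "size", "genes"]


def write_modules(modules: ModuleSet, scores, path) -> None:
    """Write a ranked module table (TSV).

    ``scores`` is a sequence of ScoreBreakdown aligned with the modules.
    Genes are comma-joined in sorted order so output is deterministic and
    round-trips through :func:`read_modules`.
    """
    if len(scores) != len(modules):
        raise ConfigurationError(
            f"{len(scores)} scores for {len(modules)} modules"
        )
    lines = ["\t".join(_MODULE_HEADER)]
    for rank, (module, sb) in enumerate(zip(modules, scores), start=1):
        lines.append(
            "\t".join(
                [
                    str(rank),
                    format(sb.ms, ".17g"),
                    format(sb.cov, ".17g"),
                    format(sb.mex, ".17g"),
                    str(len(module)),
                    ",".join(module.sorted_genes()),
                ]
            )
        )
    atomic_write(path, "\n".join(lines) + "\n")


def read_modules(path) -> tuple:
    """Read a module table back into (ModuleSet, [ScoreBreakdown])."""
    modules = ModuleSet()
    scores = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines or lines[0].split("\t") != _MODULE_HEADER:
        raise ParseError("missing or malformed module table header", path=path, line=1)
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(_MODULE_HEADER):
            raise ParseError(
                f"expected {len(_MODULE_HEADER)} columns", path=path, line=lineno
            )
        ms, cov, mex = (float(fields[i]) for i in (1, 2, 3))
        genes = frozenset(g for g in fields[5].split(",") if g)
        if len(genes) != int(fields[4]):
            raise ParseError("size column disagrees with gene list", path=path, line=lineno)
        modules.append(Module(genes))
        scores.append(ScoreBreakdown(cov=cov, mex=mex, ms=ms))
    return modules, scores
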