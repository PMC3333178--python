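"""PPI network overlay, per-protein averages, hub detection and classification.

Pair profiles computed in PC space are joined onto an undirected
protein-protein interaction graph through a protein-to-gene mapping.
Each protein then gets an average co-expression correlation and an
average stability over its profiled partners:

    r_bar_a = (1/n) * sum_i r_ai        S_bar_a = (1/n) * sum_i S_ai

Hubs (proteins with >= 5 interaction partners) are classified into four
categories by where their partner edges fall against 0.5/0.5 cutoffs on
(cor_0, stability):

    category 1: cor > 0.5, stability > 0.5   (obligate / intra-modular)
    category 2: cor <= 0.5, stability > 0.5  (transient / inter-modular)
    category 3: cor <= 0.5, stability <= 0.5 (fragile co-expression)
    category 4: cor > 0.5, stability <= 0.5  (rare)

A protein is a hub of every category in which at least ``min_partners``
of its edges fall, so multi-category membership is possible; a dominant
category (largest qualifying count, ties to the lowest number) is also
reported for single-label summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .coexpression import CoexpressionProfile

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkError",
    "AmbiguousMappingError",
    "PPINetwork",
    "OverlayStats",
    "ProteinSummary",
    "HubAssignment",
    "overlay",
    "protein_averages",
    "find_hubs",
    "categorize_edge",
    "classify_hubs",
]

CATEGORIES = (1, 2, 3, 4)


class NetworkError(ValueError):
    """Invalid network input or parameter."""


class AmbiguousMappingError(NetworkError):
    """Two proteins on one edge resolve to the same gene."""


class PPINetwork:
    """Simple undirected PPI graph with a protein-to-gene mapping.

    Self-loops and duplicate edges are dropped at construction with
    logged counts. When no mapping is given, protein ids double as gene
    ids (identity mapping).
    """

    def __init__(
        self,
        edges: Iterable[tuple[str, str]],
        protein_to_gene: Mapping[str, str] | None = None,
    ) -> None:
        self.graph = nx.Graph()
        self.n_self_loops_dropped = 0
        self.n_duplicate_edges = 0
        for a, b in edges:
            if a == b:
                self.n_self_loops_dropped += 1
                continue
            if self.graph.has_edge(a, b):
                self.n_duplicate_edges += 1
                continue
            self.graph.add_edge(a, b)
        if self.n_self_loops_dropped:
            logger.info("dropped %d self-interactions", self.n_self_loops_dropped)
        if self.n_duplicate_edges:
            logger.info("collapsed %d duplicate edges", self.n_duplicate_edges)
        if protein_to_gene is None:
            self.protein_to_gene = {p: p for p in self.graph.nodes}
        else:
            self.protein_to_gene = dict(protein_to_gene)
            missing = [p for p in self.graph.nodes if p not in self.protein_to_gene]
            if missing:
                raise NetworkError(
                    f"{len(missing)} proteins lack a gene mapping (e.g. {missing[:3]})"
                )

    @property
    def proteins(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def gene_of(self, protein: str) -> str:
        return self.protein_to_gene[protein]

    def profiled_graph(self) -> nx.Graph:
        """Subgraph restricted to edges carrying a co-expression profile."""
        g = nx.Graph()
        for a, b, data in self.graph.edges(data=True):
            if data.get("profile") is not None:
                g.add_edge(a, b, **data)
        return g

    def profiled_partners(self, protein: str) -> list[str]:
        return [
            nbr
            for nbr, data in self.graph.adj[protein].items()
            if data.get("profile") is not None
        ]

    @classmethod
    def from_edgelist_tsv(cls, path, mapping_path=None) -> "PPINetwork":
        df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
        edges = list(df.iloc[:, :2].itertuples(index=False, name=None))
        mapping = None
        if mapping_path is not None:
            mdf = pd.read_csv(mapping_path, sep="\t", comment="#", header=None, dtype=str)
            mapping = dict(mdf.iloc[:, :2].itertuples(index=False, name=None))
        return cls(edges, mapping)

    def to_edgelist_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for a, b in self.graph.edges:
                fh.write(f"{a}\t{b}\n")


@dataclass
class OverlayStats:
    n_edges: int
    n_profiled: int
    n_unprofiled: int
    n_proteins_covered: int


def overlay(network: PPINetwork, profiles: Iterable[CoexpressionProfile]) -> OverlayStats:
    """Attach pair profiles to matching network edges (in place).

    Edges whose gene pair has no profile are retained but flagged
    unprofiled. Raises :class:`AmbiguousMappingError` if both proteins of
    an edge map to the same gene.
    """
    by_pair = {p.pair: p for p in profiles}
    n_profiled = 0
    covered: set[str] = set()
    offenders = []
    for a, b, data in network.graph.edges(data=True):
        ga, gb = network.gene_of(a), network.gene_of(b)
        if ga == gb:
            offenders.append((a, b, ga))
            continue
        prof = by_pair.get(tuple(sorted((ga, gb))))
        if prof is None:
            data["profile"] = None
        else:
            data["profile"] = prof
            data["cor"] = prof.cor_0
            data["stability"] = prof.stability
            n_profiled += 1
            covered.update((a, b))
    if offenders:
        raise AmbiguousMappingError(
            f"{len(offenders)} edges join two proteins mapped to one gene: {offenders[:5]}"
        )
    stats = OverlayStats(
        n_edges=network.n_edges,
        n_profiled=n_profiled,
        n_unprofiled=network.n_edges - n_profiled,
        n_proteins_covered=len(covered),
    )
    logger.info(
        "overlay: %d/%d edges profiled over %d proteins",
        stats.n_profiled, stats.n_edges, stats.n_proteins_covered,
    )
    return stats


@dataclass
class ProteinSummary:
    """Per-protein averages over profiled edges plus optional topology."""

    protein: str
    degree: int
    avg_cor: float
    avg_stab: float
    clustering_coefficient: float | None = None
    betweenness: float | None = None


def protein_averages(network: PPINetwork) -> list[ProteinSummary]:
    """Average correlation and stability per protein over its profiled edges.

    Proteins without any profiled edge are omitted (with a logged count).
    """
    summaries = []
    n_omitted = 0
    for protein in network.graph.nodes:
        cors, stabs = [], []
        for data in network.graph.adj[protein].values():
            prof = data.get("profile")
            if prof is not None:
                cors.append(prof.cor_0)
                stabs.append(prof.stability)
        if not cors:
            n_omitted += 1
            continue
        n = len(cors)
        summaries.append(
            ProteinSummary(
                protein=protein,
                degree=n,
                avg_cor=sum(cors) / n,
                avg_stab=sum(stabs) / n,
            )
        )
    if n_omitted:
        logger.info("protein_averages: omitted %d proteins with no profiled edge", n_omitted)
    return summaries


def find_hubs(network: PPINetwork, min_degree: int = 5) -> set[str]:
    """Proteins with at least ``min_degree`` distinct profiled partners."""
    if min_degree < 1:
        raise NetworkError(f"min_degree must be at least 1, got {min_degree}")
    return {
        p for p in network.graph.nodes if len(network.profiled_partners(p)) >= min_degree
    }


def categorize_edge(
    cor: float, stab: float, cor_cutoff: float = 0.5, stab_cutoff: float = 0.5
) -> int:
    """Category (1-4) of a (cor, stability) pair; the windows partition the plane."""
    if cor > cor_cutoff:
        return 1 if stab > stab_cutoff else 4
    return 2 if stab > stab_cutoff else 3


@dataclass
class HubAssignment:
    """Category memberships of one hub with qualifying-partner counts."""

    protein: str
    qualifying_partners: dict[int, int]
    min_partners: int = 5
    categories: set[int] = field(init=False)

    def __post_init__(self) -> None:
        self.categories = {
            c for c in CATEGORIES if self.qualifying_partners.get(c, 0) >= self.min_partners
        }

    @property
    def dominant_category(self) -> int | None:
        if not self.categories:
            return None
        return max(sorted(self.categories), key=lambda c: self.qualifying_partners[c])


def classify_hubs(
    network: PPINetwork,
    cor_cutoff: float = 0.5,
    stab_cutoff: float = 0.5,
    min_partners: int = 5,
) -> list[HubAssignment]:
    """Assign hub categories from per-edge (cor_0, stability) windows.

    Boundary semantics follow the window definitions: category 1 requires
    strictly greater than both cutoffs, categories 2-4 take the
    complementary inclusive inequalities, so an edge at exactly
    (cor_cutoff, stab_cutoff) counts toward category 3.
    """
    for name, v in (("cor_cutoff", cor_cutoff), ("stab_cutoff", stab_cutoff)):
        if not (0.0 <= v <= 1.0):
            raise NetworkError(f"{name} must be in [0, 1], got {v}")
    if min_partners < 1:
        raise NetworkError(f"min_partners must be at least 1, got {min_partners}")
    assignments = []
    for protein in network.graph.nodes:
        counts: dict[int, int] = {c: 0 for c in CATEGORIES}
        for data in network.graph.adj[protein].values():
            prof = data.get("profile")
            if prof is None:
                continue
            cat = categorize_edge(prof.cor_0, prof.stability, cor_cutoff, stab_cutoff)
            counts[cat] += 1
        assignment = HubAssignment(
            protein=protein,
            qualifying_partners={c: n for c, n in counts.items() if n},
            min_partners=min_partners,
        )
        if assignment.categories:
            assignments.append(assignment)
    return assignments
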