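"""Network topology of hubs: clustering coefficient, betweenness, category summaries.

The clustering coefficient of a protein is the fraction of its neighbor
pairs that are themselves connected (2T / deg(deg-1)); high values mark
intra-modular position. Betweenness centrality is the fraction of
shortest paths between other protein pairs that pass through the
protein, normalized by (n-1)(n-2)/2 for an undirected graph; high values
mark inter-modular position. Per-category averages are reported with
standard errors of the mean, and betweenness is additionally displayed
on a 1e4 scale, the conventional magnitude for networks of a few
thousand proteins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .network import CATEGORIES, HubAssignment, NetworkError, PPINetwork, ProteinSummary

__all__ = [
    "clustering_coefficient",
    "betweenness_centrality",
    "betweenness_centrality_all",
    "CategorySummary",
    "category_summaries",
]


def _as_graph(network) -> nx.Graph:
    if isinstance(network, PPINetwork):
        return network.graph
    if isinstance(network, nx.Graph):
        return network
    raise NetworkError(f"expected a PPINetwork or networkx Graph, got {type(network)!r}")


def clustering_coefficient(network, protein: str) -> float:
    """Fraction of the protein's neighbor pairs that are connected.

    Defined as 0 for degree < 2.
    """
    g = _as_graph(network)
    if protein not in g:
        raise KeyError(f"protein {protein!r} not in network")
    return float(nx.clustering(g, protein))


def betweenness_centrality_all(network) -> dict[str, float]:
    """Normalized betweenness centrality for every protein in the graph.

    Pairs in different components contribute nothing; normalization is by
    (n-1)(n-2)/2 over the whole graph.
    """
    g = _as_graph(network)
    return {p: float(b) for p, b in nx.betweenness_centrality(g, normalized=True).items()}


def betweenness_centrality(network, protein: str) -> float:
    """Normalized betweenness centrality of one protein."""
    g = _as_graph(network)
    if protein not in g:
        raise KeyError(f"protein {protein!r} not in network")
    return betweenness_centrality_all(g)[protein]


@dataclass
class CategorySummary:
    """Mean +/- SE of clustering coefficient and betweenness for one hub category."""

    category: int
    n_hubs: int
    avg_cc: float | None
    se_cc: float | None
    avg_bc: float | None
    se_bc: float | None

    @property
    def avg_bc_e4(self) -> float | None:
        return None if self.avg_bc is None else self.avg_bc * 1e4

    @property
    def se_bc_e4(self) -> float | None:
        return None if self.se_bc is None else self.se_bc * 1e4


def _mean_se(values: list[float]) -> tuple[float | None, float | None]:
    if not values:
        return None, None
    mean = float(np.mean(values))
    if len(values) < 2:
        return mean, None
    se = float(np.std(values, ddof=1) / math.sqrt(len(values)))
    return mean, se


def category_summaries(
    assignments: Iterable[HubAssignment],
    summaries: Iterable[ProteinSummary],
) -> list[CategorySummary]:
    """Per-category mean and standard error of CC and BC over member hubs.

    Every hub must carry topology values in its :class:`ProteinSummary`.
    Hubs belonging to several categories contribute to each. Categories
    with no hubs yield a row with N = 0 and empty statistics.
    """
    assignments = list(assignments)
    by_protein = {s.protein: s for s in summaries}
    rows = []
    for cat in CATEGORIES:
        cc, bc = [], []
        for a in assignments:
            if cat not in a.categories:
                continue
            s = by_protein.get(a.protein)
            if s is None:
                raise NetworkError(f"hub {a.protein!r} has no protein summary")
            if s.clustering_coefficient is None or s.betweenness is None:
                raise NetworkError(f"hub {a.protein!r} lacks topology values")
            cc.append(s.clustering_coefficient)
            bc.append(s.betweenness)
        avg_cc, se_cc = _mean_se(cc)
        avg_bc, se_bc = _mean_se(bc)
        rows.append(
            CategorySummary(
                category=cat, n_hubs=len(cc),
                avg_cc=avg_cc, se_cc=se_cc, avg_bc=avg_bc, se_bc=se_bc,
            )
        )
    return rows


def summaries_table(rows: Iterable[CategorySummary]) -> pd.DataFrame:
    """Category summaries as a table with betweenness on the 1e4 display scale."""
    return pd.DataFrame(
        [
            {
                "category": r.category,
                "n_hubs": r.n_hubs,
                "avg_cc": r.avg_cc,
                "se_cc": r.se_cc,
                "avg_bc_e4": r.avg_bc_e4,
                "se_bc_e4": r.se_bc_e4,
            }
            for r in rows
        ]
    )
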