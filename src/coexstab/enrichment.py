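"""Hypergeometric term enrichment per hub category.

For a term annotating K of the Npop proteins in the population, the
enrichment of a hub category of size n containing k annotated hubs is the
upper-tail probability P(X >= k) for X ~ Hypergeometric(Npop, K, n).
Terms are tested per namespace (biological process, molecular function,
cellular component) against the population of profiled-network proteins
carrying at least one annotation in that namespace. Raw p-values are
reported at a fixed significance level (0.01 by default) with no
multiple-testing correction, which can be switched on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

from .network import CATEGORIES, HubAssignment

__all__ = [
    "EnrichmentError",
    "TermSet",
    "EnrichmentRecord",
    "hypergeom_upper_tail",
    "enrich_categories",
    "read_gmt",
    "write_gmt",
]

NAMESPACES = ("process", "function", "component")


class EnrichmentError(ValueError):
    """Inconsistent enrichment counts or inputs."""


@dataclass
class TermSet:
    """One annotation term with its namespace and member proteins."""

    term: str
    namespace: str
    members: set[str] = field(default_factory=set)


def hypergeom_upper_tail(k: int, K: int, n: int, Npop: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(Npop, K, n).

    ``k`` successes drawn, ``K`` annotated in the population, ``n`` drawn,
    ``Npop`` population size. Computed through the survival function,
    which accumulates log-space terms and is numerically stable.
    """
    for name, v in (("k", k), ("K", K), ("n", n), ("Npop", Npop)):
        if v < 0:
            raise EnrichmentError(f"{name} must be non-negative, got {v}")
    if K > Npop or n > Npop:
        raise EnrichmentError(f"K={K} and n={n} must not exceed Npop={Npop}")
    if k > min(K, n):
        raise EnrichmentError(f"k={k} exceeds min(K={K}, n={n})")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, Npop, K, n))


@dataclass
class EnrichmentRecord:
    """Enrichment of one term in one hub category."""

    term: str
    namespace: str
    category: int
    k: int
    n: int
    K: int
    Npop: int
    p: float
    significant: bool
    p_adjusted: float | None = None


def enrich_categories(
    assignments: Iterable[HubAssignment],
    terms: Sequence[TermSet],
    namespace: str,
    population: set[str],
    alpha: float = 0.01,
    correct: bool = False,
) -> list[EnrichmentRecord]:
    """Hypergeometric enrichment of every term in every hub category.

    ``population`` should contain the profiled-network proteins; it is
    intersected with the namespace's annotated proteins to form the test
    population. One record is emitted per (term, category) with at least
    one hit; records with p < alpha are flagged significant. With
    ``correct=True`` Benjamini-Hochberg adjusted p-values are added and
    the flag uses them instead.
    """
    ns_terms = [t for t in terms if t.namespace == namespace]
    if not ns_terms:
        raise EnrichmentError(f"no terms in namespace {namespace!r}")
    annotated = set().union(*(t.members for t in ns_terms))
    pop = population & annotated
    if not pop:
        raise EnrichmentError(f"empty population for namespace {namespace!r}")
    Npop = len(pop)
    category_members = {c: set() for c in CATEGORIES}
    for a in assignments:
        for c in a.categories:
            category_members[c].add(a.protein)
    records: list[EnrichmentRecord] = []
    for t in ns_terms:
        term_pop = t.members & pop
        K = len(term_pop)
        if K == 0:
            continue
        for c in CATEGORIES:
            cat_pop = category_members[c] & pop
            n = len(cat_pop)
            k = len(term_pop & cat_pop)
            if k == 0:
                continue
            p = hypergeom_upper_tail(k, K, n, Npop)
            records.append(
                EnrichmentRecord(
                    term=t.term, namespace=namespace, category=c,
                    k=k, n=n, K=K, Npop=Npop, p=p, significant=p < alpha,
                )
            )
    if correct and records:
        from statsmodels.stats.multitest import multipletests

        rejected, adjusted, _, _ = multipletests(
            [r.p for r in records], alpha=alpha, method="fdr_bh"
        )
        for r, padj, rej in zip(records, adjusted, rejected):
            r.p_adjusted = float(padj)
            r.significant = bool(rej)
    records.sort(key=lambda r: (r.category, r.p))
    return records


def read_gmt(path) -> list[TermSet]:
    """Read term sets from a GMT-style TSV: term, namespace, members..."""
    terms = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise EnrichmentError(f"malformed GMT line: {line[:80]!r}")
            terms.append(TermSet(term=parts[0], namespace=parts[1], members=set(parts[2:])))
    return terms


def write_gmt(terms: Sequence[TermSet], path) -> None:
    with open(path, "w") as fh:
        for t in terms:
            fh.write("\t".join([t.term, t.namespace, *sorted(t.members)]) + "\n")


def records_table(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term": r.term, "namespace": r.namespace, "category": r.category,
                "k": r.k, "n": r.n, "K": r.K, "Npop": r.Npop,
                "p": r.p, "p_adjusted": r.p_adjusted, "significant": r.significant,
            }
            for r in records
        ]
    )
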