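"""Intrinsic disorder, disease/essential group comparisons, 2-D landscapes.

Disorder content of a protein is quantified from per-residue binary
predictions: only maximal runs of at least 30 consecutive disordered
calls count as disordered regions, and the disorder fraction is the
number of residues inside such runs divided by the protein length. An
interaction is typed by the disorder fractions of its two proteins
against a 30% threshold: both at or above -> disordered pair, both
below -> ordered pair, otherwise mixed.

Group comparisons (disease vs non-disease, essential vs non-essential,
and the four disease x essential combinations) use the two-sided
Wilcoxon rank-sum test on per-protein average correlation and stability.

Landscapes are 2-D histograms over the (correlation, stability) plane,
optionally carrying the per-bin mean of an overlay variable (for example
disorder fraction); empty bins are masked so their absence is visible.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .network import ProteinSummary

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationError",
    "disorder_fraction",
    "interaction_type",
    "wilcoxon_rank_sum",
    "GroupStats",
    "GroupComparison",
    "group_compare",
    "Landscape2D",
    "build_landscape",
    "disease_class_summary",
    "read_residue_calls_tsv",
    "read_labels_tsv",
]


class AnnotationError(ValueError):
    """Invalid annotation input."""


_RUN_RE = re.compile(r"1+")


def disorder_fraction(residue_calls: str, min_run: int = 30) -> float:
    """Fraction of residues inside maximal disordered runs of >= min_run calls.

    ``residue_calls`` is a string of '0' (ordered) and '1' (predicted
    disordered), one character per residue.
    """
    if not residue_calls:
        raise AnnotationError("residue call string is empty")
    if set(residue_calls) - {"0", "1"}:
        bad = sorted(set(residue_calls) - {"0", "1"})
        raise AnnotationError(f"residue calls must be '0'/'1', found {bad}")
    covered = sum(
        len(m.group()) for m in _RUN_RE.finditer(residue_calls) if len(m.group()) >= min_run
    )
    return covered / len(residue_calls)


def interaction_type(frac_a: float, frac_b: float, threshold: float = 0.3) -> str:
    """Type an interaction by the disorder fractions of its proteins.

    Returns ``"disordered_pair"`` when both fractions are at or above the
    threshold, ``"ordered_pair"`` when both are below, ``"mixed"``
    otherwise. The boundary counts as disordered.
    """
    for name, v in (("frac_a", frac_a), ("frac_b", frac_b)):
        if not (0.0 <= v <= 1.0):
            raise AnnotationError(f"{name} must be in [0, 1], got {v}")
    hi_a, hi_b = frac_a >= threshold, frac_b >= threshold
    if hi_a and hi_b:
        return "disordered_pair"
    if not hi_a and not hi_b:
        return "ordered_pair"
    return "mixed"


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float], exact_max: int = 12) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration when both groups have at most ``exact_max``
    observations and there are no ties; otherwise the normal
    approximation with mid-ranks and tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise AnnotationError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):  # degenerate: every rank tied
        return 1.0
    no_ties = len(np.unique(pooled)) == pooled.size
    method = "exact" if (x.size <= exact_max and y.size <= exact_max and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=False
    )
    return float(res.pvalue)


@dataclass
class GroupStats:
    name: str
    n: int
    mean_cor: float
    mean_stab: float
    cor_values: np.ndarray
    stab_values: np.ndarray


@dataclass
class GroupComparison:
    grouping: str
    groups: dict[str, GroupStats]
    pairwise_p: dict[tuple[str, str], dict[str, float]]

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"group": g.name, "n": g.n, "mean_avg_cor": g.mean_cor, "mean_avg_stab": g.mean_stab}
                for g in self.groups.values()
            ]
        )


_GROUPINGS = ("disease", "essential", "disease_essential")


def _group_name(grouping: str, disease: bool, essential: bool) -> str:
    if grouping == "disease":
        return "disease" if disease else "non-disease"
    if grouping == "essential":
        return "essential" if essential else "non-essential"
    return ("disease" if disease else "non-disease") + "_" + (
        "essential" if essential else "non-essential"
    )


def group_compare(
    summaries: Iterable[ProteinSummary],
    labels: pd.DataFrame,
    grouping: str = "disease",
) -> GroupComparison:
    """Compare avg correlation and stability between labeled protein groups.

    ``labels`` must be indexed by protein id with boolean ``disease`` and
    ``essential`` columns; ``grouping`` is one of ``disease``,
    ``essential`` or ``disease_essential``. Unlabeled proteins are
    ignored; empty groups are skipped from pairwise tests with a warning.
    """
    if grouping not in _GROUPINGS:
        raise AnnotationError(f"grouping must be one of {_GROUPINGS}, got {grouping!r}")
    buckets: dict[str, list[ProteinSummary]] = {}
    for s in summaries:
        if s.protein not in labels.index:
            continue
        row = labels.loc[s.protein]
        name = _group_name(grouping, bool(row["disease"]), bool(row["essential"]))
        buckets.setdefault(name, []).append(s)
    groups = {}
    for name, members in buckets.items():
        cor = np.array([m.avg_cor for m in members])
        stab = np.array([m.avg_stab for m in members])
        groups[name] = GroupStats(
            name=name, n=len(members),
            mean_cor=float(cor.mean()), mean_stab=float(stab.mean()),
            cor_values=cor, stab_values=stab,
        )
    pairwise = {}
    for a, b in combinations(sorted(groups), 2):
        ga, gb = groups[a], groups[b]
        if ga.n == 0 or gb.n == 0:
            logger.warning("skipping comparison %s vs %s: empty group", a, b)
            continue
        pairwise[(a, b)] = {
            "avg_cor": wilcoxon_rank_sum(ga.cor_values, gb.cor_values),
            "avg_stab": wilcoxon_rank_sum(ga.stab_values, gb.stab_values),
        }
    return GroupComparison(grouping=grouping, groups=groups, pairwise_p=pairwise)


@dataclass
class Landscape2D:
    """Binned counts (and optional overlay means) on the correlation x stability plane.

    Bins are half-open ``[lo, hi)`` with the final bin closed; values are
    clipped into the axis ranges. ``overlay_mean`` is NaN wherever
    ``mask`` is True (no contributing items).
    """

    cor_edges: np.ndarray
    stab_edges: np.ndarray
    counts: np.ndarray
    overlay_mean: np.ndarray | None

    @property
    def mask(self) -> np.ndarray:
        return self.counts == 0

    def counts_table(self) -> pd.DataFrame:
        idx = [f"[{a:.2f},{b:.2f})" for a, b in zip(self.cor_edges[:-1], self.cor_edges[1:])]
        cols = [f"[{a:.2f},{b:.2f})" for a, b in zip(self.stab_edges[:-1], self.stab_edges[1:])]
        return pd.DataFrame(self.counts, index=idx, columns=cols)


def build_landscape(
    items: Iterable[tuple],
    bin_width: float = 0.1,
    cor_range: tuple[float, float] = (-1.0, 1.0),
    stab_range: tuple[float, float] = (-1.0, 1.0),
) -> Landscape2D:
    """Bin (cor, stability[, overlay]) items onto a regular 2-D grid.

    ``bin_width`` must evenly divide both axis ranges. Items carry an
    optional third element averaged per bin (for example a disorder
    fraction); without it only counts are produced.
    """
    if bin_width <= 0:
        raise AnnotationError(f"bin_width must be positive, got {bin_width}")
    spans = (cor_range[1] - cor_range[0], stab_range[1] - stab_range[0])
    nbins = []
    for span in spans:
        n = span / bin_width
        if abs(n - round(n)) > 1e-9:
            raise AnnotationError(
                f"bin_width {bin_width} does not evenly divide axis span {span}"
            )
        nbins.append(int(round(n)))
    items = [tuple(it) for it in items]
    has_overlay = any(len(it) > 2 for it in items)
    if has_overlay and not all(len(it) > 2 for it in items):
        raise AnnotationError("either all items carry an overlay value or none")
    cor_edges = cor_range[0] + bin_width * np.arange(nbins[0] + 1)
    stab_edges = stab_range[0] + bin_width * np.arange(nbins[1] + 1)
    counts = np.zeros((nbins[0], nbins[1]), dtype=int)
    sums = np.zeros_like(counts, dtype=float)
    for it in items:
        c, s = float(it[0]), float(it[1])
        if not (np.isfinite(c) and np.isfinite(s)):
            raise AnnotationError("landscape items must be finite")
        ci = min(int((np.clip(c, *cor_range) - cor_range[0]) / bin_width), nbins[0] - 1)
        si = min(int((np.clip(s, *stab_range) - stab_range[0]) / bin_width), nbins[1] - 1)
        counts[ci, si] += 1
        if has_overlay:
            sums[ci, si] += float(it[2])
    overlay = None
    if has_overlay:
        with np.errstate(invalid="ignore"):
            overlay = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return Landscape2D(
        cor_edges=cor_edges, stab_edges=stab_edges, counts=counts, overlay_mean=overlay
    )


def disease_class_summary(
    summaries: Iterable[ProteinSummary],
    labels: pd.DataFrame,
) -> pd.DataFrame:
    """Per-disease-class mean +/- SE of average correlation and stability.

    ``labels`` must carry a ``disease_class`` column; proteins without a
    class are excluded. Rows are sorted by decreasing mean stability.
    """
    rows = []
    by_class: dict[str, list[ProteinSummary]] = {}
    for s in summaries:
        if s.protein not in labels.index:
            continue
        cls = labels.loc[s.protein].get("disease_class")
        if cls is None or (isinstance(cls, float) and np.isnan(cls)) or cls == "":
            continue
        by_class.setdefault(str(cls), []).append(s)
    for cls, members in by_class.items():
        cor = np.array([m.avg_cor for m in members])
        stab = np.array([m.avg_stab for m in members])
        n = len(members)
        rows.append(
            {
                "disease_class": cls,
                "n": n,
                "mean_avg_cor": float(cor.mean()),
                "se_avg_cor": float(cor.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
                "mean_avg_stab": float(stab.mean()),
                "se_avg_stab": float(stab.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values("mean_avg_stab", ascending=False).reset_index(drop=True)
    return df


def read_residue_calls_tsv(path) -> dict[str, str]:
    """Read per-protein residue-call strings (protein id, 0/1 string)."""
    calls = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            protein, s = line.split("\t")[:2]
            calls[protein] = s
    return calls


def read_labels_tsv(path) -> pd.DataFrame:
    """Read protein labels: protein, disease 0/1, essential 0/1, disease_class."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"protein": str})
    df = df.set_index("protein")
    df["disease"] = df["disease"].astype(int).astype(bool)
    df["essential"] = df["essential"].astype(int).astype(bool)
    if "disease_class" in df.columns:
        df["disease_class"] = df["disease_class"].fillna("")
    return df
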