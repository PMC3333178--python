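"""PC-space co-expression correlation and its stability.

Co-expression of two genes is measured as the Pearson correlation of their
coordinates in principal-component space, where the PCA is performed in
sample space (each gene is a point whose coordinates are its normalized
intensities across samples). The stability statistic asks how much that
correlation depends on the leading components: the correlation is
recomputed after removing the top 1, 2, ..., N components, giving
``cor_0 ... cor_N``, and combined as

    S = mean(cor_0, ..., cor_N) / max(cor_0, ..., cor_N)

A gene pair whose correlation is supported broadly across samples barely
moves when the dominant components are removed, so S is close to 1. A pair
whose correlation is driven by a few high-leverage samples (for example a
shared tissue or batch) collapses once the component carrying that signal
is removed, giving S near zero or negative. S is therefore a reliability
measure for the correlation coefficient itself.

Pairs with ``cor_0`` below 0.2 are conventionally discarded before
downstream analysis because the stability of a near-zero correlation is
uninformative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

__all__ = [
    "CoexpressionError",
    "DimensionalityError",
    "DegeneratePairError",
    "ExpressionMatrix",
    "PCBasis",
    "CoexpressionProfile",
    "PairProfileResult",
    "fit_pca",
    "pc_correlation",
    "stability_from_correlations",
    "stability_profile",
    "pairwise_profiles",
    "spearman_rank_correlation",
]


class CoexpressionError(ValueError):
    """Invalid input to a co-expression computation."""


class DimensionalityError(CoexpressionError):
    """Too few genes, samples, or retained components."""


class DegeneratePairError(CoexpressionError):
    """A gene has no variance in the relevant subspace."""


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of normalized expression intensities.

    ``values[i, j]`` is the intensity of ``gene_ids[i]`` in
    ``sample_ids[j]``. Values must be finite; at least 2 genes and 2
    samples are required. Genes with zero variance across samples are
    permitted in the container but are flagged so that pairwise analysis
    can exclude them.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        if self.values.ndim != 2:
            raise CoexpressionError("expression values must be a 2-D matrix")
        n_genes, n_samples = self.values.shape
        if n_genes < 2 or n_samples < 2:
            raise DimensionalityError(
                f"need at least 2 genes and 2 samples, got {n_genes} x {n_samples}"
            )
        if len(self.gene_ids) != n_genes:
            raise CoexpressionError("gene_ids length does not match matrix rows")
        if len(self.sample_ids) != n_samples:
            raise CoexpressionError("sample_ids length does not match matrix columns")
        if len(set(self.gene_ids)) != n_genes:
            raise CoexpressionError("gene_ids must be unique")
        if len(set(self.sample_ids)) != n_samples:
            raise CoexpressionError("sample_ids must be unique")
        if not np.all(np.isfinite(self.values)):
            raise CoexpressionError("expression values contain non-finite entries")
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def zero_variance_genes(self) -> list[str]:
        """Genes that are constant across samples (excluded from pairwise analysis)."""
        v = self.values.var(axis=1)
        return [g for g, var in zip(self.gene_ids, v) if var == 0.0]

    def to_tsv(self, path, comments: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in comments:
                fh.write(f"# {line}\n")
            fh.write("gene\t" + "\t".join(self.sample_ids) + "\n")
            for g, row in zip(self.gene_ids, self.values):
                fh.write(g + "\t" + "\t".join(f"{x:.6g}" for x in row) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
        return cls(df.to_numpy(dtype=float), list(df.index.astype(str)), list(df.columns.astype(str)))


@dataclass
class PCBasis:
    """Retained principal-component coordinates of genes in sample space.

    ``scores[i, k]`` is the coordinate of gene ``i`` on the k-th component
    (components ordered by decreasing explained variance). ``components``
    holds the component directions so the centered matrix can be
    reconstructed as ``scores @ components``.
    """

    scores: np.ndarray
    components: np.ndarray
    explained_fraction: np.ndarray
    variance_threshold: float
    gene_ids: list[str]
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def K(self) -> int:
        return self.scores.shape[1]

    def gene_scores(self, gene: str, drop_top: int = 0) -> np.ndarray:
        try:
            i = self._index[gene]
        except KeyError:
            raise KeyError(f"gene {gene!r} not present in the PC basis") from None
        return self.scores[i, drop_top:]


def fit_pca(
    expr: ExpressionMatrix,
    variance_threshold: float = 0.8,
    scale_samples: bool = False,
) -> PCBasis:
    """PCA of the gene cloud in sample space.

    Columns (samples) are mean-centered across genes before decomposition;
    unit-variance scaling of samples is off by default and available via
    ``scale_samples``. The number of retained components K is the smallest
    count whose cumulative explained variance reaches ``variance_threshold``
    (never below 2, never above the matrix rank).
    """
    if not (0.0 < variance_threshold <= 1.0):
        raise CoexpressionError(
            f"variance_threshold must be in (0, 1], got {variance_threshold}"
        )
    X = expr.values
    if scale_samples:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0.0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    pca = PCA(n_components=None, svd_solver="full")
    scores = pca.fit_transform(X)
    ev = pca.explained_variance_
    frac = pca.explained_variance_ratio_
    # effective rank: trim numerically-zero components
    tol = ev.max() * max(X.shape) * np.finfo(float).eps if ev.size else 0.0
    rank = max(int(np.sum(ev > tol)), 1)
    cum = np.cumsum(frac)
    K = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
    K = min(max(K, 2), rank) if rank >= 2 else 2
    K = min(K, scores.shape[1])
    return PCBasis(
        scores=scores[:, :K],
        components=pca.components_[:K],
        explained_fraction=frac[:K],
        variance_threshold=variance_threshold,
        gene_ids=list(expr.gene_ids),
    )


def _score_correlation(x: np.ndarray, y: np.ndarray) -> float:
    # correlation about the origin: per-component scores are centered over
    # genes already, and this form is invariant to the arbitrary sign of
    # each principal component (a centered Pearson on the coordinate
    # vectors would not be)
    vx = float(x @ x)
    vy = float(y @ y)
    if vx == 0.0 or vy == 0.0:
        raise DegeneratePairError("zero variance in the retained subspace")
    r = float(x @ y) / np.sqrt(vx * vy)
    return float(np.clip(r, -1.0, 1.0))


def pc_correlation(basis: PCBasis, gene_a: str, gene_b: str, drop_top: int = 0) -> float:
    """Correlation of two genes' scores on components drop_top+1 ... K.

    Computed about the origin of PC space, so the value is independent of
    component sign conventions; on the full basis it equals the
    correlation of the column-centered expression profiles.
    """
    if drop_top < 0:
        raise CoexpressionError(f"drop_top must be non-negative, got {drop_top}")
    if basis.K - drop_top < 2:
        raise DimensionalityError(
            f"dropping {drop_top} of {basis.K} components leaves fewer than 2 coordinates"
        )
    return _score_correlation(
        basis.gene_scores(gene_a, drop_top), basis.gene_scores(gene_b, drop_top)
    )


def stability_from_correlations(cor: Sequence[float]) -> float:
    """Stability S = mean(cor_0..cor_N) / cor_max.

    Isolated here so an alternate reading of the statistic is a one-line
    change. Returns NaN when cor_max is exactly zero (the measure is
    undefined there; such pairs never survive the cor_0 filter).
    """
    c = np.asarray(cor, dtype=float)
    cmax = float(c.max())
    if cmax == 0.0:
        return float("nan")
    return float(c.mean() / cmax)


@dataclass
class CoexpressionProfile:
    """Correlation trajectory cor_0..cor_N of a gene pair plus its stability."""

    gene_a: str
    gene_b: str
    cor: np.ndarray
    cor_max: float
    stability: float

    @property
    def cor_0(self) -> float:
        return float(self.cor[0])

    @property
    def N(self) -> int:
        return len(self.cor) - 1

    @property
    def pair(self) -> tuple[str, str]:
        return tuple(sorted((self.gene_a, self.gene_b)))


def stability_profile(basis: PCBasis, gene_a: str, gene_b: str, N: int = 10) -> CoexpressionProfile:
    """Compute cor_0..cor_N and the stability statistic for one gene pair."""
    if N < 1:
        raise CoexpressionError(f"N must be at least 1, got {N}")
    if basis.K <= N + 1:
        raise DimensionalityError(
            f"stability with N={N} needs more than {N + 1} retained components "
            f"but only {basis.K} are available; lower N or raise variance_threshold"
        )
    cor = np.array([pc_correlation(basis, gene_a, gene_b, drop_top=i) for i in range(N + 1)])
    cmax = float(cor.max())
    return CoexpressionProfile(
        gene_a=gene_a,
        gene_b=gene_b,
        cor=cor,
        cor_max=cmax,
        stability=stability_from_correlations(cor),
    )


@dataclass
class PairProfileResult:
    """Profiles for retained pairs plus drop bookkeeping."""

    profiles: list[CoexpressionProfile]
    n_below_min_cor: int
    n_degenerate: int

    @property
    def n_retained(self) -> int:
        return len(self.profiles)


def pairwise_profiles(
    basis: PCBasis,
    pairs: Iterable[tuple[str, str]],
    min_cor0: float = 0.2,
    N: int = 10,
) -> PairProfileResult:
    """Profiles for the requested gene pairs, filtering pairs with cor_0 < min_cor0.

    The threshold is a strict "less than": a pair at exactly ``min_cor0``
    is retained. Pairs whose genes have no variance in the retained
    subspace are dropped separately from the low-correlation tally.
    """
    profiles: list[CoexpressionProfile] = []
    n_low = 0
    n_degenerate = 0
    for gene_a, gene_b in pairs:
        try:
            cor0 = pc_correlation(basis, gene_a, gene_b, drop_top=0)
        except DegeneratePairError:
            n_degenerate += 1
            continue
        if cor0 < min_cor0:
            n_low += 1
            continue
        try:
            profiles.append(stability_profile(basis, gene_a, gene_b, N=N))
        except DegeneratePairError:
            n_degenerate += 1
    if n_low or n_degenerate:
        logger.info(
            "pairwise_profiles: dropped %d pairs below cor_0=%g and %d degenerate pairs",
            n_low, min_cor0, n_degenerate,
        )
    return PairProfileResult(profiles=profiles, n_below_min_cor=n_low, n_degenerate=n_degenerate)


def spearman_rank_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman's rank correlation with mid-ranks for ties.

    Returns (rho, p) where rho is the Pearson correlation of mid-ranks and
    p comes from the large-sample approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise CoexpressionError("x and y must have equal length")
    if x.size < 3:
        raise CoexpressionError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise CoexpressionError("correlation undefined for a constant vector")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)
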