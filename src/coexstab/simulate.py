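"""Synthetic expression, network and annotation data with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage can be tested against planted labels:

* **Robust co-expression.** Genes of a module share a Gaussian latent
  factor drawn independently per sample (gene = loading x factor +
  noise), so their correlation is supported by every sample.
* **Fragile co-expression.** A fragile pair shares a signal that is zero
  everywhere except in a small set of spike samples (the same samples
  for all fragile pairs, mimicking a tissue batch), where it takes a
  fixed amplitude. The pair's sample-space correlation is high, but it
  is carried entirely by those few samples.
* **Global background factors.** Every gene carries weak loadings on a
  handful of global factors representing pervasive batch/tissue
  structure. These factors, together with the spike, dominate the top
  principal components, so removing the top PCs strips the spike (and
  with it fragile correlations) while leaving module signals - which
  rank below the globals - intact. Without this background the module
  factors themselves would occupy the top PCs and robust pairs would
  lose their correlation too.
* **Planted hubs.** Each planted hub is wired to partners whose pair
  construction places the edge in the hub's category window:
  category 1 via a strong shared module factor (with partner-partner
  edges, making the hub intra-modular), category 2 via weak partner
  loadings on the hub's factor (star topology, inter-modular),
  categories 3 and 4 via spike-driven pairs of moderate and full
  amplitude respectively.
* **Annotations.** Category-enriched terms cover most of each category's
  planted hubs plus a small background rate; residue-call strings
  realize planted disorder fractions through runs of >= 30 calls;
  disease/essential flags are biased across construction pools so the
  disease and essential groups show lower correlation and higher
  stability, and disease classes differ in mean stability.

All outputs are deterministic given the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .coexpression import ExpressionMatrix
from .enrichment import NAMESPACES, TermSet
from .network import PPINetwork

__all__ = [
    "ConfigError",
    "SimulationConfig",
    "GroundTruth",
    "AnnotationTables",
    "generate_expression",
    "generate_network",
    "generate_annotations",
    "generate_all",
]


class ConfigError(ValueError):
    """A simulation-config field violates its constraints."""


def _default_planted_hubs() -> list[tuple[int, int]]:
    # few category-4 hubs: the phenomenon is rare but the code path must run
    return [(1, 16)] * 5 + [(2, 16)] * 5 + [(3, 16)] * 5 + [(4, 16)] * 2


@dataclass
class SimulationConfig:
    """Parameters of the synthetic data generator.

    The defaults define the standard study conditions: 2000 genes by 200
    samples, 10 robust modules of 8 genes, 60 fragile pairs spiking in 5
    shared samples at 10x the noise level, and 17 planted hubs of degree
    16 across the four categories.
    """

    n_genes: int = 2000
    n_samples: int = 200
    n_modules: int = 10
    module_size: int = 8
    n_fragile_pairs: int = 60
    spike_samples: int = 5
    signal_sd: float = 1.0
    spike_amplitude: float = 3.0
    noise_sd: float = 0.3
    edge_background_rate: float = 2e-4
    planted_hubs: list[tuple[int, int]] = field(default_factory=_default_planted_hubs)
    disorder_high_fraction: float = 0.3
    seed: int = 0
    # generator-shape parameters (see module docstring)
    n_global_factors: int = 10
    global_loading_sd: float = 0.087
    weak_partner_loading: float = 0.13
    weak_spike_amplitude: float = 1.7
    partner_edge_prob: float = 0.5
    protein_length_range: tuple[int, int] = (200, 600)

    def validate(self) -> None:
        for name in ("n_genes", "n_samples", "module_size", "spike_samples",
                     "signal_sd", "spike_amplitude"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("n_modules", "n_fragile_pairs", "noise_sd",
                     "n_global_factors", "global_loading_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative, got {getattr(self, name)}")
        for name in ("edge_background_rate", "disorder_high_fraction", "partner_edge_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be a probability in [0, 1], got {v}")
        if self.spike_samples >= self.n_samples:
            raise ConfigError(
                f"spike_samples ({self.spike_samples}) must be < n_samples ({self.n_samples})"
            )
        for cat, deg in self.planted_hubs:
            if cat not in (1, 2, 3, 4):
                raise ConfigError(f"planted_hubs category must be 1-4, got {cat}")
            if deg < 5:
                raise ConfigError(f"planted_hubs degree must be >= 5, got {deg}")
        needed = (
            self.n_modules * self.module_size
            + 2 * self.n_fragile_pairs
            + sum(1 + deg for _, deg in self.planted_hubs)
        )
        if needed > self.n_genes:
            raise ConfigError(
                f"n_genes ({self.n_genes}) too small for modules + fragile pairs + "
                f"planted hubs ({needed} genes needed)"
            )

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["planted_hubs"] = [list(t) for t in self.planted_hubs]
        d["protein_length_range"] = list(self.protein_length_range)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "planted_hubs" in d:
            d["planted_hubs"] = [tuple(t) for t in d["planted_hubs"]]
        if "protein_length_range" in d:
            d["protein_length_range"] = tuple(d["protein_length_range"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Planted labels for every generated entity."""

    pair_labels: dict[tuple[str, str], str] = field(default_factory=dict)
    hub_category: dict[str, int] = field(default_factory=dict)
    hub_partners: dict[str, list[str]] = field(default_factory=dict)
    term_category: dict[str, int] = field(default_factory=dict)
    disorder_fraction: dict[str, float] = field(default_factory=dict)
    disease: dict[str, bool] = field(default_factory=dict)
    essential: dict[str, bool] = field(default_factory=dict)
    disease_class: dict[str, str] = field(default_factory=dict)
    module_members: list[list[str]] = field(default_factory=list)
    fragile_pairs: list[tuple[str, str]] = field(default_factory=list)
    spike_sample_ids: list[str] = field(default_factory=list)
    # construction pool of each structured gene, used to bias annotations
    pool: dict[str, str] = field(default_factory=dict)

    def pairs_with_label(self, label: str) -> list[tuple[str, str]]:
        return [p for p, lab in self.pair_labels.items() if lab == label]

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("entity_type\tentity\tlabel\n")
            for (a, b), lab in sorted(self.pair_labels.items()):
                fh.write(f"pair\t{a}|{b}\t{lab}\n")
            for p, c in sorted(self.hub_category.items()):
                fh.write(f"hub\t{p}\t{c}\n")
            for t, c in sorted(self.term_category.items()):
                fh.write(f"term\t{t}\t{c}\n")


def _gene_id(i: int) -> str:
    return f"G{i:05d}"


def _protein_id(i: int) -> str:
    return f"P{i:05d}"


def protein_for_gene(gene: str) -> str:
    """Identity-style gene-to-protein mapping used by the generator."""
    return "P" + gene[1:]


def generate_expression(config: SimulationConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Generate the expression matrix and its planted ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, m = config.n_genes, config.n_samples
    X = rng.normal(0.0, config.noise_sd, (n, m))

    # weak global background structure on every gene
    factors = rng.normal(0.0, 1.0, (config.n_global_factors, m))
    loadings = rng.normal(0.0, config.global_loading_sd, (n, config.n_global_factors))
    X += loadings @ factors

    spike_idx = rng.choice(m, size=config.spike_samples, replace=False)
    spike = np.zeros(m)
    spike[spike_idx] = 1.0

    truth = GroundTruth()
    truth.spike_sample_ids = [f"S{j:04d}" for j in sorted(spike_idx)]
    g = 0

    def take(k: int) -> np.ndarray:
        nonlocal g
        idx = np.arange(g, g + k)
        g += k
        return idx

    # robust modules: all within-module pairs are robust
    for _ in range(config.n_modules):
        idx = take(config.module_size)
        f = rng.normal(0.0, config.signal_sd, m)
        load = rng.normal(1.0, 0.1, idx.size)
        X[idx] += load[:, None] * f
        members = [_gene_id(i) for i in idx]
        truth.module_members.append(members)
        for gene in members:
            truth.pool[gene] = "module"
        for a_i in range(len(members)):
            for b_i in range(a_i + 1, len(members)):
                pair = tuple(sorted((members[a_i], members[b_i])))
                truth.pair_labels[pair] = "robust"

    # fragile pairs: shared spike samples, per-pair sign
    for _ in range(config.n_fragile_pairs):
        idx = take(2)
        sign = rng.choice([-1.0, 1.0])
        X[idx] += sign * config.spike_amplitude * spike
        a, b = (_gene_id(i) for i in idx)
        truth.fragile_pairs.append((a, b))
        truth.pair_labels[tuple(sorted((a, b)))] = "fragile"
        truth.pool[a] = truth.pool[b] = "fragile"

    # planted hubs
    for cat, deg in config.planted_hubs:
        hub_i = take(1)[0]
        part_idx = take(deg)
        hub = _gene_id(hub_i)
        partners = [_gene_id(i) for i in part_idx]
        if cat == 1:
            f = rng.normal(0.0, config.signal_sd, m)
            X[hub_i] += f
            X[part_idx] += rng.normal(1.0, 0.05, deg)[:, None] * f
            edge_label, pool = "robust", "cat1"
        elif cat == 2:
            f = rng.normal(0.0, config.signal_sd, m)
            X[hub_i] += f
            X[part_idx] += (
                config.weak_partner_loading * rng.normal(1.0, 0.05, deg)[:, None] * f
            )
            edge_label, pool = "robust", "cat2"
        else:
            amp = config.spike_amplitude if cat == 4 else config.weak_spike_amplitude
            sign = rng.choice([-1.0, 1.0])
            X[hub_i] += sign * amp * spike
            X[part_idx] += sign * amp * spike
            edge_label, pool = "fragile", f"cat{cat}"
        truth.hub_category[protein_for_gene(hub)] = cat
        truth.hub_partners[protein_for_gene(hub)] = [protein_for_gene(p) for p in partners]
        truth.pool[hub] = pool
        for p in partners:
            truth.pool[p] = pool
            truth.pair_labels[tuple(sorted((hub, p)))] = edge_label
        if cat == 1:
            # partner-partner robust pairs (wired probabilistically later)
            for a_i in range(len(partners)):
                for b_i in range(a_i + 1, len(partners)):
                    pair = tuple(sorted((partners[a_i], partners[b_i])))
                    truth.pair_labels[pair] = "robust"

    gene_ids = [_gene_id(i) for i in range(n)]
    sample_ids = [f"S{j:04d}" for j in range(m)]
    expr = ExpressionMatrix(X, gene_ids, sample_ids)
    return expr, truth


def generate_network(config: SimulationConfig, truth: GroundTruth) -> PPINetwork:
    """Wire the PPI graph: modules as cliques, hub stars, fragile-pair edges,
    category-1 partner-partner edges, plus random background edges."""
    config.validate()
    rng = np.random.default_rng(config.seed + 1_000_003)
    edges: list[tuple[str, str]] = []

    for members in truth.module_members:
        prots = [protein_for_gene(g) for g in members]
        for i in range(len(prots)):
            for j in range(i + 1, len(prots)):
                edges.append((prots[i], prots[j]))

    for a, b in truth.fragile_pairs:
        edges.append((protein_for_gene(a), protein_for_gene(b)))

    for hub, partners in truth.hub_partners.items():
        for p in partners:
            edges.append((hub, p))
        if truth.hub_category[hub] == 1:
            for i in range(len(partners)):
                for j in range(i + 1, len(partners)):
                    if rng.random() < config.partner_edge_prob:
                        edges.append((partners[i], partners[j]))

    # sparse random background edges (mostly uncorrelated pairs)
    n = config.n_genes
    n_possible = n * (n - 1) // 2
    n_bg = rng.binomial(n_possible, config.edge_background_rate)
    seen = {tuple(sorted(e)) for e in edges}
    while n_bg > 0:
        i, j = rng.integers(0, n, 2)
        if i == j:
            continue
        e = tuple(sorted((_protein_id(i), _protein_id(j))))
        if e in seen:
            continue
        seen.add(e)
        edges.append(e)
        ga, gb = _gene_id(int(i)), _gene_id(int(j))
        truth.pair_labels.setdefault(tuple(sorted((ga, gb))), "null")
        n_bg -= 1

    proteins = {p for e in edges for p in e}
    mapping = {p: "G" + p[1:] for p in proteins}
    return PPINetwork(edges, mapping)


@dataclass
class AnnotationTables:
    """Generated annotation inputs: term sets, residue calls, protein labels."""

    terms: list[TermSet]
    residue_calls: dict[str, str]
    labels: pd.DataFrame

    def write(self, terms_path, calls_path, labels_path) -> None:
        from .enrichment import write_gmt

        write_gmt(self.terms, terms_path)
        with open(calls_path, "w") as fh:
            for p, s in sorted(self.residue_calls.items()):
                fh.write(f"{p}\t{s}\n")
        out = self.labels.reset_index().rename(columns={"index": "protein"})
        out["disease"] = out["disease"].astype(int)
        out["essential"] = out["essential"].astype(int)
        out.to_csv(labels_path, sep="\t", index=False)


# per-pool multipliers on disorder_high_fraction: categories 1 and 2 are
# disorder-rich, fragile-coexpression pools are disorder-poor
_DISORDER_MULT = {"cat1": 2.0, "cat2": 2.8, "cat3": 0.17, "cat4": 0.17,
                  "fragile": 0.5, "module": 1.0}
_DISEASE_PROB = {"cat2": 0.75, "cat1": 0.15, "module": 0.15,
                 "fragile": 0.15, "cat3": 0.15, "cat4": 0.15}
_ESSENTIAL_PROB = {"cat2": 0.6, "cat1": 0.15, "module": 0.15,
                   "fragile": 0.1, "cat3": 0.1, "cat4": 0.1}
# disease classes ordered by the stability of their construction pool
_CLASS_BY_POOL = {"module": "hematological", "cat1": "hematological",
                  "cat2": "metabolic",
                  "fragile": "neurological", "cat3": "neurological", "cat4": "neurological"}
_BACKGROUND_PROB = 0.05
_TERM_COVERAGE = 0.9
_TERM_BACKGROUND = 0.02


def _residue_string(rng: np.random.Generator, length: int, high: bool) -> str:
    """Build a residue-call string; high-disorder proteins get >=30-runs
    realizing a 0.35-0.6 disorder fraction, low-disorder proteins only
    short runs that the 30-residue rule zeroes out."""
    calls = np.zeros(length, dtype=int)
    if high:
        target = int(round(rng.uniform(0.35, 0.6) * length))
        n_runs = 1 if target < 70 else int(rng.integers(1, 3))
        lengths = []
        remaining = target
        for r in range(n_runs - 1):
            take = int(rng.integers(30, max(31, remaining - 30 * (n_runs - r - 1))))
            lengths.append(take)
            remaining -= take
        lengths.append(max(remaining, 30))
        pos = 0
        for run in lengths:
            run = min(run, length - pos)
            gap_max = length - pos - run
            start = pos + int(rng.integers(0, gap_max + 1)) if gap_max > 0 else pos
            calls[start:start + run] = 1
            pos = start + run + 1
            if pos >= length:
                break
    else:
        # short runs in disjoint 40-residue chunks so they can never
        # merge into a run the 30-residue rule would count
        n_chunks = length // 40
        if n_chunks:
            k = int(rng.integers(0, min(4, n_chunks + 1)))
            for chunk in rng.choice(n_chunks, size=k, replace=False):
                run = int(rng.integers(1, 30))
                start = int(chunk) * 40 + 1
                calls[start:start + run] = 1
    return "".join(map(str, calls))


def generate_annotations(config: SimulationConfig, truth: GroundTruth) -> AnnotationTables:
    """Emit term sets, residue-call strings and disease/essential labels."""
    config.validate()
    from .annotations import disorder_fraction

    rng = np.random.default_rng(config.seed + 2_000_003)
    proteins = sorted({protein_for_gene(g) for g in truth.pool} |
                      set(truth.hub_category) |
                      {p for ps in truth.hub_partners.values() for p in ps})
    # include some pure-background proteins so population sizes are realistic
    extra = [_protein_id(i) for i in range(config.n_genes)
             if _gene_id(i) not in truth.pool][: max(0, 200)]
    proteins = sorted(set(proteins) | set(extra))
    pool_of = {p: truth.pool.get("G" + p[1:], "background") for p in proteins}

    # ---- terms -------------------------------------------------------
    hubs_by_cat: dict[int, list[str]] = {}
    for hub, cat in truth.hub_category.items():
        hubs_by_cat.setdefault(cat, []).append(hub)
    terms: list[TermSet] = []
    for ns in NAMESPACES:
        # a broad term so most proteins are annotated (the population)
        root_members = {p for p in proteins if rng.random() < 0.95}
        terms.append(TermSet(f"TERM:{ns.upper()}_ROOT", ns, root_members))
        for cat, hubs in sorted(hubs_by_cat.items()):
            # category 1 is intra-modular: the planted complex members
            # (hub plus partners) all become category-1 hubs, so the term
            # annotates the whole complex, as a real complex term would
            members = list(hubs)
            if cat == 1:
                for h in hubs:
                    members.extend(truth.hub_partners[h])
            n_cov = max(1, math.ceil(_TERM_COVERAGE * len(members)))
            covered = {str(h) for h in rng.choice(members, size=n_cov, replace=False)}
            background = {
                p for p in proteins
                if p not in set(members) and rng.random() < _TERM_BACKGROUND
            }
            name = f"TERM:{ns.upper()}_CAT{cat}"
            terms.append(TermSet(name, ns, covered | background))
            truth.term_category[name] = cat
        for j in range(3):  # unplanted decoy terms
            members = {p for p in proteins if rng.random() < 0.05}
            if members:
                terms.append(TermSet(f"TERM:{ns.upper()}_RAND{j}", ns, members))

    # ---- disorder ----------------------------------------------------
    residue_calls: dict[str, str] = {}
    lo, hi = config.protein_length_range
    for p in proteins:
        mult = _DISORDER_MULT.get(pool_of[p], 1.0)
        p_high = min(1.0, mult * config.disorder_high_fraction)
        high = rng.random() < p_high
        length = int(rng.integers(lo, hi + 1))
        s = _residue_string(rng, length, high)
        residue_calls[p] = s
        truth.disorder_fraction[p] = disorder_fraction(s)

    # ---- disease / essential flags and classes -----------------------
    rows = []
    for p in proteins:
        pool = pool_of[p]
        disease = rng.random() < _DISEASE_PROB.get(pool, _BACKGROUND_PROB)
        essential = rng.random() < _ESSENTIAL_PROB.get(pool, _BACKGROUND_PROB)
        cls = _CLASS_BY_POOL.get(pool, "metabolic") if disease else ""
        truth.disease[p] = disease
        truth.essential[p] = essential
        if disease:
            truth.disease_class[p] = cls
        rows.append(
            {"protein": p, "disease": disease, "essential": essential, "disease_class": cls}
        )
    labels = pd.DataFrame(rows).set_index("protein")
    return AnnotationTables(terms=terms, residue_calls=residue_calls, labels=labels)


def generate_all(config: SimulationConfig):
    """Convenience: expression, truth, network and annotations in one call."""
    expr, truth = generate_expression(config)
    net = generate_network(config, truth)
    ann = generate_annotations(config, truth)
    return expr, truth, net, ann
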