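"""End-to-end orchestration: simulate/load -> co-expression -> network ->
topology -> enrichment -> annotations, with TSV/figure outputs and a
reproducibility manifest.

Every threshold of the analysis (cor_0 filter 0.2, category cutoffs
0.5/0.5, hub degree 5, 80% PCA variance, N = 10 removed components,
30% disorder threshold, enrichment alpha 0.01) is a named parameter
defaulting to its conventional value. Filtered entities (pairs below the
correlation floor, zero-variance genes, self-loops, unprofiled edges)
are all counted in the manifest so dataset bookkeeping is auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotations import (
    build_landscape,
    disorder_fraction,
    disease_class_summary,
    group_compare,
    interaction_type,
    read_labels_tsv,
    read_residue_calls_tsv,
)
from .coexpression import (
    ExpressionMatrix,
    fit_pca,
    pairwise_profiles,
    spearman_rank_correlation,
)
from .enrichment import NAMESPACES, enrich_categories, read_gmt, records_table
from .network import PPINetwork, classify_hubs, find_hubs, overlay, protein_averages
from .simulate import SimulationConfig, generate_all
from .topology import (
    betweenness_centrality_all,
    category_summaries,
    summaries_table,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

STAGES = ("coexpression", "network", "topology", "enrichment", "annotations", "report")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``synthetic`` or the input-path group
    (``expression_path`` + ``edges_path``) must be provided. Annotation
    paths are optional in file mode; the matching stages are skipped
    when absent.
    """

    outdir: str = "coexstab_run"
    synthetic: SimulationConfig | None = None
    expression_path: str | None = None
    edges_path: str | None = None
    mapping_path: str | None = None
    terms_path: str | None = None
    residue_calls_path: str | None = None
    labels_path: str | None = None

    variance_threshold: float = 0.8
    n_drop: int = 10
    min_cor0: float = 0.2
    scale_samples: bool = False
    cor_cutoff: float = 0.5
    stab_cutoff: float = 0.5
    min_degree: int = 5
    min_partners: int = 5
    alpha: float = 0.01
    disorder_min_run: int = 30
    disorder_threshold: float = 0.3
    bin_width: float = 0.1
    write_figures: bool = True
    log_level: str = "INFO"

    def validate(self) -> None:
        synthetic = self.synthetic is not None
        files = self.expression_path is not None or self.edges_path is not None
        if synthetic and files:
            raise ValueError("provide either a synthetic block or input paths, not both")
        if not synthetic:
            if self.expression_path is None or self.edges_path is None:
                raise ValueError("file mode needs both expression_path and edges_path")
        for name, lo, hi in (
            ("variance_threshold", 0.0, 1.0), ("min_cor0", -1.0, 1.0),
            ("cor_cutoff", 0.0, 1.0), ("stab_cutoff", 0.0, 1.0), ("alpha", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        for name in ("n_drop", "min_degree", "min_partners", "disorder_min_run"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be at least 1")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _plot_landscape(l2d, path: Path, title: str, overlay: bool = False) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grid = l2d.overlay_mean if overlay else l2d.counts.astype(float)
    grid = np.ma.masked_where(l2d.mask, grid)
    fig, ax = plt.subplots(figsize=(5, 4))
    cmap = plt.get_cmap("viridis").copy()
    cmap.set_bad("0.7")  # gray marks empty bins
    im = ax.imshow(
        grid.T, origin="lower", aspect="auto", cmap=cmap,
        extent=[l2d.cor_edges[0], l2d.cor_edges[-1], l2d.stab_edges[0], l2d.stab_edges[-1]],
    )
    ax.set_xlabel("co-expression correlation")
    ax.set_ylabel("co-expression stability")
    ax.set_title(title)
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def run_pipeline(config: RunConfig) -> dict:
    """Run every analysis stage and write outputs under ``config.outdir``.

    Returns the manifest (also written as ``manifest.json``): stage list,
    parameter values, drop tallies, summary statistics and output
    checksums. Deterministic given the same config.
    """
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "coexstab_version": __version__,
        "parameters": {
            k: v for k, v in asdict(config).items() if k != "synthetic"
        },
        "seed": config.synthetic.seed if config.synthetic else None,
        "stages": [],
        "tallies": {},
        "results": {},
        "outputs": {},
    }
    truth = None
    stage = "inputs"
    try:
        if config.synthetic is not None:
            expr, truth, net, ann = generate_all(config.synthetic)
            manifest["parameters"]["synthetic"] = {
                **{k: v for k, v in asdict(config.synthetic).items() if k != "planted_hubs"},
                "planted_hubs": [list(t) for t in config.synthetic.planted_hubs],
            }
            terms, residue_calls, labels = ann.terms, ann.residue_calls, ann.labels
            manifest["stages"].append("simulate")
        else:
            expr = ExpressionMatrix.from_tsv(config.expression_path)
            net = PPINetwork.from_edgelist_tsv(config.edges_path, config.mapping_path)
            terms = read_gmt(config.terms_path) if config.terms_path else None
            residue_calls = (
                read_residue_calls_tsv(config.residue_calls_path)
                if config.residue_calls_path else None
            )
            labels = read_labels_tsv(config.labels_path) if config.labels_path else None

        # ---- co-expression ------------------------------------------
        stage = "coexpression"
        basis = fit_pca(expr, config.variance_threshold, config.scale_samples)
        gene_pairs = sorted(
            {tuple(sorted((net.gene_of(a), net.gene_of(b)))) for a, b in net.graph.edges}
        )
        result = pairwise_profiles(basis, gene_pairs, config.min_cor0, config.n_drop)
        profiles = result.profiles
        manifest["tallies"].update(
            {
                "zero_variance_genes": len(expr.zero_variance_genes()),
                "pairs_requested": len(gene_pairs),
                "pairs_below_min_cor0": result.n_below_min_cor,
                "pairs_degenerate": result.n_degenerate,
                "pairs_retained": len(profiles),
                "retained_components": basis.K,
            }
        )
        prof_rows = []
        for p in profiles:
            row = {"gene_a": p.gene_a, "gene_b": p.gene_b}
            row.update({f"cor_{i}": c for i, c in enumerate(p.cor)})
            row.update({"cor_max": p.cor_max, "stability": p.stability})
            prof_rows.append(row)
        _write_tsv(pd.DataFrame(prof_rows), outdir / "pair_profiles.tsv")
        if len(profiles) >= 3:
            rho, pval = spearman_rank_correlation(
                [p.cor_0 for p in profiles], [p.stability for p in profiles]
            )
            manifest["results"]["spearman_cor_vs_stability"] = {"rho": rho, "p": pval}
        manifest["stages"].append(stage)

        # ---- network -------------------------------------------------
        stage = "network"
        ostats = overlay(net, profiles)
        manifest["tallies"].update(
            {
                "edges_total": ostats.n_edges,
                "edges_profiled": ostats.n_profiled,
                "edges_unprofiled": ostats.n_unprofiled,
                "proteins_covered": ostats.n_proteins_covered,
                "self_loops_dropped": net.n_self_loops_dropped,
                "duplicate_edges_dropped": net.n_duplicate_edges,
            }
        )
        summaries = protein_averages(net)
        hubs = find_hubs(net, config.min_degree)
        assignments = classify_hubs(
            net, config.cor_cutoff, config.stab_cutoff, config.min_partners
        )
        manifest["results"]["n_hubs"] = len(hubs)
        manifest["results"]["hub_category_counts"] = {
            c: sum(1 for a in assignments if c in a.categories) for c in (1, 2, 3, 4)
        }
        manifest["stages"].append(stage)

        # ---- topology ------------------------------------------------
        stage = "topology"
        pg = net.profiled_graph()
        bc = betweenness_centrality_all(pg)
        import networkx as nx

        cc = nx.clustering(pg)
        for s in summaries:
            s.clustering_coefficient = float(cc.get(s.protein, 0.0))
            s.betweenness = float(bc.get(s.protein, 0.0))
        sum_df = pd.DataFrame(
            [
                {
                    "protein": s.protein, "degree": s.degree,
                    "avg_cor": s.avg_cor, "avg_stab": s.avg_stab,
                    "clustering_coefficient": s.clustering_coefficient,
                    "betweenness": s.betweenness,
                }
                for s in summaries
            ]
        )
        assign_by_protein = {a.protein: a for a in assignments}
        sum_df["categories"] = [
            ",".join(map(str, sorted(assign_by_protein[p].categories)))
            if p in assign_by_protein else ""
            for p in sum_df["protein"]
        ]
        sum_df["dominant_category"] = [
            assign_by_protein[p].dominant_category if p in assign_by_protein else ""
            for p in sum_df["protein"]
        ]
        _write_tsv(sum_df, outdir / "protein_summaries.tsv")
        cat_rows = category_summaries(assignments, summaries)
        _write_tsv(summaries_table(cat_rows), outdir / "category_topology.tsv")
        manifest["stages"].append(stage)

        # ---- enrichment ----------------------------------------------
        stage = "enrichment"
        if terms:
            profiled_proteins = {
                p for p in net.graph.nodes if net.profiled_partners(p)
            }
            all_records = []
            for ns in NAMESPACES:
                if any(t.namespace == ns for t in terms):
                    all_records.extend(
                        enrich_categories(
                            assignments, terms, ns, profiled_proteins, config.alpha
                        )
                    )
            _write_tsv(records_table(all_records), outdir / "enrichment.tsv")
            manifest["results"]["n_significant_terms"] = sum(
                r.significant for r in all_records
            )
            manifest["stages"].append(stage)

        # ---- annotations ---------------------------------------------
        stage = "annotations"
        landscape = build_landscape(
            [(p.cor_0, p.stability) for p in profiles], config.bin_width
        )
        landscape.counts_table().to_csv(outdir / "landscape_interactions.tsv", sep="\t")
        protein_landscape = build_landscape(
            [(s.avg_cor, s.avg_stab) for s in summaries], config.bin_width
        )
        protein_landscape.counts_table().to_csv(outdir / "landscape_proteins.tsv", sep="\t")
        figures = {
            "landscape_interactions.png": (landscape, "Interactions", False),
            "landscape_proteins.png": (protein_landscape, "Proteins", False),
        }
        if residue_calls:
            fracs = {
                p: disorder_fraction(s, config.disorder_min_run)
                for p, s in residue_calls.items()
            }
            itype_rows = []
            for a, b, data in net.graph.edges(data=True):
                prof = data.get("profile")
                if prof is None or a not in fracs or b not in fracs:
                    continue
                itype_rows.append(
                    {
                        "protein_a": a, "protein_b": b,
                        "cor": prof.cor_0, "stability": prof.stability,
                        "interaction_type": interaction_type(
                            fracs[a], fracs[b], config.disorder_threshold
                        ),
                    }
                )
            itype_df = pd.DataFrame(itype_rows)
            _write_tsv(itype_df, outdir / "interaction_types.tsv")
            manifest["results"]["interaction_type_counts"] = (
                itype_df["interaction_type"].value_counts().to_dict()
                if not itype_df.empty else {}
            )
            disorder_overlay = build_landscape(
                [
                    (s.avg_cor, s.avg_stab, fracs[s.protein])
                    for s in summaries if s.protein in fracs
                ],
                config.bin_width,
            )
            figures["landscape_disorder.png"] = (disorder_overlay, "Mean disorder fraction", True)
        if labels is not None:
            comparisons = {}
            for grouping in ("disease", "essential", "disease_essential"):
                cmp_res = group_compare(summaries, labels, grouping)
                comparisons[grouping] = {
                    "groups": {
                        g.name: {"n": g.n, "mean_avg_cor": g.mean_cor, "mean_avg_stab": g.mean_stab}
                        for g in cmp_res.groups.values()
                    },
                    "pairwise_p": {
                        f"{a}|{b}": p for (a, b), p in cmp_res.pairwise_p.items()
                    },
                }
            manifest["results"]["group_comparisons"] = comparisons
            class_df = disease_class_summary(summaries, labels)
            _write_tsv(class_df, outdir / "disease_class_summary.tsv")
        manifest["stages"].append(stage)

        # ---- report ---------------------------------------------------
        stage = "report"
        if config.write_figures:
            for fname, (l2d, title, is_overlay) in figures.items():
                _plot_landscape(l2d, outdir / fname, title, is_overlay)
        if truth is not None:
            truth.write_tsv(outdir / "ground_truth.tsv")
            recovered = 0
            for hub, cat in truth.hub_category.items():
                a = assign_by_protein.get(hub)
                if a is not None and cat in a.categories:
                    recovered += 1
            manifest["results"]["planted_hub_recovery"] = {
                "recovered": recovered,
                "planted": len(truth.hub_category),
            }
        manifest["stages"].append(stage)
    except Exception as exc:  # noqa: BLE001 - annotate failing stage
        manifest["failed_stage"] = stage
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise PipelineError(stage, exc) from exc

    for path in sorted(outdir.iterdir()):
        if path.is_file() and path.name != "manifest.json":
            manifest["outputs"][path.name] = _sha256(path)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
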