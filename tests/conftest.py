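import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from coexstab import ExpressionMatrix, RunConfig, SimulationConfig, run_pipeline

SEEDS = (1, 2, 3, 4, 5)


@pytest.fixture(scope="session")
def default_runs(tmp_path_factory) -> dict[int, Path]:
    """Full pipeline on the default synthetic conditions, one run per seed.

    Shared across tests; figure rendering is skipped here since the
    downstream assertions read the TSV/JSON outputs.
    """
    base = tmp_path_factory.mktemp("runs")
    out = {}
    for seed in SEEDS:
        outdir = base / f"seed{seed}"
        run_pipeline(
            RunConfig(
                outdir=str(outdir),
                synthetic=SimulationConfig(seed=seed),
                write_figures=False,
            )
        )
        out[seed] = outdir
    return out


def load_manifest(outdir: Path) -> dict:
    return json.loads((outdir / "manifest.json").read_text())


def load_profiles(outdir: Path) -> pd.DataFrame:
    return pd.read_csv(outdir / "pair_profiles.tsv", sep="\t")


def load_truth_pairs(outdir: Path) -> dict[tuple[str, str], str]:
    labels = {}
    with open(outdir / "ground_truth.tsv") as fh:
        next(fh)
        for line in fh:
            etype, entity, label = line.rstrip("\n").split("\t")
            if etype == "pair":
                a, b = entity.split("|")
                labels[(a, b)] = label
    return labels


def load_truth_hubs(outdir: Path) -> dict[str, int]:
    hubs = {}
    with open(outdir / "ground_truth.tsv") as fh:
        next(fh)
        for line in fh:
            etype, entity, label = line.rstrip("\n").split("\t")
            if etype == "hub":
                hubs[entity] = int(label)
    return hubs


@pytest.fixture
def small_expr() -> ExpressionMatrix:
    """6 genes x 5 samples with planted structure: genes 0/1 duplicated,
    gene 2 the exact negation of gene 0. Rows sum to zero per sample so
    column centering leaves the planted relations intact."""
    rng = np.random.default_rng(42)
    v, w, x = rng.normal(0, 1, (3, 5))
    values = np.vstack([v, v, -v, w, x, -(v + w + x)])
    return ExpressionMatrix(values, [f"g{i}" for i in range(6)], [f"s{j}" for j in range(5)])
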