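# coexstab

Gene co-expression **stability** analysis of protein–protein interaction
(PPI) networks.

Co-expression correlation between two genes is widely used to interpret
PPI networks — for example to split hub proteins into transient ("date")
and obligate ("party") hubs — but the plain Pearson correlation is easily
biased by a handful of high-leverage samples: two genes expressed in the
same tissue can look strongly co-expressed with no functional
relationship. `coexstab` implements a reliability measure for the
correlation coefficient and the downstream network analysis built on it,
for computational biologists studying interactomes alongside large
expression compendia.

## The statistic

PCA is performed in sample space, so each gene has a score vector over
the principal components that explain 80% of the expression variance.
The co-expression correlation of a gene pair is the correlation of their
score vectors (`cor_0`); it is then recomputed after removing the top
1, 2, …, N components (`cor_1 … cor_N`, N = 10 by default), and the
stability is

```
S = mean(cor_0, …, cor_N) / max(cor_0, …, cor_N)
```

A correlation supported broadly across samples barely changes when the
dominant components are removed (S ≈ 1); a "fragile" correlation carried
by a few samples collapses as soon as the component holding that signal
is dropped (S ≈ 0 or negative). Pairs with `cor_0 < 0.2` are discarded.

On the PPI network, each protein gets an average correlation r̄ and
average stability S̄ over its profiled partners. Hubs (≥ 5 partners) are
classified by where their partner edges fall against 0.5/0.5 cutoffs:

| category | correlation | stability | interpretation |
|---|---|---|---|
| 1 | > 0.5 | > 0.5 | obligate / intra-modular (complex subunits) |
| 2 | ≤ 0.5 | > 0.5 | transient / inter-modular |
| 3 | ≤ 0.5 | ≤ 0.5 | fragile co-expression — a distinct class |
| 4 | > 0.5 | ≤ 0.5 | rare |

Categories are then characterized by clustering coefficient and
normalized betweenness centrality (mean ± SE per category),
hypergeometric term enrichment (p < 0.01, per namespace), intrinsic
disorder (fraction of residues in runs of ≥ 30 predicted-disordered
calls; interactions typed ordered/mixed/disordered at a 30% threshold),
and disease/essential group comparisons (two-sided Wilcoxon rank-sum).

Because the original expression compendium, interactome and annotation
resources are external, the package ships a synthetic-data generator
that plants all of this structure — robust modules, fragile spike-driven
pairs, hubs of each category, enriched terms, disorder and disease
labels — with known ground truth, so every stage is testable end to end.

## Worked example

```
$ coexstab all --seed 1 --outdir run1
pipeline complete: stages=['simulate', 'coexpression', 'network', 'topology',
'enrichment', 'annotations', 'report'] outputs in run1
```

`run1/` then contains `pair_profiles.tsv` (cor_0…cor_10, cor_max,
stability per retained pair), `protein_summaries.tsv`,
`category_topology.tsv`, `enrichment.tsv`, `interaction_types.tsv`,
group and disease-class tables, landscape heat maps (gray bins are
empty) and a `manifest.json` recording parameters, drop tallies and
output checksums. From the seed-1 manifest:

```
"pairs_requested": 1307, "pairs_below_min_cor0": 326, "pairs_retained": 981
"planted_hub_recovery": {"recovered": 17, "planted": 17}
```

981 of the network's 1307 gene pairs survive the `cor_0 ≥ 0.2` filter,
and all 17 planted hubs are assigned their planted category. In
`pair_profiles.tsv` a planted fragile pair looks like

```
gene_a   gene_b   cor_0   cor_1   ...  stability
G00082   G00083   0.692   0.175   ...  0.131
```

— strong correlation (0.69) that collapses the moment the first
principal component is removed, hence the low stability: exactly the
bias the statistic is designed to expose. A robust module pair such as
`G00000–G00001` keeps `cor_i ≈ 0.86` throughout and scores S ≈ 0.97.

The same steps are available as separate subcommands (`simulate`,
`coexpr`, `classify`, `enrich`, `annotate`) and as library functions
(`coexstab.fit_pca`, `stability_profile`, `classify_hubs`, …).

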