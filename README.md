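# degrerank

Machine-learning refinement of differential gene expression analysis:
re-rank a list of differentially expressed genes (DEGs) by how often a
minimum-redundancy-maximum-relevance (MRMR) selector picks them inside
repeated stratified cross-validation, then extract a minimal gene
signature that discriminates two phenotype groups.

Standard two-group differential expression (fold change + FDR-adjusted
p-value) typically returns a hundred or more genes, many of them highly
inter-correlated — far too many, and too redundant, to serve directly as
a biomarker panel. `degrerank` is for analysts who already have such a
DEG list (from limma, or the built-in Welch test) for a binary outcome
such as survival vs. non-survival, and want a short, non-redundant,
data-driven marker panel with an honest cross-validated performance
estimate.

## Method

Starting from a log2 expression matrix restricted to the DEGs, each of
R runs partitions the samples into K stratified folds. In every
iteration the selector sees only the K−1 training folds and greedily
picks genes maximizing

    argmax_{x_j ∉ S}  f(x_j, y) − (1/|S|²) Σ_{l ∈ S} g(x_j, x_l)

where f is a relevance function (folded ROC AUC by default; χ² and the
two-group F-statistic are alternatives), g(x_j, x_l) = |r| is the
absolute Pearson correlation with the already-selected set S, and the
1/|S|² divisor down-weights the redundancy penalty as S grows (1/|S|,
the conventional mean-redundancy form, is a config option). A classifier
(L2 logistic regression, 100-tree random forest, or 100-round gradient
boosting) is fitted on the selected genes and scored on the held-out
fold with ACC, Sn, Sp, MCC and AUC, plus a vertically averaged ROC
curve.

A gene's **importance score** is the fraction of the R·K iterations in
which it was selected (selected in 85 of 100 iterations → 0.85). The
**minimal signature** is the smallest top-k panel of this re-ranking
whose mean AUC and high-specificity partial AUC (specificity > 0.80)
are both within ε of the best over the searched k range.

A synthetic-cohort generator with planted differential blocks (one
latent factor per block → strong within-block correlation, shared mean
shift) provides ground truth for every stage.

## Worked example

```python
from degrerank import (SyntheticConfig, simulate_expression, build_deg_table,
                       filter_degs, CVConfig, run_repeated_cv,
                       importance_scores, rank_by_importance, minimal_signature)

cfg = SyntheticConfig(n_samples=200, n_positive=28, n_genes=500,
                      n_blocks=5, block_size=5, effect_size=2.0,
                      within_block_correlation=0.9, seed=1)
m, y, truth = simulate_expression(cfg)

degs = filter_degs(build_deg_table(m, y))          # |FC| >= 1.5, adj-p <= 0.05
sub = m.subset_genes(degs["gene_id"])
cv = CVConfig(n_runs=10, n_folds=10, k_grid=(5,), base_seed=1)
res = run_repeated_cv(sub, y, cv)                   # 100 train/test iterations
imp = importance_scores(res, "logistic_l2", "mrmr_auc", 5, gene_ids=sub.gene_ids)
ranked = rank_by_importance(imp)
sig = minimal_signature(m, y, ranked, range(1, 11), cv)
```

This prints (`res.report`, top of the ranking, and the chosen panel):

```
27 of 500 genes pass |FC| >= 1.5, adj-p <= 0.05
 classifier selector  k   acc    sn    sp   mcc   auc
logistic_l2 mrmr_auc  5 0.984 0.917 0.996 0.936 0.999
top 5 by selection frequency: G00010 (0.97), G00013 (0.83), G00023 (0.78),
                              G00005 (0.74), G00014 (0.35)
minimal signature: k=3, genes=['G00010', 'G00013', 'G00023']
```

The cohort plants five differential blocks of five tightly correlated
genes each; the DEG filter recovers the block genes, MRMR's redundancy
penalty spreads the selections across distinct blocks instead of
re-picking correlated copies, and the selection-frequency ranking
concentrates on one representative per strong block — so three genes
already saturate the ROC curve and the search stops there.

## Command line

Every stage is also a subcommand of the `degrerank` console script
(`simulate`, `de`, `rerank`, `signature`, `evaluate`, `run-all`), driven
by flags or a flat YAML config; all outputs are TSV/JSON-lines plus a
manifest with seeds and input checksums:

```sh
degrerank run-all --seed 1 --out results/ --n-genes 2000 --k 5
```

Identical seed and inputs give byte-identical output tables.

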