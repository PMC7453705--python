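# Methods

## Problem setting

Given a log2-scale expression matrix (genes × samples, gcRMA-style
normalized upstream; this package performs no normalization) and a
binary phenotype with a minority positive class (the event of interest,
e.g. non-survival), the pipeline (1) identifies differentially
expressed genes (DEGs), (2) re-ranks them by selection frequency under
repeated cross-validated MRMR feature selection, and (3) searches the
re-ranking for a minimal discriminative panel.

## Differential expression stage

Per gene, the log2 fold change is the positive-class mean minus the
negative-class mean; the signed linear fold change is
`sign(log_fc) · 2^|log_fc|` (so |FC| ≥ 1 always, FC = +1 at log_fc = 0,
and negative FC encodes down-regulation in the positive class). The
built-in test is Welch's unequal-variance two-sided t-test; genes with
zero variance in both groups get p = 1 (equal means) or p = 0 (unequal).
Multiplicity is handled by Benjamini–Hochberg step-up adjustment
(statsmodels). The DEG filter keeps |FC| ≥ 1.5 and adjusted p ≤ 0.05,
both inclusive.

Welch's t is a deliberate stand-in for moderated-t pipelines such as
limma: variance moderation matters most at very small n, and users with
a real limma table can import it via `import_deg_table` (fold change
and log fold change are reconstructed from one another and checked for
consistency at 1e-6 when both are present). Empirical-Bayes moderation
is out of scope.

## MRMR selection

Greedy forward selection over candidate genes: step 1 takes the argmax
of relevance (the redundancy term is defined as 0 for the empty set);
step t+1 takes

    argmax_j  f(x_j, y) − (1/|S|^d) Σ_{l∈S} |r(x_j, x_l)|

with d = 2 by default and d = 1 (`redundancy_norm="cardinality"`, the
conventional mean-redundancy MRMR) available. The squared divisor
shrinks the redundancy penalty faster as the panel grows; both variants
are tested against a brute-force stepwise maximizer, so the choice is a
modelling knob, not an implementation detail.

Relevance functions:

- **auc** (default): Mann–Whitney rank AUC of the raw feature against
  the positive class, ties at half weight, folded to max(a, 1−a) so
  down-regulated markers are not penalized for ranking in reverse
  (`fold_auc=False` exposes the raw directional AUC).
- **chi2**: the feature is shifted by −min(x) to be non-negative, then
  the χ² statistic of per-class feature sums against class-frequency
  expectations (scikit-learn's convention) is used. Shift-invariant by
  construction; an all-zero shifted feature scores 0.
- **fstat**: two-group one-way ANOVA F (equals the squared pooled-
  variance t). Zero within-group variance yields 0 for equal means and
  a cap of 1e12 for unequal means.

Redundancy is |Pearson r| (a constant vector has redundancy 0 with
everything). The absolute value is used because anti-correlated genes
(up- vs down-regulated clusters) are just as redundant as correlated
ones; signed r is available in `redundancy_pearson`. Ties in the
objective break by candidate order, making selection fully
deterministic. A 100-tree random-forest importance ranking (`rffi`) is
provided as the standard comparator selector.

## Repeated cross-validated re-ranking

R runs (default 10) of stratified K-fold CV (default 10); the per-run
fold seed is `base_seed + run`, so runs are independent but the whole
procedure is reproducible from one integer. Stratification delegates to
scikit-learn's `StratifiedKFold` (per-fold positive counts within one
of the proportional share); K may not exceed the minority-class count.

In each iteration the selector sees only the training folds (the greedy
trace is nested, so one length-max(k) run yields every top-k prefix);
the classifier — L2 logistic regression (scikit-learn defaults, the
package's primary model), 100-tree random forest, or 100-round gradient
boosting — is fitted on the training samples restricted to the selected
genes and scored on the held-out fold. Hard labels use the 0.5
probability threshold; AUC uses the predicted positive-class
probability. Metrics (ACC, Sn on the positive class, Sp, MCC with the
0-on-degenerate-marginal convention, rank AUC) are averaged unweighted
over the R·K iterations (fold sizes differ by at most one sample, so
weighting is immaterial).

ROC curves are averaged vertically: each per-iteration curve is treated
as a right-continuous step function of FPR and evaluated on a fixed
101-point FPR grid; the mean TPR per grid point defines the averaged
curve and its trapezoidal AUC. The value at FPR = 0 is the mean of the
curves' TPR at zero FPR (it is not clamped to 0, so averaging a
degenerate perfect curve with the diagonal gives (f+1)/2 as it should).
Model AUC distributions are compared with a two-sided Mann–Whitney U
test (exact when both sides have ≤ 12 untied values, tie-corrected
normal approximation otherwise; identical constant samples give p = 1).

The importance score of a gene is `count / (R·K)` where count is the
number of iterations whose selected set contained it; counts over all
genes sum to k·R·K by construction.

## Minimal-signature search

Genes with non-zero importance are ranked by score (ties
lexicographically by gene id). For each k in the searched range the
top-k panel is evaluated by repeated CV with no in-fold selection, and
two summaries are recorded: mean AUC, and partial AUC over FPR ≤ 0.20
(specificity > 0.80, the leftmost ROC region where competitive
clinical models are distinguished), normalized by its maximum possible
area so it lives in [0, 1]. The chosen size is the smallest k whose
mean AUC and partial AUC are both within ε (default 0.005) of their
respective maxima — an operationalization of "no further improvement in
the ROC curve". When the two optima disagree by more than ε, no k
satisfies both and the search falls back to the mean-AUC rule alone.
The chosen panel is then re-evaluated with every configured classifier.
`compare_rankings` evaluates several rankings' top-k panels under the
same CV partitions (shared seed) for a paired comparison and reports
pairwise overlaps.

## Synthetic cohorts

The generator emulates a normalized microarray cohort for a
rare-outcome study. Defaults mirror a 199-sample cohort with 28 events
and a 10 000-gene transcriptome: per-gene log2 expression is Gaussian
around baseline 6.0 with SD 1.0. Informative structure comes in
*blocks*: each block's genes share one latent factor,
`x = √ρ·z + √(1−ρ)·ε`, giving exact pairwise correlation ρ (default
0.9, matching tightly co-expressed DEG clusters), and every gene of a
block receives the same class mean shift of `effect_size · noise_sd`
(default 2 SD) — correlated copies are genuinely differential, as real
co-expressed DEGs are, which makes MRMR-vs-relevance comparisons fair.
Defaults chosen once and fixed: 5 blocks of 5 genes, and
`direction_mix = 0.2` (one block in five down-regulated, echoing the
typical minority of down-regulated top DEGs and the separate up/down
correlation clusters seen in real cohorts).

What the generator does **not** model: count-based (negative binomial)
RNA-seq noise, batch effects, missing values, heavy-tailed per-gene
variances, or correlation between blocks. Tests passing on these
cohorts therefore demonstrate the machinery (recovery, ranking,
no-leakage, calibration under the null) — not performance on any real
dataset.

## Numerical and design choices

- All randomness flows from integer seeds; per-iteration classifier
  seeds are derived as `(base_seed·9973 + run·101 + fold) mod (2³¹−1)`.
  Identical inputs and seeds give byte-identical output tables (the CLI
  manifest alone carries a timestamp).
- Relevance/redundancy are computed vectorized (rank-based AUC;
  correlations via normalized dot products); the greedy step keeps a
  running redundancy sum per candidate, so selection is O(k·p·n).
- TSV output uses up to 17 significant digits for the expression matrix
  (lossless float round-trip) and 10 for derived reports.
- Degenerate inputs are defined, not crashed on: constant features
  (AUC 0.5, χ² 0, redundancy 0), zero-variance groups (capped F,
  p ∈ {0, 1} for Welch), empty selections (importance 0 retained).
- Test problem sizes are scaled (hundreds of genes, tens-to-hundreds of
  samples) so the full suite and the acceptance script run in minutes;
  the statistical properties asserted (recovery rates, null bands,
  oracle equivalence) are size-stable, and the cohort-scale stratified
  allocation (199/28/10-fold) is checked explicitly.

## Known limitations

- Welch's t is less powerful than moderated-t at very small group
  sizes; import a limma table when that matters.
- Selection-frequency scores depend on the chosen per-fold k; the
  package reports them per (classifier, selector, k) and does not
  aggregate across k.
- The ε rule for the signature size is an operationalization of visual
  ROC inspection; its default (0.005) is conservative but arbitrary and
  should be varied in sensitivity analyses.
- The Mann–Whitney comparison of per-run AUC summaries treats runs as
  exchangeable; runs share samples, so p-values are heuristic, as in
  any repeated-CV comparison.
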