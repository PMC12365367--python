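# Methods

`pairedsc` implements a paired case/control single-cell transcriptomics
analysis for cohorts of matched patient/control PBMC samples annotated with
a fixed cell-type vocabulary. Every stage is driven by one idea: *each
case/control pair is an independent experiment*, and evidence is aggregated
across pairs by replication rather than by pooling cells.

## Normalization and fold changes

Counts are library-size normalized per cell, `x = ln(1 + c/T * s)` with
scale factor `s = 1e4`. The per-pair, per-cell-type fold change de-logs the
normalized values and compares group means with a pseudocount:

```
log2FC = log2( (mean_case[exp(x) - 1] + 1) / (mean_ctrl[exp(x) - 1] + 1) )
```

Positive values mean higher expression in the case sample. The pseudocount
of 1 (on the counts-per-10k scale) bounds the statistic at zero expression
and shrinks fold changes of weakly expressed genes toward 0; at a baseline
of ~5-20 CP10K a planted 2x effect realizes ~0.9-0.97 on the log2 scale
rather than 1.0. This estimator is a documented convention: the exact
estimator of the upstream single-cell toolkits varies between versions, and
any sign-correct, zero-bounded choice supports the replication logic
identically. A gene with zero counts on both sides of a pair is flagged
`not_expressed` (a sentinel) rather than assigned the vacuous `log2(1/1)=0`.

## Per-pair differential expression and replication

Within each (pair, cell type) with at least `min_cells = 3` cells on both
sides, genes are tested with a two-sided Wilcoxon rank-sum test on the
normalized values: exact enumeration when both sides have <= 25 cells and
the gene has no ties, otherwise the normal approximation with midranks, tie
correction and continuity correction (an all-tied gene yields p = 1).
Benjamini-Hochberg correction runs across the genes tested within that
(pair, cell type) only — this is the scope under which "FDR < 0.05 in at
least two pairs" is meaningful. No expression-fraction or fold-change
prefilter is applied; only the `not_expressed` status and `min_cells`
gate testing.

A (gene, cell type) is called replicated-DE "up" when at least
`min_supporting_pairs = 2` pairs reach FDR < 0.05 with positive log2FC
(symmetrically "down"). If both directions independently meet the support
threshold the call is "none": the replication rule is meant to certify a
consistent direction. Opposite-direction genes are those called up in at
least one cell type and down in at least one other. Ancestry concordance is
the Pearson correlation between two patient groups' mean per-gene log2FC
vectors within a cell type, over genes observed in both; the analysis
driver restricts it to replicated-DE genes, since over mostly-null genes
the correlation measures noise, not biology.

## Fold-change matrix and cell-type importance

The matrix has one row per (gene, pair) and one column per cell type.
Entries observed in the pairwise DE stage pass through; entries missing for
a (gene, pair, cell type) — insufficient cells, or the gene unobserved in
that pair — are imputed with the mean log2FC of the same (gene, cell type)
across the pairs that observed it; a (gene, cell type) with no observed
donor at all is assigned exactly 0. The rules are total: the assembled
matrix has no missing entries, and per-entry provenance
(`observed` / `imputed_mean` / `zero_not_expressed`) is retained.

A `RandomForestRegressor` (100 trees, unlimited depth, min_samples_split 2,
random_state 42) is trained on an 0.8/0.2 train-test split, with 5-fold CV
MSE (mean +/- SD) reported on the training split and MSE on the held-out
split. **Regression target.** The target is deliberately configurable
because the scientific question — "which cell types' expression changes
carry the disease signal?" — does not fix it. The default response for row
(gene, pair) is the pair's *all-cells pseudobulk log2FC* of that gene,
computed ignoring cell-type labels; feature importance then measures how
much each cell type's fold change explains the overall per-gene disease
effect. Normalized impurity importances rank the cell types; the cumulative
importance of the top k is their sum. Sex-stratified runs refit on the row
subset belonging to female or male pairs, sharing the assembled matrix.

**Permutation significance.** Each feature column of the held-out split is
shuffled `n_perm` times (default 1000) against the fitted model, and the
p-value is the proportion of shuffles in which the model's held-out score
is at least the unshuffled score — equivalently, in which the importance
drop is <= 0, ties included. Stored p-values live on the grid
{0, 1/n_perm, ..., 1}; a stored 0 is displayed as "<1/n_perm" (e.g.
"<0.001" at 1000 permutations). A constant feature never changes the
predictions, so its p is exactly 1. Two caveats are worth stating plainly:

* This proportion is a *descriptive screen*, not a calibrated test.
  Without refitting the model per permutation, the null distribution of the
  score drop for an uninformative feature concentrates near 0, so its
  p-values cluster around 0.5-1 instead of spreading uniformly. Calibrated
  alternatives (permuting the response and refitting per permutation) cost
  a full forest fit per permutation and answer a slightly different
  question.
* Under the pseudobulk-response target, *every* cell type's column carries
  some genuine signal — each cell type's cells contribute to the all-cells
  average — so even cell types without planted effects can reach small
  p-values. In the planted-recovery experiments the planted types are
  separated by rank, not by p-value alone.

## Co-expression modules

The network stage takes the replicated-DE genes, keeps those detected
(total count > 0) in every sample, and builds observations as
(sample x cell type) pseudobulk profiles over the cell types informative in
every pair; correlating module summaries simultaneously with cell-type
one-hots, sex and disease requires exactly this observation unit. The
signed adjacency is `a_ij = ((1 + r_ij)/2)^beta` with soft power beta = 6,
and the topological overlap is

```
TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)
```

with connectivities `k` excluding the diagonal. Modules are cut from the
average-linkage dendrogram of `1 - TOM` by an adaptive variant of dynamic
tree cut: the cut height (capped at 0.99 of the top merge) is chosen to
maximize the number of branches of size >= `min_module_size` (ties resolve
to the highest such cut), and each branch is then recursively sub-split
when, capped at (1 - gap) of the branch's own top merge height, the same
rule still yields two or more large branches. `deep_split` in 0-4 maps to
gap fractions 0.40/0.30/0.20/0.10/0.05 (default 2 -> 0.20). This replaces
the hybrid PAM-like assignment stage of the reference dynamic tree cut with
a simpler rule that is deterministic and directly testable; genes in
branches below the size floor are "unassigned" (the grey set). A fixed
fraction of the top height alone is not usable because average linkage
chains weakly connected genes onto module branches just below the top.
Modules take color aliases by size rank (largest = "turquoise"), following
the field's convention.

Each module's eigengene is the first principal component of its
column-standardized submatrix, scaled to unit variance and sign-aligned so
that its correlation with the module's mean profile is non-negative.
Module-trait associations are Pearson correlations with two-sided
Student-t p-values (n - 2 df) against per-observation traits: cell-type
indicators, sex (male = 1), disease (case = 1).

## Overrepresentation analysis

Gene sets come from GMT files. The universe is the collection's annotated
genes intersected with the detected genes — this is what makes the
background ratio denominator a few thousand rather than genome-sized. For a
query of n genes, a set with K members in the universe and k in the query
is scored with the hypergeometric upper tail P(X >= k), computed in log
space (gammaln log-pmf, max-shifted summation) so that tails around 1e-24
keep full relative precision; the implementation is vectorized and agrees
with exact integer enumeration to < 1e-10 relative error (tested
exhaustively for N <= 60). Benjamini-Hochberg q-values are computed across
*all* sets in the collection, including non-significant ones. BH was chosen
over Storey's q for determinism; on the published worked example
(k = 164, n = 2073, K = 200, N = 4383, two-way tie among 50 sets) BH
reproduces the printed q to within ~0.2 orders of magnitude, which is the
expected residual given the source's unstated q-value variant.

## Synthetic cohort generator

The generator emulates the paired study design, not any particular
sequencing run. Defaults: 33 pairs (10 female / 23 male; ancestry split
20 EUR / 9 AFR / 1 ASN / 3 other), 15 PBMC cell types, negative binomial
counts with inverse-dispersion theta = 2 and lognormal baseline means
(meanlog -1.5, sdlog 1.2, i.e. ~0.45 mean counts/gene/cell, ~25% of genes
above 0.5) — chosen as a realistic sparsity profile for droplet scRNA-seq
at moderate depth. Case-side means are multiplied by `2^log2fc` for planted
(gene, cell type) effects, optionally scaled per sex to emulate
sex-differential effects. Planted co-expression modules draw one latent
factor per (sample, active cell type) observation, `f ~ N(0, 1)` plus a
trait shift (case samples, male samples, or one cell type), and multiply
member-gene means by `2^(loading * f)`. Dropout removes a cell type from
one or both sides of a pair with a configurable rate, which is what
exercises both imputation rules downstream. The
`planted_effect_config` helper plants effects on genes with baseline mean
>= 0.5 counts/cell: a gene at 0.01 counts/cell cannot exhibit observable
DE at a few hundred cells, and planting there would test sequencing depth,
not the method. The generator is byte-deterministic given (config, seed).

What the generator does *not* model: ambient RNA, doublets, batch or
chemistry effects, UMI saturation, per-gene zero inflation beyond the NB
(at these means the NB already yields realistic zero fractions), and
cell-type-correlated library sizes. Passing tests therefore demonstrate
the pipeline's statistical logic under a clean generative model, not
robustness to every artifact of real droplet data.

## Problem sizes used in validation

The validation suite runs scaled-down cohorts chosen to keep a full
laptop-class run practical while preserving the statistical regime
(hundreds of cells per group, thousands of gene-pair rows):

* replication-criterion experiments: 8 pairs, 6 cell types, 1000 genes,
  150 cells/type/sample; 20 seeds for the null false-call rate, 3 seeds
  (90 planted effects) for recovery;
* importance-recovery experiments: 8 pairs, 15 cell types, 400 genes,
  60 planted per affected type (~15% of genes, matching the DE prevalence
  the emulated study reports), 200 permutations, 20 seeds;
* module-recovery experiments: 3 planted modules of 60/50/40 genes plus 60
  background genes over 80 observations, within-module correlation ~0.72,
  10 seeds;
* the analysis drivers use one 12-pair, 15-type, 1200-gene cohort.

## Known limitations

* The permutation p-value, as defined, is conservative and uncalibrated
  (see above); rank order of importances is the primary readout.
* The tree-cut variant can absorb weakly attached genes into a module that
  the reference hybrid algorithm would assign to grey, and vice versa;
  module *membership at the margins* is less stable than module existence.
* The fold-change pseudocount shrinks effects of weakly expressed genes;
  realized log2FCs underestimate planted effects at low expression.
* With many strong planted effects, normalization couples genes through
  cell totals, producing a small opposite-sign bias in unaffected genes;
  at the simulated depths this stays well below the replication
  criterion's detection threshold.
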