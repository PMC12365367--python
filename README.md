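# pairedsc

Paired case/control single-cell PBMC analysis: per-pair differential
expression with a replication criterion, random-forest cell-type importance,
signed co-expression modules, and gene-set overrepresentation.

## The problem

In case/control single-cell studies of matched patient cohorts — here
modeled on pediatric single ventricle / hypoplastic left heart syndrome
(SV/HLHS) patients paired with heart-healthy controls — each pair of
subjects is an independent experiment. Pooling cells across patients
inflates significance through pseudoreplication; `pairedsc` instead tests
each pair separately and aggregates by replication:

* **Differential expression.** Within each (pair, cell type), genes are
  compared between case and control cells with a two-sided Wilcoxon
  rank-sum test on log-normalized values, Benjamini-Hochberg corrected per
  (pair, cell type). A gene is *replicated-DE* in a cell type when it
  reaches FDR < 0.05 in at least two pairs with log2 fold changes in the
  same direction. Genes called up in one cell type and down in another are
  reported as opposite-direction (cell-specific) genes.
* **Cell-type importance.** A (gene, pair) x cell-type matrix of log2 fold
  changes — missing entries mean-imputed per (gene, cell type), never-
  expressed combinations set to 0 — feeds a `RandomForestRegressor`
  (100 trees, random_state 42, 0.8/0.2 split, 5-fold CV) predicting each
  gene's all-cells pseudobulk fold change per pair. Normalized impurity
  importances rank the cell types by how much their expression changes
  explain the overall disease effect; permutation p-values shuffle each
  held-out feature column.
* **Co-expression modules.** Replicated-DE genes detected in every sample
  form a signed weighted network over (sample x cell type) pseudobulk
  profiles: adjacency `((1+r)/2)^6`, topological overlap, average-linkage
  dynamic tree cut (deepSplit 2, minModuleSize 30). Module eigengenes
  (first principal components) are correlated with cell types, sex and
  disease status.
* **Overrepresentation.** Gene lists are scored against GMT gene-set
  collections with the hypergeometric upper tail P(X >= k), computed in
  log space, with BH q-values across the whole collection and
  GeneRatio/BgRatio bookkeeping (k/n vs K/N within the detected-gene
  universe).

Because the emulated study's raw data are not public, the package ships a
first-class synthetic cohort generator (`pairedsc.simulate`) producing
paired cohorts with known ground truth — planted cell-type-specific
effects, opposite-direction programs, co-expression modules, and cell-type
dropout — so every stage is validated against planted truth.

## Worked example

```bash
python analysis/01_simulate_cohort.py
python analysis/02_pairwise_de.py
python analysis/03_celltype_importance.py
python analysis/04_coexpression_modules.py
python analysis/05_enrichment.py
```

The drivers build a 12-pair, 15-cell-type, 1200-gene cohort with effects
planted in four "most affected" cell types plus an opposite-direction
MYC-like program, and write tables under `results/analysis/`. Sample
output (abridged):

```
planted effects recovered with correct direction: 306/335
opposite-direction genes called: 89; planted: 25; overlap: 24
ancestry concordance over DE genes (EUR vs AFR): median r = 0.737 across 15 cell types

cell-type importance ranking (* = carries planted effects; 10 of 15 types do):
  T cells, CD8+, naive                 0.1753  p <0.005 *
  T cells, CD4+, Th1/17                0.1316  p <0.005 *
  ...
cumulative importance of top 4: 0.451
model diagnostics (all): CV MSE 0.003748 (+/- 0.00031), test MSE 0.003529

module sizes: {'turquoise': 85, 'blue': 74, 'brown': 63, 'yellow': 44, 'green': 37, 'unassigned': 13}
module-disease correlations:
  blue         r = +0.474 (p = 1.7e-13)     # contains the planted disease-up module
  turquoise    r = -0.311 (p = 3.2e-06)     # contains the planted disease-down module
```

Reading this: 91% of planted (gene, cell type) effects pass the two-pair
replication rule with the right sign; nearly all planted opposite-direction
genes are found (extra calls trace to module genes whose latent factors
flip direction between pairs); the held-out MSE matches the
cross-validation MSE, i.e. the forest is not overfitting; and the three
planted co-expression modules are recovered intact with disease
correlations of the planted signs.

The same stages are scriptable through a thin CLI
(`pairedsc simulate|de|importance|ora|run-all`) or the `PipelineConfig` /
`run_pipeline` API, which reruns byte-identically for a fixed config and
seed.

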