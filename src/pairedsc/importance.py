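"""Cell-type importance: fold-change matrix assembly, random-forest fit,
permutation significance, and cumulative importance.

The matrix has one row per (gene, pair) and one column per cell type, holding
the pair's log2 fold change for that gene in that cell type. Missing entries
(insufficient cells, or the gene unobserved in that pair) are imputed with
the mean log2FC of the same (gene, cell type) across the other pairs; a
(gene, cell type) never observed anywhere is assigned exactly 0. A random
forest regressor then predicts a per-row response (by default the pair's
all-cells pseudobulk log2FC of the gene), and the normalized impurity
importances rank the cell types by how much their expression changes explain
the overall disease effect.

Permutation significance follows the shuffle-against-the-fitted-model
procedure: each feature column of the held-out set is shuffled ``n_perm``
times and the p-value is the proportion of shuffles in which the model's
held-out score is at least the unshuffled score (i.e. the importance drop is
<= 0). Stored p-values live on the grid {0, 1/n_perm, ..., 1}; a stored 0 is
displayed as "<1/n_perm". Note this proportion is a descriptive significance
screen, not a calibrated test: truly uninformative features concentrate near
p = 0.5-1 rather than spreading uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import anndata as ad
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import r2_score
from sklearn.model_selection import KFold, cross_val_score, train_test_split

from .expression import STATUS_TESTED, pair_log2fc_profile

PROV_OBSERVED = "observed"
PROV_IMPUTED = "imputed_mean"
PROV_ZERO = "zero_not_expressed"


@dataclass
class FoldChangeMatrix:
    """(gene, pair) x cell-type log2FC matrix with per-entry provenance."""

    values: pd.DataFrame  # MultiIndex (gene, pair_id) x cell types, float
    provenance: pd.DataFrame  # same shape, strings in {observed, imputed_mean, zero_not_expressed}
    informative_pairs: pd.Series  # per cell type: number of pairs with >= 1 observed gene


def assemble_fc_matrix(tables: pd.DataFrame) -> FoldChangeMatrix:
    """Assemble the fold-change matrix from the long per-pair DE table.

    Entries whose status is ``tested`` are copied as observed. All other
    entries of a (gene, cell type) are imputed with the mean of its observed
    entries; if no pair observed the combination, every entry is exactly 0
    with provenance ``zero_not_expressed``. The rules are total: the result
    has no missing values.
    """
    values = tables.pivot_table(
        index=["gene", "pair_id"],
        columns="cell_type",
        values="log2fc",
        aggfunc="first",
        dropna=False,
        observed=True,
    )
    # complete the (gene, pair) grid in case whole blocks were absent
    genes = tables["gene"].unique()
    pairs = tables["pair_id"].unique()
    full_index = pd.MultiIndex.from_product([genes, pairs], names=["gene", "pair_id"])
    values = values.reindex(full_index)
    values = values.sort_index()

    observed = values.notna()
    provenance = pd.DataFrame(
        np.where(observed, PROV_OBSERVED, PROV_IMPUTED),
        index=values.index,
        columns=values.columns,
    )
    # mean over observed entries of the same (gene, cell type)
    gene_ct_mean = values.groupby(level="gene", sort=False).transform("mean")
    values = values.where(observed, gene_ct_mean)
    never = values.isna()  # no observed donor anywhere for this (gene, cell type)
    provenance = provenance.where(~never, PROV_ZERO)
    values = values.fillna(0.0)

    informative = (
        observed.groupby(level="pair_id", sort=False).any().sum(axis=0).astype(int)
    )
    informative.name = "informative_pairs"
    return FoldChangeMatrix(values=values, provenance=provenance, informative_pairs=informative)


def informative_mask(adata: ad.AnnData, min_cells: int = 3) -> pd.DataFrame:
    """Per cell type, the fraction of pairs where both sides have at least
    ``min_cells`` cells; types informative in < 50% of pairs are flagged."""
    obs = adata.obs
    counts = (
        obs.groupby(["cell_type", "pair_id", "group"], observed=True)
        .size()
        .unstack("group", fill_value=0)
    )
    for col in ("case", "control"):
        if col not in counts.columns:
            counts[col] = 0
    ok = (counts["case"] >= min_cells) & (counts["control"] >= min_cells)
    n_pairs = obs["pair_id"].nunique()
    frac = ok.groupby(level="cell_type", observed=True).sum() / n_pairs
    out = pd.DataFrame({"informative_fraction": frac})
    out["flagged_below_half"] = out["informative_fraction"] < 0.5
    return out.sort_index()


def pseudobulk_response(
    norm: ad.AnnData, matrix: FoldChangeMatrix, pseudocount: float = 1.0
) -> pd.Series:
    """Default regression target: per (gene, pair) all-cells pseudobulk
    log2FC, computed ignoring cell-type labels and aligned to matrix rows."""
    pairs = matrix.values.index.get_level_values("pair_id").unique()
    per_pair = {}
    for pair in pairs:
        prof = pair_log2fc_profile(norm, pair, cell_type=None, pseudocount=pseudocount)
        lfc = prof["log2fc"].where(prof["status"] == STATUS_TESTED, 0.0)
        per_pair[pair] = lfc
    wide = pd.DataFrame(per_pair)  # genes x pairs
    stacked = wide.stack()
    stacked.index.names = ["gene", "pair_id"]
    return stacked.reindex(matrix.values.index).rename("pseudobulk_log2fc")


@dataclass
class ImportanceResult:
    """Random-forest importances with diagnostics and permutation state."""

    importances: pd.Series  # normalized impurity importance per cell type
    cv_mse_mean: float
    cv_mse_sd: float
    test_mse: float
    model: RandomForestRegressor
    X_test: pd.DataFrame
    y_test: pd.Series
    seed: int
    p_values: Optional[pd.Series] = None
    n_perm: Optional[int] = None

    @property
    def ranking(self) -> pd.Series:
        return self.importances.sort_values(ascending=False)


def fit_importance(
    matrix: FoldChangeMatrix,
    target: pd.Series,
    seed: int = 42,
    n_estimators: int = 100,
    max_depth: Optional[int] = None,
    min_samples_split: int = 2,
    test_size: float = 0.2,
    cv_folds: int = 5,
    row_subset: Optional[np.ndarray] = None,
) -> ImportanceResult:
    """Fit the random-forest regressor and report importances + diagnostics.

    Hyperparameters default to 100 trees, unlimited depth, min_samples_split
    2, random_state 42, an 0.8/0.2 train-test split, and 5-fold CV MSE on the
    training split. ``row_subset`` (boolean mask over rows) supports
    sex-stratified reruns sharing one assembled matrix.
    """
    X = matrix.values
    y = target.reindex(X.index)
    if row_subset is not None:
        X, y = X[row_subset], y[row_subset]
    keep = y.notna().to_numpy()
    X, y = X[keep], y[keep]
    if len(X) < cv_folds:
        raise ValueError(f"{len(X)} rows is fewer than cv_folds={cv_folds}")
    X_train, X_test, y_train, y_test = train_test_split(
        X, y, test_size=test_size, random_state=seed
    )
    model = RandomForestRegressor(
        n_estimators=n_estimators,
        max_depth=max_depth,
        min_samples_split=min_samples_split,
        random_state=seed,
    )
    cv = KFold(n_splits=cv_folds, shuffle=False)
    cv_scores = -cross_val_score(
        model, X_train.to_numpy(), y_train.to_numpy(), cv=cv, scoring="neg_mean_squared_error"
    )
    model.fit(X_train.to_numpy(), y_train.to_numpy())
    test_mse = float(np.mean((model.predict(X_test.to_numpy()) - y_test) ** 2))
    importances = pd.Series(model.feature_importances_, index=X.columns, name="importance")
    return ImportanceResult(
        importances=importances,
        cv_mse_mean=float(np.mean(cv_scores)),
        cv_mse_sd=float(np.std(cv_scores, ddof=1)),
        test_mse=test_mse,
        model=model,
        X_test=X_test,
        y_test=y_test,
        seed=seed,
    )


def permutation_pvalues(
    result: ImportanceResult,
    n_perm: int = 1000,
    seed: int = 42,
) -> pd.Series:
    """Per-feature permutation p on the held-out split.

    Each feature column is shuffled ``n_perm`` times; p is the proportion of
    shuffles with held-out score >= the unshuffled score (importance drop
    <= 0, ties included). A constant feature never changes the predictions,
    so all its drops are exactly 0 and p = 1.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    X = np.asarray(result.X_test, dtype=float)
    y = np.asarray(result.y_test, dtype=float)
    n = len(y)
    base_score = r2_score(y, result.model.predict(X))
    p = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        # all shuffles of one feature scored in a single batched predict
        X_rep = np.tile(X, (n_perm, 1))
        for r in range(n_perm):
            X_rep[r * n : (r + 1) * n, j] = X[rng.permutation(n), j]
        preds = result.model.predict(X_rep)
        scores = np.fromiter(
            (r2_score(y, preds[r * n : (r + 1) * n]) for r in range(n_perm)),
            dtype=float,
            count=n_perm,
        )
        p[j] = np.mean(scores >= base_score)
    pvals = pd.Series(p, index=result.importances.index, name="perm_p")
    result.p_values = pvals
    result.n_perm = n_perm
    return pvals


def format_pvalue(p: float, n_perm: int) -> str:
    """Human-readable permutation p: a stored 0.0 prints as '<1/n_perm'."""
    if p == 0.0:
        return f"<{1.0 / n_perm:g}"
    return f"{p:g}"


def cumulative_importance(result: ImportanceResult, k: int) -> float:
    """Sum of the k largest importances (fraction of total importance)."""
    if k > len(result.importances):
        raise ValueError(f"k={k} exceeds the number of features ({len(result.importances)})")
    return float(result.ranking.iloc[:k].sum())
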