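"""Per-pair differential expression and the replication-based DE call.

Each case/control pair is an independent experiment: genes are tested per
(pair, cell type) with a two-sided Wilcoxon rank-sum test on log-normalized
values, followed by Benjamini-Hochberg correction across the genes tested
within that (pair, cell type). A gene is called differentially expressed in
a cell type when it reaches FDR < 0.05 in at least two pairs with log2 fold
changes in the same direction (the replication criterion); a gene may be up
in one cell type and down in another, and such opposite-direction genes are
reported separately.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Optional, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .expression import (
    STATUS_INSUFFICIENT,
    STATUS_NOT_EXPRESSED,
    STATUS_TESTED,
    _group_mask,
    pair_log2fc_profile,
)

DE_COLUMNS = [
    "gene",
    "pair_id",
    "cell_type",
    "log2fc",
    "p",
    "fdr",
    "n_cells_case",
    "n_cells_control",
    "status",
]


def _wilcoxon_pvalues(case: np.ndarray, ctrl: np.ndarray) -> np.ndarray:
    """Two-sided rank-sum p per gene (rows of genes x cells arrays).

    Exact enumeration when both sides have <= 25 cells and a gene has no
    ties; otherwise the normal approximation with tie correction and
    continuity correction. Midranks everywhere; fully deterministic.
    """
    n1, n2 = case.shape[1], ctrl.shape[1]
    with warnings.catch_warnings():
        # an all-tied gene yields 0/0 in the tie-corrected z; mapped to p = 1
        warnings.simplefilter("ignore", RuntimeWarning)
        if min(n1, n2) <= 25:
            pvals = np.empty(case.shape[0])
            for i in range(case.shape[0]):
                combined = np.concatenate([case[i], ctrl[i]])
                method = "exact" if len(np.unique(combined)) == len(combined) else "asymptotic"
                pvals[i] = scipy.stats.mannwhitneyu(
                    case[i], ctrl[i], alternative="two-sided", method=method
                ).pvalue
        else:
            res = scipy.stats.mannwhitneyu(
                case, ctrl, alternative="two-sided", method="asymptotic", axis=1
            )
            pvals = np.asarray(res.pvalue, dtype=float).copy()
    return np.where(np.isnan(pvals), 1.0, pvals)


def de_test_pair(
    norm: ad.AnnData,
    pair: str,
    cell_type: str,
    min_cells: int = 3,
    pseudocount: float = 1.0,
    fdr_method: str = "fdr_bh",
) -> pd.DataFrame:
    """Per-gene (log2FC, p, FDR) for one (pair, cell type).

    If either side of the pair has fewer than ``min_cells`` cells of the
    type, every gene is flagged ``insufficient_cells``. Genes with zero
    counts on both sides are ``not_expressed`` and excluded from testing and
    from the FDR correction.
    """
    profile = pair_log2fc_profile(norm, pair, cell_type, pseudocount)
    out = profile.copy()
    out.insert(0, "gene", out.index.to_numpy())
    out.insert(1, "pair_id", pair)
    out.insert(2, "cell_type", cell_type)
    out["p"] = np.nan
    out["fdr"] = np.nan
    n_case = int(out["n_cells_case"].iloc[0])
    n_ctrl = int(out["n_cells_control"].iloc[0])
    if n_case < min_cells or n_ctrl < min_cells:
        out["status"] = STATUS_INSUFFICIENT
        out["log2fc"] = np.nan
        return out[DE_COLUMNS].reset_index(drop=True)
    tested = (out["status"] == STATUS_TESTED).to_numpy()
    if tested.any():
        case_mask = _group_mask(norm, pair=pair, group="case", cell_type=cell_type)
        ctrl_mask = _group_mask(norm, pair=pair, group="control", cell_type=cell_type)
        case = np.asarray(norm.X[case_mask].todense()).T[tested]  # genes x cells
        ctrl = np.asarray(norm.X[ctrl_mask].todense()).T[tested]
        p = _wilcoxon_pvalues(case, ctrl)
        out.loc[tested, "p"] = p
        out.loc[tested, "fdr"] = multipletests(p, method=fdr_method)[1]
    return out[DE_COLUMNS].reset_index(drop=True)


def run_pairwise_de(
    norm: ad.AnnData,
    min_cells: int = 3,
    pseudocount: float = 1.0,
    pairs: Optional[Sequence[str]] = None,
    cell_types: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Long table of per-(gene, pair, cell type) DE results over the cohort."""
    obs = norm.obs
    pairs = list(pairs) if pairs is not None else sorted(pd.unique(obs["pair_id"]))
    cell_types = (
        list(cell_types) if cell_types is not None else sorted(pd.unique(obs["cell_type"]))
    )
    tables = [
        de_test_pair(norm, pair, ct, min_cells=min_cells, pseudocount=pseudocount)
        for pair in pairs
        for ct in cell_types
    ]
    return pd.concat(tables, ignore_index=True)


def replicated_de(
    tables: pd.DataFrame,
    fdr_threshold: float = 0.05,
    min_supporting_pairs: int = 2,
) -> pd.DataFrame:
    """Replication-based DE call per (gene, cell type).

    direction = "up" when at least ``min_supporting_pairs`` pairs reach
    FDR < ``fdr_threshold`` with positive log2FC (symmetrically "down");
    "none" otherwise, including the ambiguous case where both directions
    meet the support threshold. Also reports the mean log2FC over tested
    pairs, matching the signed per-cell-type summary layout.
    """
    t = tables[tables["status"] == STATUS_TESTED]
    sig = t[t["fdr"] < fdr_threshold]
    grouped = sig.groupby(["gene", "cell_type"], sort=True, observed=True)
    rows = []
    for (gene, ct), g in grouped:
        up = g[g["log2fc"] > 0]
        down = g[g["log2fc"] < 0]
        up_ok = len(up) >= min_supporting_pairs
        down_ok = len(down) >= min_supporting_pairs
        if up_ok and not down_ok:
            direction, support = "up", up
        elif down_ok and not up_ok:
            direction, support = "down", down
        else:
            continue
        rows.append(
            {
                "gene": gene,
                "cell_type": ct,
                "direction": direction,
                "n_supporting_pairs": len(support),
                "supporting_pairs": ",".join(sorted(support["pair_id"])),
            }
        )
    calls = pd.DataFrame(rows, columns=["gene", "cell_type", "direction",
                                        "n_supporting_pairs", "supporting_pairs"])
    if len(calls):
        mean_lfc = (
            t.groupby(["gene", "cell_type"], observed=True)["log2fc"].mean().rename("mean_log2fc")
        )
        calls = calls.join(mean_lfc, on=["gene", "cell_type"])
    else:
        calls["mean_log2fc"] = pd.Series(dtype=float)
    return calls.reset_index(drop=True)


def opposite_direction_genes(calls: pd.DataFrame) -> pd.DataFrame:
    """Genes replicated-DE up in at least one cell type and down in at least
    one other; per-cell-type directions are retained."""
    if calls.empty:
        return calls.iloc[0:0]
    per_gene = calls.groupby("gene")["direction"].agg(set)
    both = per_gene[per_gene.apply(lambda s: {"up", "down"} <= s)].index
    return calls[calls["gene"].isin(both)].sort_values(["gene", "cell_type"]).reset_index(drop=True)


class UndefinedCorrelationError(ValueError):
    pass


def ancestry_concordance(
    tables: pd.DataFrame,
    group_a_pairs: Iterable[str],
    group_b_pairs: Iterable[str],
    cell_type: str,
    min_genes: int = 3,
) -> float:
    """Pearson r between two patient groups' mean per-gene log2FC profiles
    in one cell type, over genes observed in both groups."""
    t = tables[(tables["cell_type"] == cell_type) & (tables["status"] == STATUS_TESTED)]
    a = t[t["pair_id"].isin(set(group_a_pairs))].groupby("gene")["log2fc"].mean()
    b = t[t["pair_id"].isin(set(group_b_pairs))].groupby("gene")["log2fc"].mean()
    common = a.index.intersection(b.index)
    if len(common) < min_genes:
        raise UndefinedCorrelationError(
            f"only {len(common)} overlapping genes (< {min_genes}); correlation undefined"
        )
    r, _ = scipy.stats.pearsonr(a[common], b[common])
    return float(r)
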