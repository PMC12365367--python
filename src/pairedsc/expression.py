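"""Normalization, pseudobulk aggregation and per-pair fold changes.

Normalization is the standard library-size log transform: for a cell with
total UMI count T, a count c becomes ln(1 + c / T * scale_factor) with
scale_factor 1e4. Fold changes within a case/control pair are computed on
the de-logged normalized scale with a pseudocount of 1:

    log2FC = log2( (mean_case exp(x) - 1 + 1) / (mean_ctrl exp(x) - 1 + 1) )

where the means run over the pair's case and control cells of one cell type
(or all cells when cell_type is None). Positive values mean higher
expression in the case sample.
"""

from __future__ import annotations

from typing import Optional

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

STATUS_TESTED = "tested"
STATUS_INSUFFICIENT = "insufficient_cells"
STATUS_NOT_EXPRESSED = "not_expressed"


class ZeroTotalCellError(ValueError):
    """A cell has zero total counts and cannot be normalized."""


class EmptyGroupError(KeyError):
    """A requested (sample/pair, cell type) group contains no cells."""


def log_normalize(adata: ad.AnnData, scale_factor: float = 1e4) -> ad.AnnData:
    """Return a copy with X = ln(1 + count / cell_total * scale_factor).

    Sparsity is preserved (zero counts stay exactly zero); raw counts remain
    available in ``layers['counts']``.
    """
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    counts = sp.csr_matrix(adata.layers.get("counts", adata.X), dtype=np.float64)
    totals = np.asarray(counts.sum(axis=1)).ravel()
    if (totals == 0).any():
        bad = adata.obs["barcode"].to_numpy()[totals == 0]
        raise ZeroTotalCellError(
            f"{len(bad)} cells have zero total counts: {list(bad[:5])}"
        )
    norm = counts.multiply((scale_factor / totals)[:, None]).tocsr()
    norm.data = np.log1p(norm.data)
    out = adata.copy()
    out.X = norm
    out.uns["scale_factor"] = float(scale_factor)
    out.uns["normalized"] = True
    return out


def _group_mask(
    adata: ad.AnnData,
    *,
    sample: Optional[str] = None,
    pair: Optional[str] = None,
    group: Optional[str] = None,
    cell_type: Optional[str] = None,
) -> np.ndarray:
    mask = np.ones(adata.n_obs, dtype=bool)
    if sample is not None:
        mask &= (adata.obs["sample_id"] == sample).to_numpy()
    if pair is not None:
        mask &= (adata.obs["pair_id"] == pair).to_numpy()
    if group is not None:
        mask &= (adata.obs["group"] == group).to_numpy()
    if cell_type is not None:
        mask &= (adata.obs["cell_type"] == cell_type).to_numpy()
    return mask


def pseudobulk_mean(
    norm: ad.AnnData, sample: str, cell_type: Optional[str] = None
) -> pd.Series:
    """Per-gene arithmetic mean of normalized values over a (sample, cell
    type) group of cells; ``cell_type=None`` averages all cells of the
    sample. Raises :class:`EmptyGroupError` on an empty group."""
    mask = _group_mask(norm, sample=sample, cell_type=cell_type)
    if not mask.any():
        raise EmptyGroupError(f"no cells for sample={sample!r}, cell_type={cell_type!r}")
    means = np.asarray(norm.X[mask].mean(axis=0)).ravel()
    return pd.Series(means, index=norm.var_names, name=(sample, cell_type))


def pair_log2fc_profile(
    norm: ad.AnnData,
    pair: str,
    cell_type: Optional[str] = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-gene case-vs-control log2 fold change within one pair.

    Returns a DataFrame indexed by gene with columns ``log2fc``, ``status``,
    ``n_cells_case``, ``n_cells_control``. If either side of the pair has no
    cells of the requested type the whole profile is flagged
    ``insufficient_cells``; genes with zero counts on both sides of the pair
    are flagged ``not_expressed`` (no fold change is reported rather than a
    vacuous 0).
    """
    case_mask = _group_mask(norm, pair=pair, group="case", cell_type=cell_type)
    ctrl_mask = _group_mask(norm, pair=pair, group="control", cell_type=cell_type)
    n_case, n_ctrl = int(case_mask.sum()), int(ctrl_mask.sum())
    out = pd.DataFrame(
        {
            "log2fc": np.nan,
            "status": STATUS_INSUFFICIENT,
            "n_cells_case": n_case,
            "n_cells_control": n_ctrl,
        },
        index=norm.var_names.copy(),
    )
    if n_case == 0 or n_ctrl == 0:
        return out
    counts = norm.layers["counts"]
    expressed = (
        np.asarray(counts[case_mask].sum(axis=0)).ravel()
        + np.asarray(counts[ctrl_mask].sum(axis=0)).ravel()
    ) > 0
    case_mean = _mean_expm1(norm.X, case_mask)
    ctrl_mean = _mean_expm1(norm.X, ctrl_mask)
    lfc = np.log2((case_mean + pseudocount) / (ctrl_mean + pseudocount))
    out.loc[expressed, "log2fc"] = lfc[expressed]
    out.loc[expressed, "status"] = STATUS_TESTED
    out.loc[~expressed, "status"] = STATUS_NOT_EXPRESSED
    return out


def pair_log2fc(
    norm: ad.AnnData,
    pair: str,
    cell_type: Optional[str],
    gene: str,
    pseudocount: float = 1.0,
) -> float:
    """Scalar fold change for one gene; NaN when not expressed or a side of
    the pair is missing (see :func:`pair_log2fc_profile` for the reasons)."""
    profile = pair_log2fc_profile(norm, pair, cell_type, pseudocount)
    return float(profile.loc[gene, "log2fc"])


def _mean_expm1(X: sp.spmatrix, mask: np.ndarray) -> np.ndarray:
    sub = X[mask]
    sub = sub.copy()
    sub.data = np.expm1(sub.data)
    return np.asarray(sub.mean(axis=0)).ravel()


def pseudobulk_table(norm: ad.AnnData, cell_types: Optional[list[str]] = None) -> pd.DataFrame:
    """Genes x (sample, cell type) table of pseudobulk means over all
    populated groups. Columns are a MultiIndex (sample_id, cell_type)."""
    obs = norm.obs
    cols = {}
    samples = list(pd.unique(obs["sample_id"]))
    cts = cell_types if cell_types is not None else list(pd.unique(obs["cell_type"]))
    for s in samples:
        for ct in cts:
            mask = _group_mask(norm, sample=s, cell_type=ct)
            if mask.any():
                cols[(s, ct)] = np.asarray(norm.X[mask].mean(axis=0)).ravel()
    table = pd.DataFrame(cols, index=norm.var_names.copy())
    table.columns = pd.MultiIndex.from_tuples(table.columns, names=["sample_id", "cell_type"])
    return table
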