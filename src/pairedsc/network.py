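"""Signed weighted co-expression network on pseudobulk profiles.

Observations are (sample, cell type) pseudobulk profiles over the
informative cell types; variables are genes detected in every sample.
The signed adjacency between genes i and j is

    a_ij = ((1 + cor(x_i, x_j)) / 2) ** beta        (beta = 6 by default)

which maps anticorrelated pairs near 0 and correlated pairs near 1. The
topological overlap measure (TOM) smooths adjacency by shared neighborhoods:

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)

with k_i the connectivity excluding the diagonal. Modules are branches of
the average-linkage dendrogram of 1 - TOM, cut by a dynamic tree cut
(static-height descent with recursive splitting governed by ``deep_split``
and a ``min_module_size`` floor). Each module is summarized by its
eigengene, the first principal component of the standardized module
submatrix, sign-aligned with the module's mean profile, and correlated
against trait vectors (cell-type one-hots, sex, disease status).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
import scipy.stats

UNASSIGNED = "unassigned"

#: module color aliases by size rank, following the co-expression convention
#: that the largest module is "turquoise" and unclustered genes are "grey".
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
)


class ZeroVarianceGeneError(ValueError):
    pass


class ConstantTraitError(ValueError):
    pass


def detected_everywhere_filter(counts_by_sample: pd.DataFrame) -> pd.Index:
    """Genes with total count > 0 in every sample.

    ``counts_by_sample``: genes x samples table of per-sample total counts.
    """
    if counts_by_sample.shape[1] == 0:
        raise ValueError("no samples provided")
    keep = (counts_by_sample > 0).all(axis=1)
    return counts_by_sample.index[keep]


def sample_gene_totals(adata) -> pd.DataFrame:
    """Genes x samples matrix of total raw counts."""
    totals = {}
    counts = adata.layers.get("counts", adata.X)
    for s in pd.unique(adata.obs["sample_id"]):
        mask = (adata.obs["sample_id"] == s).to_numpy()
        totals[s] = np.asarray(counts[mask].sum(axis=0)).ravel()
    return pd.DataFrame(totals, index=adata.var_names.copy())


def build_profile_matrix(
    pseudobulk: pd.DataFrame, genes: pd.Index, cell_types: list[str]
) -> pd.DataFrame:
    """Observations x genes matrix from a genes x (sample, cell type)
    pseudobulk table, restricted to ``genes`` and ``cell_types``."""
    sub = pseudobulk.loc[genes, pseudobulk.columns.get_level_values("cell_type").isin(cell_types)]
    X = sub.T
    X.index = pd.MultiIndex.from_tuples(X.index, names=["sample_id", "cell_type"])
    return X.sort_index()


def signed_adjacency(X: pd.DataFrame, beta: float = 6.0) -> pd.DataFrame:
    """Signed soft-threshold adjacency between genes (columns of X)."""
    if X.shape[0] < 3:
        raise ValueError("need at least 3 observations to correlate genes")
    sd = X.std(axis=0, ddof=0)
    zero_var = sd.index[sd == 0]
    if len(zero_var):
        raise ZeroVarianceGeneError(
            f"{len(zero_var)} gene(s) have zero variance across observations: "
            f"{list(zero_var[:5])}"
        )
    r = np.corrcoef(X.to_numpy(), rowvar=False)
    a = ((1.0 + r) / 2.0) ** beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=X.columns, columns=X.columns)


def tom_similarity(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix; diagonal 1 by convention."""
    A = np.asarray(adjacency, dtype=float)
    if A.shape[0] != A.shape[1] or not np.allclose(A, A.T, atol=1e-12):
        raise ValueError("adjacency must be square and symmetric")
    if A.min() < -1e-12 or A.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    B = A.copy()
    np.fill_diagonal(B, 0.0)  # diagonal excluded from sums
    shared = B @ B
    k = B.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - B
    tom = (shared + B) / denom
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


#: relative height margin below a branch's top merge that a sub-split must
#: respect; smaller values split more aggressively (higher deep_split)
_DEEP_SPLIT_GAP = {0: 0.40, 1: 0.30, 2: 0.20, 3: 0.10, 4: 0.05}

#: number of candidate cut heights scanned (quantiles of merge heights)
_MAX_CUT_CANDIDATES = 200


def _count_maximizing_cut(
    Z: np.ndarray, min_size: int, height_cap: float
) -> tuple[float, np.ndarray]:
    """Adaptive cut height: the threshold (<= height_cap) that yields the
    most branches of size >= min_size; ties resolve to the highest cut.

    A single fixed fraction of the top merge height fails on real TOM
    dendrograms because average linkage chains weakly connected genes onto
    module branches just below the top; scanning candidate heights finds the
    band where distinct modules are separated but still intact.
    """
    heights = np.unique(Z[:, 2])
    heights = heights[heights <= height_cap]
    n = Z.shape[0] + 1
    if heights.size == 0:
        return height_cap, np.ones(n, dtype=int)
    if heights.size > _MAX_CUT_CANDIDATES:
        qs = np.linspace(0, 1, _MAX_CUT_CANDIDATES)
        heights = np.unique(np.quantile(heights, qs))
    # cut midway between consecutive merge heights (and just above the top)
    candidates = np.append((heights[:-1] + heights[1:]) / 2.0, heights[-1] * 1.0 + 1e-12)
    best = (-1, -np.inf, None)
    for t in candidates:
        labels = sch.fcluster(Z, t=t, criterion="distance")
        sizes = np.bincount(labels)
        n_big = int((sizes >= min_size).sum())
        if (n_big, t) > best[:2]:
            best = (n_big, t, labels)
    return best[1], best[2]


def _split_cluster(
    D: np.ndarray, members: np.ndarray, min_size: int, gap: float
) -> list[np.ndarray]:
    """Recursively sub-split one cluster on its own sub-dendrogram.

    A sub-split is accepted only when, capped at (1 - gap) of the branch's
    own top merge height, the adaptive cut still produces two or more
    branches of size >= min_size; members falling into smaller fragments
    of an accepted split are left for the unassigned pool.
    """
    if len(members) < 2 * min_size:
        return [members]
    sub = D[np.ix_(members, members)]
    Z = sch.linkage(ssd.squareform(sub, checks=False), method="average")
    top = Z[-1, 2]
    if top <= 0:
        return [members]
    _, labels = _count_maximizing_cut(Z, min_size, (1.0 - gap) * top)
    sizes = np.bincount(labels)
    big = np.flatnonzero(sizes >= min_size)
    if len(big) < 2:
        return [members]
    out: list[np.ndarray] = []
    for b in big:
        out.extend(_split_cluster(D, members[labels == b], min_size, gap))
    return out


def cut_modules(
    diss: pd.DataFrame,
    deep_split: int = 2,
    min_module_size: int = 30,
    cut_height: float | None = None,
) -> pd.Series:
    """Dynamic tree cut of the 1 - TOM dissimilarity.

    Average-linkage clustering of the dissimilarity, cut at the adaptive
    height that maximizes the number of branches satisfying the size floor
    (candidates capped at ``cut_height``, default 0.99 of the top merge
    height), followed by recursive sub-splitting of each branch;
    ``deep_split`` (0-4) sets how pronounced a height jump a sub-split must
    show. Clusters below ``min_module_size`` become "unassigned". Labels are
    color aliases assigned by size rank (largest module first).
    """
    if deep_split not in _DEEP_SPLIT_GAP:
        raise ValueError(f"deep_split must be one of {sorted(_DEEP_SPLIT_GAP)}")
    gap = _DEEP_SPLIT_GAP[deep_split]
    genes = diss.index
    n = len(genes)
    if n < min_module_size:
        return pd.Series(UNASSIGNED, index=genes, name="module")
    D = np.asarray(diss, dtype=float)
    D = (D + D.T) / 2.0
    Z = sch.linkage(ssd.squareform(D, checks=False), method="average")
    if cut_height is None:
        cut_height = 0.99 * Z[-1, 2]
    _, labels0 = _count_maximizing_cut(Z, min_module_size, cut_height)

    final: list[np.ndarray] = []
    for lab in np.unique(labels0):
        members = np.flatnonzero(labels0 == lab)
        if len(members) < min_module_size:
            continue
        final.extend(_split_cluster(D, members, min_module_size, gap))

    final = [c for c in final if len(c) >= min_module_size]
    final.sort(key=lambda c: (-len(c), int(c.min())))
    labels = np.full(n, UNASSIGNED, dtype=object)
    for rank, members in enumerate(final):
        color = MODULE_COLORS[rank] if rank < len(MODULE_COLORS) else f"module{rank + 1}"
        labels[members] = color
    return pd.Series(labels, index=genes, name="module")


def module_eigengene(
    X: pd.DataFrame, labels: pd.Series, module: str
) -> tuple[pd.Series, float]:
    """Eigengene of a module: first principal component over observations.

    The module submatrix is column-standardized; the leading left singular
    vector is scaled to unit variance and sign-fixed so its correlation with
    the module's mean standardized profile is non-negative. Returns the
    eigengene and the fraction of variance it explains.
    """
    genes = labels.index[labels == module]
    if len(genes) < 2:
        raise ValueError(f"module {module!r} has {len(genes)} gene(s); need >= 2")
    sub = X[genes].to_numpy(dtype=float)
    sub = (sub - sub.mean(axis=0)) / sub.std(axis=0, ddof=0)
    u, s, _ = np.linalg.svd(sub, full_matrices=False)
    e = u[:, 0]
    var_explained = float(s[0] ** 2 / np.sum(s**2))
    mean_profile = sub.mean(axis=1)
    if np.corrcoef(e, mean_profile)[0, 1] < 0:
        e = -e
    e = e / np.std(e, ddof=1)
    return pd.Series(e, index=X.index, name=module), var_explained


def module_eigengenes(X: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Observations x modules eigengene table (unassigned genes excluded)."""
    modules = [m for m in labels.unique() if m != UNASSIGNED]
    cols = {m: module_eigengene(X, labels, m)[0] for m in sorted(modules)}
    return pd.DataFrame(cols, index=X.index)


def trait_matrix(observations: pd.MultiIndex, sample_meta: pd.DataFrame) -> pd.DataFrame:
    """Numeric trait encoding per (sample, cell type) observation:
    one-hot cell-type columns, sex (male = 1), disease (case = 1)."""
    obs = pd.DataFrame(index=observations)
    cts = observations.get_level_values("cell_type")
    for ct in sorted(set(cts)):
        obs[ct] = (cts == ct).astype(float)
    meta = sample_meta.set_index("sample_id") if "sample_id" in sample_meta.columns else sample_meta
    samples = observations.get_level_values("sample_id")
    obs["sex_male"] = (meta.loc[samples, "sex"] == "M").astype(float).to_numpy()
    obs["disease"] = (meta.loc[samples, "group"] == "case").astype(float).to_numpy()
    return obs


def module_trait_correlation(
    eigengenes: pd.DataFrame, traits: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r and two-sided Student-t p for every (module, trait)."""
    const = traits.columns[traits.std(axis=0, ddof=0) == 0]
    if len(const):
        raise ConstantTraitError(f"constant trait column(s): {list(const)}")
    r = pd.DataFrame(index=eigengenes.columns, columns=traits.columns, dtype=float)
    p = r.copy()
    for m in eigengenes.columns:
        for t in traits.columns:
            res = scipy.stats.pearsonr(eigengenes[m], traits[t])
            r.loc[m, t] = res.statistic
            p.loc[m, t] = res.pvalue
    return r, p


@dataclass
class ModuleResult:
    """Bundle of the network stage outputs."""

    labels: pd.Series
    eigengenes: pd.DataFrame
    trait_r: pd.DataFrame
    trait_p: pd.DataFrame
    parameters: dict
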