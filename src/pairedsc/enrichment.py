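"""Hypergeometric overrepresentation analysis (ORA) against GMT gene sets.

For a query of n genes drawn from a universe of N genes (the union of all
collection members intersected with the detected genes), a set with K
members in the universe and k members in the query is scored with the
hypergeometric upper tail P(X >= k), computed in log space so that extreme
tails (q ~ 1e-24 for the strongest hallmark hits) remain accurate.
Benjamini-Hochberg adjustment runs across every set in the collection,
including the non-significant ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests


class GmtFormatError(ValueError):
    pass


@dataclass
class GeneSetCollection:
    """Named gene sets; the universe is the union of all members."""

    sets: dict[str, frozenset]

    @property
    def universe(self) -> frozenset:
        out: set = set()
        for members in self.sets.values():
            out |= members
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, ``name <TAB> description <TAB>
    member...``; members deduplicated, description ignored."""
    p = Path(path)
    sets: dict[str, frozenset] = {}
    with open(p) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtFormatError(
                    f"{p} line {lineno}: expected >= 3 tab-separated fields, got {len(fields)}"
                )
            name, _desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise GmtFormatError(f"{p} line {lineno}: set {name!r} has no members")
            sets[name] = frozenset(members)
    if not sets:
        raise GmtFormatError(f"{p}: no gene sets found")
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path, description: str = "na") -> None:
    lines = [
        "\t".join([name, description, *sorted(members)])
        for name, members in collection.sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def hypergeom_upper_tail(k, n, K, N):
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws).

    Computed via the log survival function for numerical safety at extreme
    tails. k = 0 gives 1; k beyond min(n, K) gives 0. Accepts scalars or
    equal-length arrays (returning an array).
    """
    k, n, K, N = np.broadcast_arrays(
        *(np.asarray(a, dtype=np.int64) for a in (k, n, K, N))
    )
    scalar = k.ndim == 0
    k, n, K, N = (np.atleast_1d(a) for a in (k, n, K, N))
    if np.any(k < 0) or np.any(n < 0) or np.any(n > N) or np.any(K < 0) or np.any(K > N):
        raise ValueError("inconsistent arguments: need 0 <= k, 0 <= n <= N, 0 <= K <= N")
    upper = np.minimum(n, K)
    lo = np.maximum(k, np.maximum(0, n - (N - K)))  # support lower bound
    counts = np.maximum(upper - lo + 1, 0)
    p = np.zeros(k.shape, dtype=float)
    p[k <= 0] = 1.0
    live = (counts > 0) & (k > 0)
    if live.any():
        # flatten all summation terms, log-pmf via gammaln, segmented logsumexp
        c = counts[live]
        offsets = np.concatenate([[0], np.cumsum(c)[:-1]])
        ii = np.repeat(lo[live], c) + (np.arange(c.sum()) - np.repeat(offsets, c))
        nn, KK, NN = (np.repeat(a[live], c) for a in (n, K, N))
        logpmf = (
            gammaln(KK + 1) - gammaln(ii + 1) - gammaln(KK - ii + 1)
            + gammaln(NN - KK + 1) - gammaln(nn - ii + 1) - gammaln(NN - KK - nn + ii + 1)
            - (gammaln(NN + 1) - gammaln(nn + 1) - gammaln(NN - nn + 1))
        )
        seg_max = np.maximum.reduceat(logpmf, offsets)
        sums = np.add.reduceat(np.exp(logpmf - np.repeat(seg_max, c)), offsets)
        p[live] = np.exp(seg_max + np.log(sums))
    p = np.minimum(p, 1.0)
    return float(p[0]) if scalar else p


def bh_qvalues(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def synthetic_overlap_scenario(
    overlaps: list[tuple[str, int, int]],
    n_query: int,
    n_universe: int,
    n_sets: int,
    filler_set_size: int = 200,
    seed: int = 0,
) -> tuple[list[str], GeneSetCollection, list[str]]:
    """Synthetic (query, collection, detected) reproducing given overlap rows.

    ``overlaps`` lists (set name, k, K): each named set receives exactly k
    members inside the query and K - k outside it. The collection is padded
    with filler sets whose query overlap sits at its expectation (so they
    are unenriched), plus one covering set so the universe size is exactly
    ``n_universe``. Used to validate the ORA arithmetic against published
    GeneRatio/BgRatio/q rows, which fix (k, n, K, N) but not gene identities.
    """
    rng = np.random.default_rng(seed)
    genes = [f"u{i:05d}" for i in range(n_universe)]
    query = genes[:n_query]
    non_query = genes[n_query:]
    sets: dict[str, frozenset] = {}
    for name, k, K in overlaps:
        if k > n_query or K - k > len(non_query):
            raise ValueError(f"overlap row {name!r} is infeasible")
        members = list(rng.choice(query, size=k, replace=False)) + list(
            rng.choice(non_query, size=K - k, replace=False)
        )
        sets[name] = frozenset(members)
    k_expected = int(round(filler_set_size * n_query / n_universe))
    n_fillers = n_sets - len(overlaps) - 1
    for i in range(n_fillers):
        members = list(rng.choice(query, size=k_expected, replace=False)) + list(
            rng.choice(non_query, size=filler_set_size - k_expected, replace=False)
        )
        sets[f"FILLER{i:02d}"] = frozenset(members)
    sets["COVER"] = frozenset(genes)  # fixes the universe at n_universe
    return query, GeneSetCollection(sets), genes


def ora(
    query_genes: Iterable[str],
    collection: GeneSetCollection,
    detected_genes: Iterable[str],
) -> pd.DataFrame:
    """Overrepresentation table for a query gene list.

    The universe is the collection's annotated genes intersected with the
    detected genes; q-values are BH-adjusted across all sets. Rows are
    sorted by q then p ascending.
    """
    detected = set(detected_genes)
    universe = collection.universe & detected
    N = len(universe)
    query = set(query_genes) & universe
    n = len(query)
    if N == 0 or n == 0:
        raise ValueError("empty universe or query after intersection with detected genes")
    rows = []
    for name, members in collection.sets.items():
        members_u = members & universe
        K = len(members_u)
        overlap = sorted(query & members_u)
        k = len(overlap)
        p = hypergeom_upper_tail(k, n, K, N) if K else 1.0
        rows.append(
            {
                "set": name,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "gene_ratio": f"{k}/{n}",
                "bg_ratio": f"{K}/{N}",
                "pvalue": p,
                "genes": "/".join(overlap),
            }
        )
    table = pd.DataFrame(rows)
    table["qvalue"] = bh_qvalues(table["pvalue"])
    table = table.sort_values(["qvalue", "pvalue", "set"], kind="mergesort").reset_index(drop=True)
    return table[
        ["set", "k", "n", "K", "N", "gene_ratio", "bg_ratio", "pvalue", "qvalue", "genes"]
    ]
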