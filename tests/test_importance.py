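"""Fold-change matrix assembly (imputation rules), informative fractions,
random-forest importance and permutation significance."""

import numpy as np
import pandas as pd
import pytest

from pairedsc import (
    assemble_fc_matrix,
    cumulative_importance,
    fit_importance,
    informative_mask,
    permutation_pvalues,
)
from pairedsc.expression import STATUS_INSUFFICIENT, STATUS_NOT_EXPRESSED, STATUS_TESTED
from pairedsc.importance import PROV_IMPUTED, PROV_OBSERVED, PROV_ZERO, format_pvalue

from test_expression import make_adata


def long_row(gene, pair, ct, lfc, status):
    return {
        "gene": gene, "pair_id": pair, "cell_type": ct,
        "log2fc": lfc if status == STATUS_TESTED else np.nan,
        "p": 0.5, "fdr": 0.5, "n_cells_case": 10, "n_cells_control": 10,
        "status": status,
    }


@pytest.fixture()
def assembled():
    rows = [
        # g1/NK observed in P1, P2 with 1.0 and 2.0; missing in P3
        long_row("g1", "P1", "NK", 1.0, STATUS_TESTED),
        long_row("g1", "P2", "NK", 2.0, STATUS_TESTED),
        long_row("g1", "P3", "NK", None, STATUS_INSUFFICIENT),
        # g2 never expressed in NK
        long_row("g2", "P1", "NK", None, STATUS_NOT_EXPRESSED),
        long_row("g2", "P2", "NK", None, STATUS_NOT_EXPRESSED),
        long_row("g2", "P3", "NK", None, STATUS_NOT_EXPRESSED),
        # second column, fully observed
        long_row("g1", "P1", "B", 0.5, STATUS_TESTED),
        long_row("g1", "P2", "B", -0.5, STATUS_TESTED),
        long_row("g1", "P3", "B", 0.25, STATUS_TESTED),
        long_row("g2", "P1", "B", 0.1, STATUS_TESTED),
        long_row("g2", "P2", "B", 0.2, STATUS_TESTED),
        long_row("g2", "P3", "B", 0.3, STATUS_TESTED),
    ]
    return assemble_fc_matrix(pd.DataFrame(rows))


def test_mean_imputation_rule(assembled):
    m = assembled
    assert m.values.loc[("g1", "P3"), "NK"] == pytest.approx(1.5)
    assert m.provenance.loc[("g1", "P3"), "NK"] == PROV_IMPUTED


def test_never_expressed_column_is_exact_zero(assembled):
    m = assembled
    for pair in ("P1", "P2", "P3"):
        assert m.values.loc[("g2", pair), "NK"] == 0.0
        assert m.provenance.loc[("g2", pair), "NK"] == PROV_ZERO


def test_observed_entries_pass_through(assembled):
    m = assembled
    assert m.values.loc[("g1", "P1"), "NK"] == 1.0
    assert m.provenance.loc[("g1", "P1"), "NK"] == PROV_OBSERVED
    assert not m.values.isna().any().any()  # rules are total


def test_informative_mask_fractions():
    # build 33 pairs; cell type "T" informative in 16, "B" in 27
    rows = []
    for i in range(33):
        pair = f"P{i:02d}"
        for ct, informative_upto in (("T", 16), ("B", 27)):
            for group in ("case", "control"):
                n = 5 if i < informative_upto else 1
                for j in range(n):
                    rows.append((pair, group, ct))
    obs = pd.DataFrame(rows, columns=["pair_id", "group", "cell_type"])
    n = len(obs)
    counts = np.ones((n, 3), dtype=int)
    adata = make_adata(
        counts,
        cell_types=list(obs["cell_type"]),
        groups=list(obs["group"]),
        pairs=list(obs["pair_id"]),
    )
    out = informative_mask(adata, min_cells=3)
    assert out.loc["T", "informative_fraction"] == pytest.approx(16 / 33, abs=1e-4)
    assert bool(out.loc["T", "flagged_below_half"])
    assert out.loc["B", "informative_fraction"] == pytest.approx(27 / 33, abs=1e-4)
    assert not bool(out.loc["B", "flagged_below_half"])


def make_matrix(X, columns):
    index = pd.MultiIndex.from_tuples(
        [(f"g{i}", "P1") for i in range(len(X))], names=["gene", "pair_id"]
    )
    values = pd.DataFrame(X, index=index, columns=columns)
    from pairedsc.importance import FoldChangeMatrix

    prov = pd.DataFrame(PROV_OBSERVED, index=index, columns=columns)
    return FoldChangeMatrix(values, prov, pd.Series(1, index=columns))


def test_constant_response_gives_zero_mse_and_importance_contract():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(200, 4))
    m = make_matrix(X, ["a", "b", "c", "d"])
    target = pd.Series(3.0, index=m.values.index)
    res = fit_importance(m, target, seed=42)
    assert res.test_mse == pytest.approx(0.0, abs=1e-20)
    assert res.cv_mse_mean == pytest.approx(0.0, abs=1e-20)
    assert res.importances.sum() == pytest.approx(1.0, abs=1e-9) or res.importances.sum() == 0.0


def test_informative_column_dominates_importance():
    """Response built from column j plus small noise: j must rank first."""
    rng = np.random.default_rng(1)
    X = rng.normal(size=(5000, 5))
    m = make_matrix(X, list("abcde"))
    target = pd.Series(X[:, 2] + rng.normal(0, 0.01, 5000), index=m.values.index)
    res = fit_importance(m, target, seed=42)
    assert res.ranking.index[0] == "c"
    assert res.importances.sum() == pytest.approx(1.0, abs=1e-9)
    assert res.importances.min() >= 0


def test_fit_importance_is_deterministic():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(300, 3))
    m = make_matrix(X, list("abc"))
    target = pd.Series(X[:, 0] + rng.normal(0, 0.1, 300), index=m.values.index)
    r1 = fit_importance(m, target, seed=42)
    r2 = fit_importance(m, target, seed=42)
    pd.testing.assert_series_equal(r1.importances, r2.importances)
    assert r1.test_mse == r2.test_mse and r1.cv_mse_mean == r2.cv_mse_mean
    p1 = permutation_pvalues(r1, n_perm=50, seed=7)
    p2 = permutation_pvalues(r2, n_perm=50, seed=7)
    pd.testing.assert_series_equal(p1, p2)


def test_permutation_p_counting_rules():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(400, 3))
    X[:, 2] = 1.0  # constant feature
    m = make_matrix(X, list("abc"))
    target = pd.Series(X[:, 0] + rng.normal(0, 0.05, 400), index=m.values.index)
    res = fit_importance(m, target, seed=42)
    p = permutation_pvalues(res, n_perm=40, seed=0)
    # p-values live on the grid {0, 1/n_perm, ..., 1}
    assert np.allclose(p * 40, np.round(p * 40))
    # shuffling a constant feature never changes predictions -> p = 1
    assert p["c"] == 1.0
    # the informative feature always loses score when shuffled -> p = 0
    assert p["a"] == 0.0
    with pytest.raises(ValueError):
        permutation_pvalues(res, n_perm=0)


def test_format_pvalue_display():
    assert format_pvalue(0.0, 1000) == "<0.001"
    assert format_pvalue(0.5, 1000) == "0.5"


def test_cumulative_importance_sums_top_k():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(300, 4))
    m = make_matrix(X, list("abcd"))
    target = pd.Series(X[:, 0] - X[:, 1] + rng.normal(0, 0.1, 300), index=m.values.index)
    res = fit_importance(m, target, seed=42)
    assert cumulative_importance(res, 4) == pytest.approx(1.0, abs=1e-9)
    assert cumulative_importance(res, 2) == pytest.approx(res.ranking.iloc[:2].sum())
    with pytest.raises(ValueError):
        cumulative_importance(res, 5)


def test_cv_and_test_mse_agree_on_homogeneous_data():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(2000, 4))
    m = make_matrix(X, list("abcd"))
    target = pd.Series(X @ np.array([1.0, 0.5, 0.0, 0.0]) + rng.normal(0, 0.3, 2000),
                       index=m.values.index)
    res = fit_importance(m, target, seed=42)
    assert abs(res.test_mse - res.cv_mse_mean) < 2 * res.cv_mse_sd + 0.1 * res.cv_mse_mean
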