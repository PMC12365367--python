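"""Signed adjacency, TOM, dynamic tree cut, eigengenes, trait correlation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pairedsc import (
    cut_modules,
    detected_everywhere_filter,
    module_eigengene,
    module_trait_correlation,
    signed_adjacency,
    tom_similarity,
)
from pairedsc.network import (
    UNASSIGNED,
    ConstantTraitError,
    ZeroVarianceGeneError,
    module_eigengenes,
)


def tom_bruteforce(A):
    """Double-loop reference implementation of the topological overlap."""
    n = A.shape[0]
    B = A.copy()
    np.fill_diagonal(B, 0.0)
    k = B.sum(axis=1)
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(B[i, u] * B[u, j] for u in range(n) if u != i and u != j)
            out[i, j] = (shared + B[i, j]) / (min(k[i], k[j]) + 1 - B[i, j])
    return out


def obs_frame(X, genes=None):
    X = np.asarray(X, dtype=float)
    genes = genes or [f"g{j}" for j in range(X.shape[1])]
    idx = pd.MultiIndex.from_tuples(
        [(f"S{i}", "NK") for i in range(X.shape[0])], names=["sample_id", "cell_type"]
    )
    return pd.DataFrame(X, index=idx, columns=genes)


def test_detected_everywhere_filter():
    totals = pd.DataFrame(
        {"s1": [5, 0, 2], "s2": [1, 3, 2]}, index=["g1", "g2", "g3"]
    )
    assert list(detected_everywhere_filter(totals)) == ["g1", "g3"]
    empty = totals.iloc[0:0]
    assert list(detected_everywhere_filter(empty)) == []


def test_signed_adjacency_limits():
    t = np.linspace(0, 1, 8)
    X = obs_frame(np.column_stack([t, t * 2 + 1, -t, np.random.default_rng(0).normal(size=8)]))
    a = signed_adjacency(X, beta=6.0).to_numpy()
    assert a[0, 1] == pytest.approx(1.0)  # perfectly correlated
    assert a[0, 2] == pytest.approx(0.0, abs=1e-12)  # perfectly anti-correlated
    assert np.all((a >= 0) & (a <= 1)) and np.allclose(a, a.T)
    # exactly uncorrelated pair at beta 6 -> 0.5^6
    Y = obs_frame(np.array([[1, 0], [1, 0], [-1, 0], [-1, 0],
                            [0, 1], [0, -1], [0, 1], [0, -1]], dtype=float))
    ay = signed_adjacency(Y, beta=6.0).to_numpy()
    assert ay[0, 1] == pytest.approx(0.5**6, rel=1e-12)


def test_signed_adjacency_rejects_zero_variance_gene():
    X = obs_frame(np.column_stack([np.arange(5.0), np.ones(5)]), genes=["ok", "flat"])
    with pytest.raises(ZeroVarianceGeneError, match="flat"):
        signed_adjacency(X)


def test_tom_isolated_pair_equals_adjacency():
    A = np.eye(2)
    A[0, 1] = A[1, 0] = 0.37
    tom = tom_similarity(pd.DataFrame(A)).to_numpy()
    assert tom[0, 1] == pytest.approx(0.37, rel=1e-12)
    assert tom[0, 0] == 1.0


def test_tom_matches_bruteforce_on_random_graphs():
    rng = np.random.default_rng(0)
    for _ in range(5):
        n = 30
        A = rng.uniform(0, 1, size=(n, n))
        A = (A + A.T) / 2
        A[rng.uniform(size=(n, n)) < 0.6] = 0.0  # sparsify
        A = np.maximum(A, A.T)
        np.fill_diagonal(A, 1.0)
        tom = tom_similarity(pd.DataFrame(A)).to_numpy()
        ref = tom_bruteforce(A)
        assert np.abs(tom - ref).max() < 1e-12
        assert np.allclose(tom, tom.T) and tom.min() >= 0 and tom.max() <= 1 + 1e-12


@settings(derandomize=True, max_examples=30, deadline=None)
@given(st.integers(0, 2**31 - 1), st.floats(0.1, 0.9))
def test_tom_oracle_property_on_random_sparse_graphs(seed, density):
    """TOM equals the double-loop oracle and stays within [0, 1] for
    arbitrary sparse symmetric adjacencies with unit diagonal."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 16))
    A = rng.uniform(0, 1, size=(n, n))
    A = (A + A.T) / 2
    A[rng.uniform(size=(n, n)) > density] = 0.0
    A = np.maximum(A, A.T)
    np.fill_diagonal(A, 1.0)
    tom = tom_similarity(pd.DataFrame(A)).to_numpy()
    assert np.abs(tom - tom_bruteforce(A)).max() < 1e-12
    assert tom.min() >= 0 and tom.max() <= 1 + 1e-12


def test_tom_rejects_asymmetric_input():
    A = np.eye(3)
    A[0, 1] = 0.5
    with pytest.raises(ValueError, match="symmetric"):
        tom_similarity(pd.DataFrame(A))


def planted_block_diss(sizes, rng, within=0.15, between=0.9, jitter=0.02):
    n = sum(sizes)
    D = between + rng.uniform(-jitter, jitter, size=(n, n))
    start = 0
    for s in sizes:
        D[start : start + s, start : start + s] = within + rng.uniform(
            -jitter, jitter, size=(s, s)
        )
        start += s
    D = (D + D.T) / 2
    np.fill_diagonal(D, 0.0)
    genes = [f"g{j}" for j in range(n)]
    return pd.DataFrame(D, index=genes, columns=genes)


def test_cut_modules_recovers_planted_blocks():
    rng = np.random.default_rng(1)
    diss = planted_block_diss([50, 50], rng)
    labels = cut_modules(diss, deep_split=2, min_module_size=30)
    first = labels.iloc[:50]
    second = labels.iloc[50:]
    assert first.nunique() == 1 and second.nunique() == 1
    assert first.iloc[0] != second.iloc[0]
    assert UNASSIGNED not in set(labels)
    # largest module takes the first color alias
    assert "turquoise" in set(labels)


def test_cut_modules_small_block_is_unassigned():
    rng = np.random.default_rng(2)
    diss = planted_block_diss([40, 10], rng)
    labels = cut_modules(diss, deep_split=2, min_module_size=30)
    assert (labels.iloc[40:] == UNASSIGNED).all()


def test_cut_modules_identical_profiles_single_module():
    n = 40
    genes = [f"g{j}" for j in range(n)]
    diss = pd.DataFrame(np.zeros((n, n)), index=genes, columns=genes)
    labels = cut_modules(diss, min_module_size=30)
    assert labels.nunique() == 1 and labels.iloc[0] != UNASSIGNED


def test_cut_modules_fewer_genes_than_floor():
    genes = ["a", "b", "c"]
    diss = pd.DataFrame(np.zeros((3, 3)), index=genes, columns=genes)
    labels = cut_modules(diss, min_module_size=30)
    assert (labels == UNASSIGNED).all()


def test_eigengene_of_identical_profiles_and_sign_convention():
    rng = np.random.default_rng(3)
    profile = rng.normal(size=12)
    X = obs_frame(np.column_stack([profile * s + o for s, o in [(1, 0), (2, 1), (0.5, -3)]]))
    labels = pd.Series(["m"] * 3, index=X.columns)
    e, var_explained = module_eigengene(X, labels, "m")
    assert var_explained == pytest.approx(1.0)
    z = (profile - profile.mean()) / profile.std()
    np.testing.assert_allclose(np.corrcoef(e, z)[0, 1], 1.0, atol=1e-10)
    assert np.corrcoef(e, X.mean(axis=1))[0, 1] >= 0
    assert np.std(e.to_numpy(), ddof=1) == pytest.approx(1.0)


def test_eigengene_variance_explained_matches_eigendecomposition():
    rng = np.random.default_rng(4)
    X = obs_frame(rng.normal(size=(15, 5)))
    labels = pd.Series(["m"] * 5, index=X.columns)
    _, var_explained = module_eigengene(X, labels, "m")
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    cov = Z.T @ Z
    eig = np.linalg.eigvalsh(cov.to_numpy())
    assert var_explained == pytest.approx(eig[-1] / eig.sum(), rel=1e-10)


def test_module_eigengene_rejects_singleton():
    X = obs_frame(np.random.default_rng(5).normal(size=(10, 2)))
    labels = pd.Series(["m", "other"], index=X.columns)
    with pytest.raises(ValueError, match="m"):
        module_eigengene(X, labels, "m")


def test_module_trait_correlation_limits():
    rng = np.random.default_rng(6)
    e = rng.normal(size=20)
    eig = pd.DataFrame({"m1": e})
    ec = e - e.mean()
    orth = rng.normal(size=20)
    orth = orth - orth.mean()
    orth -= (orth @ ec) / (ec @ ec) * ec  # center, then orthogonalize
    traits = pd.DataFrame({"same": e, "orth": orth})
    r, p = module_trait_correlation(eig, traits)
    assert r.loc["m1", "same"] == pytest.approx(1.0)
    assert abs(r.loc["m1", "orth"]) < 1e-10
    assert p.loc["m1", "orth"] == pytest.approx(1.0, abs=1e-6)
    with pytest.raises(ConstantTraitError):
        module_trait_correlation(eig, pd.DataFrame({"const": np.ones(20)}))


def test_module_recovery_ari_on_planted_latent_factors():
    """Three planted modules driven by latent factors across observations
    are recovered with high agreement (adjusted Rand index)."""
    from sklearn.metrics import adjusted_rand_score

    sizes = [60, 50, 40]
    n_background = 60
    aris = []
    for seed in range(3):
        rng = np.random.default_rng(seed)
        n_obs = 80
        cols, truth_labels = [], []
        for mi, s in enumerate(sizes):
            f = rng.normal(size=n_obs)
            for _ in range(s):
                lam = 0.85
                cols.append(lam * f + np.sqrt(1 - lam**2) * rng.normal(size=n_obs))
                truth_labels.append(mi)
        for _ in range(n_background):
            cols.append(rng.normal(size=n_obs))
            truth_labels.append(-1)
        X = obs_frame(np.column_stack(cols))
        adj = signed_adjacency(X, beta=6.0)
        tom = tom_similarity(adj)
        labels = cut_modules(1.0 - tom, deep_split=2, min_module_size=30)
        n_mod = sum(sizes)
        aris.append(
            adjusted_rand_score(truth_labels[:n_mod], labels.iloc[:n_mod].to_numpy())
        )
    assert np.mean(aris) >= 0.8
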