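"""Generator contracts: determinism, bookkeeping, planted signal, IO round-trip."""

import numpy as np
import pandas as pd
import pytest

from pairedsc import (
    CohortConfig,
    ConfigurationError,
    PlantedEffect,
    PlantedModule,
    log_normalize,
    pair_log2fc_profile,
    read_cohort,
    simulate_cohort,
    write_cohort,
)
from pairedsc.expression import pseudobulk_mean
from pairedsc.io import CohortFormatError


def small_config(**kwargs):
    defaults = dict(
        n_pairs=4,
        cell_types=("A", "B", "C", "D", "E", "F"),
        n_genes=80,
        cells_per_type_per_sample=50,
        seed=1,
    )
    defaults.update(kwargs)
    return CohortConfig(**defaults)


def test_identical_config_and_seed_reproduces_cohort_exactly():
    a1, t1 = simulate_cohort(small_config())
    a2, t2 = simulate_cohort(small_config())
    assert (a1.X != a2.X).nnz == 0
    pd.testing.assert_frame_equal(a1.obs, a2.obs)
    assert t1.to_json() == t2.to_json()


def test_cell_bookkeeping_without_dropout():
    adata, _ = simulate_cohort(small_config())
    per_sample = adata.obs.groupby("sample_id", observed=True).size()
    assert (per_sample == 6 * 50).all()  # 6 cell types x 50 cells
    assert adata.n_obs == 4 * 2 * 6 * 50
    # every pair appears as exactly one case and one control sample
    pairs = adata.obs.drop_duplicates("sample_id").groupby("pair_id", observed=True)["group"]
    for _, groups in pairs:
        assert sorted(groups) == ["case", "control"]


def test_dropout_removes_cell_types_on_recorded_sides():
    adata, truth = simulate_cohort(small_config(dropout_rate=0.2, seed=5))
    assert truth.dropped, "expected at least one dropout event at rate 0.2"
    obs = adata.obs
    for pair, ct, side in truth.dropped:
        sub = obs[(obs["pair_id"] == pair) & (obs["cell_type"] == ct)]
        present = set(sub["group"])
        if side == "both":
            assert present == set()
        else:
            assert side not in present


def test_metadata_columns_complete_and_valid():
    adata, _ = simulate_cohort(small_config())
    obs = adata.obs
    assert not obs.isna().any().any()
    assert set(obs["group"]) == {"case", "control"}
    assert set(obs["sex"]) <= {"F", "M"}
    # paired design: case and control of a pair share sex and ancestry
    per_pair = obs.drop_duplicates("sample_id").groupby("pair_id", observed=True)
    assert (per_pair["sex"].nunique() == 1).all()
    assert (per_pair["ancestry"].nunique() == 1).all()


def test_planted_effect_realizes_target_fold_change():
    """Monte-Carlo check: a +1.0 log2 effect planted in one cell type
    yields a mean realized per-pair log2FC within 0.15 of 1.0."""
    gene, ct = "G0010", "NK"
    cfg = CohortConfig(
        n_pairs=30,
        cell_types=("NK", "B"),
        n_genes=60,
        cells_per_type_per_sample=500,
        baseline_log_mean=0.0,  # ~1 count/cell so the effect is observable
        planted_effects=(PlantedEffect(gene, ct, 1.0),),
        seed=9,
    )
    adata, _ = simulate_cohort(cfg)
    norm = log_normalize(adata)
    lfcs = [
        pair_log2fc_profile(norm, pair, ct).loc[gene, "log2fc"]
        for pair in adata.obs["pair_id"].unique()
    ]
    assert abs(np.mean(lfcs) - 1.0) < 0.15


def test_module_genes_correlate_above_background():
    genes = [f"G{i + 1:04d}" for i in range(100)]
    mod = PlantedModule(name="m1", genes=tuple(genes[:20]), loading=0.8)
    cfg = CohortConfig(
        n_pairs=6,
        cell_types=("A", "B", "C"),
        n_genes=100,
        cells_per_type_per_sample=80,
        baseline_log_mean=0.0,
        planted_modules=(mod,),
        seed=3,
    )
    adata, truth = simulate_cohort(cfg)
    assert set(truth.module_membership) == set(genes[:20])
    norm = log_normalize(adata)
    profiles = pd.DataFrame(
        {
            (s, ct): pseudobulk_mean(norm, s, ct)
            for s in adata.obs["sample_id"].unique()
            for ct in ("A", "B", "C")
        }
    ).T
    corr = np.corrcoef(profiles.to_numpy(), rowvar=False)
    in_mod = corr[:20, :20][np.triu_indices(20, 1)]
    background = corr[20:, 20:][np.triu_indices(80, 1)]
    assert in_mod.mean() > background.mean() + 0.3


def test_invalid_config_errors_name_the_field():
    with pytest.raises(ConfigurationError, match="n_pairs"):
        simulate_cohort(small_config(n_pairs=0))
    with pytest.raises(ConfigurationError, match="dropout_rate"):
        simulate_cohort(small_config(dropout_rate=1.5))
    with pytest.raises(ConfigurationError, match="planted_effects"):
        simulate_cohort(
            small_config(planted_effects=(PlantedEffect("NOPE", "A", 1.0),))
        )
    with pytest.raises(ConfigurationError, match="cell_type"):
        simulate_cohort(
            small_config(planted_effects=(PlantedEffect("G0001", "NOPE", 1.0),))
        )


def test_write_read_round_trip(tmp_path, toy_cohort):
    adata, truth = toy_cohort
    out = write_cohort(adata, tmp_path / "cohort", truth)
    back, truth_back = read_cohort(out)
    assert (back.X != adata.X).nnz == 0
    assert list(back.var_names) == list(adata.var_names)
    pd.testing.assert_frame_equal(
        back.obs.reset_index(drop=True),
        adata.obs.astype(str).reset_index(drop=True),
    )
    assert truth_back.to_json() == truth.to_json()


def test_truncated_features_file_is_rejected(tmp_path, toy_cohort):
    adata, truth = toy_cohort
    out = write_cohort(adata, tmp_path / "cohort", truth)
    features = (out / "features.tsv").read_text().splitlines()
    (out / "features.tsv").write_text("\n".join(features[:-5]) + "\n")
    with pytest.raises(CohortFormatError, match="features"):
        read_cohort(out)


def test_empty_cohort_refused(tmp_path, toy_cohort):
    adata, _ = toy_cohort
    with pytest.raises(CohortFormatError, match="empty"):
        write_cohort(adata[0:0], tmp_path / "empty")
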