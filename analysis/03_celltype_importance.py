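"""Rank cell types by random-forest importance on the fold-change matrix.

Assembles the (gene, pair) x cell-type log2FC matrix with the imputation
rules, fits the 100-tree random forest against the all-cells pseudobulk
fold change, reports permutation significance, cumulative importance of the
top four cell types, and the sex-stratified model diagnostics.
"""

import json
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import AFFECTED, COHORT_DIR, RESULTS

import pandas as pd

from pairedsc import (
    assemble_fc_matrix,
    cumulative_importance,
    fit_importance,
    informative_mask,
    log_normalize,
    permutation_pvalues,
    pseudobulk_response,
    read_cohort,
    run_pairwise_de,
)
from pairedsc.importance import format_pvalue

N_PERM = 200


def main() -> None:
    adata, truth = read_cohort(COHORT_DIR)
    norm = log_normalize(adata)
    info = informative_mask(adata, min_cells=3)
    flagged = info.index[info["flagged_below_half"]].tolist()
    print("informative fractions:",
          {ct: round(f, 3) for ct, f in info['informative_fraction'].items()})
    if flagged:
        print(f"flagged (<50% of pairs informative): {flagged}")

    tables = pd.read_csv(RESULTS / "de_pairwise.tsv", sep="\t")
    matrix = assemble_fc_matrix(tables)
    prov = matrix.provenance.stack().value_counts()
    print("matrix entries by provenance:", prov.to_dict())

    target = pseudobulk_response(norm, matrix)
    result = fit_importance(matrix, target, seed=42)
    pvals = permutation_pvalues(result, n_perm=N_PERM, seed=42)
    out = pd.DataFrame(
        {
            "cell_type": result.importances.index,
            "importance": result.importances.to_numpy(),
            "p_value": pvals.to_numpy(),
            "p_display": [format_pvalue(p, N_PERM) for p in pvals],
        }
    ).sort_values("importance", ascending=False)
    out.to_csv(RESULTS / "importance.tsv", sep="\t", index=False, float_format="%.6g")

    affected = truth.truly_affected_cell_types
    print(f"\ncell-type importance ranking (* = carries planted effects; "
          f"{len(affected)} of {len(result.importances)} types do):")
    for r in out.itertuples():
        mark = " *" if r.cell_type in affected else ""
        print(f"  {r.cell_type:<36s} {r.importance:.4f}  p {r.p_display}{mark}")
    top4 = list(out["cell_type"].iloc[:4])
    n_hit = sum(ct in affected for ct in top4)
    print(f"top-4 ranks held by planted-effect types: {n_hit}/4 "
          f"(strongest planted program: {sorted(set(top4) & set(AFFECTED))})")
    print(f"cumulative importance of top 4: {cumulative_importance(result, 4):.3f}")

    diag = {
        "all": {"cv_mse_mean": result.cv_mse_mean, "cv_mse_sd": result.cv_mse_sd,
                "test_mse": result.test_mse},
    }
    sex_by_pair = adata.obs.drop_duplicates("pair_id").set_index("pair_id")["sex"]
    row_sex = matrix.values.index.get_level_values("pair_id").map(sex_by_pair)
    for sex, label in (("F", "females"), ("M", "males")):
        mask = np.asarray(row_sex == sex)
        if mask.sum() < 50:
            continue
        res_s = fit_importance(matrix, target, seed=42, row_subset=mask)
        diag[label] = {"cv_mse_mean": res_s.cv_mse_mean, "cv_mse_sd": res_s.cv_mse_sd,
                       "test_mse": res_s.test_mse}
        top = res_s.ranking.index[0]
        print(f"{label}: top cell type {top!r}, "
              f"CV MSE {res_s.cv_mse_mean:.4g} (+/- {res_s.cv_mse_sd:.2g}), "
              f"test MSE {res_s.test_mse:.4g}")
    (RESULTS / "importance_diagnostics.json").write_text(json.dumps(diag, indent=1) + "\n")
    print(f"model diagnostics (all): CV MSE {result.cv_mse_mean:.4g} "
          f"(+/- {result.cv_mse_sd:.2g}), test MSE {result.test_mse:.4g}")


if __name__ == "__main__":
    main()
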