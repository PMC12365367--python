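"""Generate the synthetic paired cohort and write it in 10x-style layout.

Prints the cohort composition and the planted ground truth, and stores the
counts, metadata and truth under results/analysis/cohort/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import COHORT_DIR, study_config

from pairedsc import simulate_cohort, write_cohort


def main() -> None:
    cfg = study_config()
    adata, truth = simulate_cohort(cfg)
    write_cohort(adata, COHORT_DIR, truth)

    obs = adata.obs
    print(f"cohort: {adata.n_obs} cells x {adata.n_vars} genes, "
          f"{obs['pair_id'].nunique()} pairs, {obs['cell_type'].nunique()} cell types")
    sexes = obs.drop_duplicates("pair_id")["sex"].value_counts().to_dict()
    ancestries = obs.drop_duplicates("pair_id")["ancestry"].value_counts().to_dict()
    print(f"pair sexes: {sexes}; pair ancestries: {ancestries}")
    print(f"planted effects: {sum(len(v) for v in truth.true_log2fc.values())} "
          f"(gene, cell type) pairs in {len(truth.truly_affected_cell_types)} cell types")
    print(f"opposite-direction genes planted: {len(truth.opposite_direction_genes)}")
    print(f"planted modules: "
          f"{ {m: list(truth.module_membership.values()).count(m) for m in set(truth.module_membership.values())} }")
    print(f"(pair, cell type) dropout events: {len(truth.dropped)}")
    print(f"written to {COHORT_DIR}")


if __name__ == "__main__":
    main()
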