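"""Signed co-expression network on the replicated-DE genes.

Restricts to genes detected in every sample and cell types informative in
every sample, builds the signed adjacency (power 6) and TOM on
(sample x cell type) pseudobulk profiles, cuts modules (deepSplit 2,
minModuleSize 30 scaled to the cohort), and correlates module eigengenes
with cell types, sex and disease status.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import COHORT_DIR, RESULTS

import pandas as pd

from pairedsc import (
    cut_modules,
    log_normalize,
    module_trait_correlation,
    read_cohort,
    signed_adjacency,
    tom_similarity,
)
from pairedsc.expression import pseudobulk_table
from pairedsc.network import (
    UNASSIGNED,
    build_profile_matrix,
    detected_everywhere_filter,
    module_eigengenes,
    sample_gene_totals,
    trait_matrix,
)

MIN_MODULE_SIZE = 30
BETA = 6.0
DEEP_SPLIT = 2


def main() -> None:
    adata, truth = read_cohort(COHORT_DIR)
    norm = log_normalize(adata)
    calls = pd.read_csv(RESULTS / "replicated_de.tsv", sep="\t")
    de_genes = sorted(calls["gene"].unique())
    print(f"replicated-DE genes entering the network stage: {len(de_genes)}")

    totals = sample_gene_totals(adata)
    everywhere = detected_everywhere_filter(totals.loc[de_genes])
    print(f"of these, detected in every sample: {len(everywhere)}")

    from pairedsc import informative_mask

    info = informative_mask(adata, min_cells=3)
    informative_everywhere = info.index[info["informative_fraction"] >= 1.0].tolist()
    print(f"cell types informative in every pair: {len(informative_everywhere)}")

    pseudobulk = pseudobulk_table(norm, cell_types=informative_everywhere)
    X = build_profile_matrix(pseudobulk, everywhere, informative_everywhere)
    X = X.loc[:, X.std(axis=0, ddof=0) > 0]
    print(f"profile matrix: {X.shape[0]} observations x {X.shape[1]} genes")

    adj = signed_adjacency(X, beta=BETA)
    tom = tom_similarity(adj)
    labels = cut_modules(1.0 - tom, deep_split=DEEP_SPLIT, min_module_size=MIN_MODULE_SIZE)
    labels.rename_axis("gene").reset_index().to_csv(
        RESULTS / "modules.tsv", sep="\t", index=False
    )
    sizes = labels.value_counts()
    print("module sizes:", sizes.to_dict())

    # agreement of recovered modules with the planted membership
    planted = pd.Series(truth.module_membership)
    common_genes = labels.index.intersection(planted.index)
    if len(common_genes):
        cross = pd.crosstab(labels[common_genes], planted[common_genes])
        print("recovered-vs-planted gene counts:")
        print(cross.to_string())

    modules = [m for m in sizes.index if m != UNASSIGNED]
    if modules:
        eig = module_eigengenes(X, labels)
        sample_meta = adata.obs.drop_duplicates("sample_id")[["sample_id", "sex", "group"]]
        traits = trait_matrix(X.index, sample_meta)
        r, p = module_trait_correlation(eig, traits)
        long = (
            r.stack().rename("r").to_frame().join(p.stack().rename("p"))
            .rename_axis(["module", "trait"]).reset_index()
        )
        long.to_csv(RESULTS / "module_trait.tsv", sep="\t", index=False, float_format="%.4g")
        eig.reset_index().to_csv(RESULTS / "eigengenes.tsv", sep="\t", index=False,
                                 float_format="%.6g")
        print("\nmodule-disease correlations:")
        for m in eig.columns:
            print(f"  {m:<12s} r = {r.loc[m, 'disease']:+.3f} (p = {p.loc[m, 'disease']:.2g})")


if __name__ == "__main__":
    main()
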