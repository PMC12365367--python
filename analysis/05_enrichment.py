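"""Hypergeometric overrepresentation of the DE genes and of each module.

Builds a gene-set collection containing the planted programs (the
module gene sets and the opposite-direction MYC-like program) plus random
filler sets, then runs ORA of the replicated-DE gene list and of each
recovered module against the detected-gene universe.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import COHORT_DIR, RESULTS, SEED, study_config

import numpy as np
import pandas as pd

from pairedsc import ora, read_cohort, read_gmt
from pairedsc.enrichment import GeneSetCollection, write_gmt
from pairedsc.network import UNASSIGNED


def build_collection() -> GeneSetCollection:
    cfg = study_config()
    genes = cfg.gene_names
    sets: dict[str, frozenset] = {}
    for mod in cfg.planted_modules:
        sets[f"MODULE_{mod.name.upper()}"] = frozenset(mod.genes)
    opposite = sorted(
        {e.gene for e in cfg.planted_effects if e.log2fc < 0}
        & {e.gene for e in cfg.planted_effects if e.log2fc > 0}
    )
    sets["MYC_LIKE_PROGRAM"] = frozenset(opposite)
    up = sorted({e.gene for e in cfg.planted_effects if e.log2fc > 0} - set(opposite))
    sets["AFFECTED_UP_PROGRAM"] = frozenset(up)
    rng = np.random.default_rng(SEED + 2)
    for i in range(9):
        sets[f"RANDOM{i:02d}"] = frozenset(rng.choice(genes, size=60, replace=False))
    sets["ALL_DETECTED"] = frozenset(genes)
    return GeneSetCollection(sets)


def main() -> None:
    adata, _ = read_cohort(COHORT_DIR)
    detected = list(adata.var_names)
    collection = build_collection()
    write_gmt(collection, RESULTS / "genesets.gmt")

    calls = pd.read_csv(RESULTS / "replicated_de.tsv", sep="\t")
    de_genes = sorted(calls["gene"].unique())
    table = ora(de_genes, collection, detected)
    table.to_csv(RESULTS / "ora_de_genes.tsv", sep="\t", index=False, float_format="%.4g")
    print(f"ORA of {len(de_genes)} replicated-DE genes over {len(collection)} sets "
          f"(universe {table['N'].iloc[0]}):")
    for r in table.head(5).itertuples():
        print(f"  {r.set:<24s} GeneRatio {r.gene_ratio:<9s} BgRatio {r.bg_ratio:<9s} "
              f"q = {r.qvalue:.3g}")

    modules_path = RESULTS / "modules.tsv"
    if modules_path.exists():
        labels = pd.read_csv(modules_path, sep="\t").set_index("gene")["module"]
        for m in sorted(set(labels) - {UNASSIGNED}):
            genes_m = labels.index[labels == m].tolist()
            t_m = ora(genes_m, collection, detected)
            t_m.to_csv(RESULTS / f"ora_module_{m}.tsv", sep="\t", index=False,
                       float_format="%.4g")
            top = t_m.iloc[0]
            print(f"module {m} ({len(genes_m)} genes): top set {top['set']} "
                  f"(q = {top['qvalue']:.3g})")


if __name__ == "__main__":
    main()
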