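"""Shared study configuration for the numbered analysis scripts.

One desk-scale paired cohort emulating the study design: 12 case/control
pairs, the full 15-type PBMC annotation, 1200 genes at ~100 cells per type
per sample. Ground truth plants:

* cell-type-specific up-regulation (+1.2 log2) in the four "most affected"
  populations (Th1/17, TFH, NK, Th2), scaled down in female pairs to
  emulate a male-biased effect;
* a MYC-targets-like opposite-direction program: up in naive/helper T
  cells, down in monocytes and memory Tregs;
* three co-expression modules, two of them disease-associated (one up, one
  down in cases) and one disease-neutral (which the DE-gene filter should
  therefore exclude from the network stage).
"""

from pathlib import Path

import numpy as np

from pairedsc import CohortConfig, PlantedEffect, PlantedModule
from pairedsc.config import DEFAULT_CELL_TYPES

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results" / "analysis"
COHORT_DIR = RESULTS / "cohort"

SEED = 7
N_PAIRS = 12
N_GENES = 1200
CELLS_PER_TYPE = 100

AFFECTED = (
    "T cells, CD4+, Th1/17",
    "T cells, CD4+, TFH",
    "NK cells",
    "T cells, CD4+, Th2",
)
MYC_UP_CTS = (
    "T cells, CD4+, naive",
    "T cells, CD4+, TFH",
    "T cells, CD4+, Th1",
    "T cells, CD8+, naive",
)
MYC_DOWN_CTS = (
    "Monocytes, CD14+",
    "Monocytes, CD16+",
    "T cells, CD4+, memory Treg",
)


def study_config() -> CohortConfig:
    base = CohortConfig(
        n_pairs=N_PAIRS,
        cell_types=DEFAULT_CELL_TYPES,
        n_genes=N_GENES,
        cells_per_type_per_sample=CELLS_PER_TYPE,
        dropout_rate=0.06,
        effect_sex_scaling={"F": 0.6, "M": 1.0},
        seed=SEED,
    )
    # reproduce the generator's baseline draw to plant on expressed genes
    rng = np.random.default_rng(SEED)
    baseline = rng.lognormal(base.baseline_log_mean, base.baseline_log_sigma, N_GENES)
    eligible = [base.gene_names[i] for i in np.flatnonzero(baseline >= 0.3)]
    pick = np.random.default_rng(SEED + 1)

    def take(n):
        idx = pick.choice(len(eligible), size=n, replace=False)
        chosen = [eligible[i] for i in idx]
        for i in sorted(idx, reverse=True):
            eligible.pop(int(i))
        return chosen

    effects = []
    per_ct_genes = {}
    for ct in AFFECTED:
        genes = take(40)
        per_ct_genes[ct] = genes
        effects += [PlantedEffect(g, ct, 1.2) for g in genes]
    myc_like = take(25)
    for ct in MYC_UP_CTS:
        effects += [PlantedEffect(g, ct, 1.0) for g in myc_like]
    for ct in MYC_DOWN_CTS:
        effects += [PlantedEffect(g, ct, -1.0) for g in myc_like]

    modules = (
        PlantedModule("disease_up", tuple(take(45)), loading=0.6,
                      trait="disease", trait_shift=1.2),
        PlantedModule("disease_down", tuple(take(40)), loading=0.6,
                      trait="disease", trait_shift=-1.0),
        PlantedModule("neutral", tuple(take(35)), loading=0.6, trait=None),
    )
    return CohortConfig(
        n_pairs=base.n_pairs,
        cell_types=base.cell_types,
        n_genes=base.n_genes,
        cells_per_type_per_sample=base.cells_per_type_per_sample,
        dropout_rate=base.dropout_rate,
        effect_sex_scaling=base.effect_sex_scaling,
        planted_effects=tuple(effects),
        planted_modules=modules,
        seed=SEED,
    )
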