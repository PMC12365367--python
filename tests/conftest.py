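import numpy as np
import pytest

from pairedsc import CohortConfig, PlantedEffect, log_normalize, simulate_cohort
from pairedsc.config import DEFAULT_CELL_TYPES


@pytest.fixture(scope="session")
def toy_cell_types():
    return DEFAULT_CELL_TYPES[:6]


@pytest.fixture(scope="session")
def toy_cohort(toy_cell_types):
    """Small paired cohort with a few planted effects and some dropout."""
    effects = (
        PlantedEffect("G0005", toy_cell_types[2], 1.5),
        PlantedEffect("G0010", toy_cell_types[2], -1.5),
        PlantedEffect("G0010", toy_cell_types[0], 1.5),
    )
    cfg = CohortConfig(
        n_pairs=4,
        cell_types=toy_cell_types,
        n_genes=120,
        cells_per_type_per_sample=40,
        planted_effects=effects,
        dropout_rate=0.08,
        seed=42,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def toy_norm(toy_cohort):
    adata, _ = toy_cohort
    return log_normalize(adata)
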