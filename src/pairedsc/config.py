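"""Configuration objects for the synthetic paired cohort and the pipeline.

The cohort generator emulates a paired case/control single-cell study:
``n_pairs`` independent case/control pairs, each contributing one case and
one control PBMC sample annotated with the same vocabulary of cell types.
Ground-truth structure (cell-type-specific fold changes, co-expressed gene
modules, cell-type dropout) is planted explicitly so that every downstream
stage can be validated against known answers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence, Union

#: Cell-type vocabulary of a 15-population PBMC annotation (immune-cell
#: reference labels: monocyte subsets, NK cells, naive B cells, and the
#: CD4/CD8 T-cell compartments including stimulated and regulatory subsets).
DEFAULT_CELL_TYPES: tuple[str, ...] = (
    "Monocytes, CD14+",
    "Monocytes, CD16+",
    "NK cells",
    "B cells, naive",
    "T cells, CD4+, naive",
    "T cells, CD4+, naive, stimulated",
    "T cells, CD4+, naive Treg",
    "T cells, CD4+, memory Treg",
    "T cells, CD4+, TFH",
    "T cells, CD4+, Th1",
    "T cells, CD4+, Th1/17",
    "T cells, CD4+, Th17",
    "T cells, CD4+, Th2",
    "T cells, CD8+, naive",
    "T cells, CD8+, naive, stimulated",
)

ANCESTRY_LABELS = ("EUR", "AFR", "ASN", "OTH")


class ConfigurationError(ValueError):
    """Raised when a configuration field is invalid; names the field."""


@dataclass(frozen=True)
class PlantedEffect:
    """A cell-type-specific disease effect: case-side means of ``gene`` in
    ``cell_type`` are multiplied by ``2**log2fc``."""

    gene: str
    cell_type: str
    log2fc: float


@dataclass(frozen=True)
class PlantedModule:
    """A co-expressed gene set driven by a shared latent factor.

    Each (sample, active cell type) observation draws a latent factor
    f ~ N(0, 1); member-gene means are multiplied by ``2**(loading * f)``.
    If ``trait`` is "disease" the factor mean is shifted by ``trait_shift``
    in case samples; "sex" shifts male samples; a cell-type name shifts
    observations of that cell type.
    """

    name: str
    genes: tuple[str, ...]
    loading: float = 0.7
    cell_types: Optional[tuple[str, ...]] = None  # None = active everywhere
    trait: Optional[str] = None
    trait_shift: float = 1.0


@dataclass
class CohortConfig:
    """Parameters of the synthetic paired cohort.

    Defaults mirror the emulated study design: 33 case/control pairs with a
    ~10/33 female fraction and a 20/9/1/3 EUR/AFR/ASN/other ancestry split,
    annotated with 15 PBMC cell types. Counts are negative binomial with
    lognormal gene-level baseline means.
    """

    n_pairs: int = 33
    cell_types: Sequence[str] = DEFAULT_CELL_TYPES
    n_genes: int = 2000
    cells_per_type_per_sample: Union[int, tuple[int, int]] = 100
    baseline_log_mean: float = -1.5
    baseline_log_sigma: float = 1.2
    nb_dispersion: float = 2.0
    planted_effects: Sequence[PlantedEffect] = field(default_factory=tuple)
    planted_modules: Sequence[PlantedModule] = field(default_factory=tuple)
    dropout_rate: float = 0.0
    female_fraction: float = 10 / 33
    ancestry_probs: dict = field(
        default_factory=lambda: {"EUR": 20 / 33, "AFR": 9 / 33, "ASN": 1 / 33, "OTH": 3 / 33}
    )
    effect_sex_scaling: dict = field(default_factory=lambda: {"F": 1.0, "M": 1.0})
    seed: int = 0

    # -- derived -----------------------------------------------------------
    @property
    def gene_names(self) -> list[str]:
        width = max(4, len(str(self.n_genes)))
        return [f"G{i + 1:0{width}d}" for i in range(self.n_genes)]

    def validate(self) -> None:
        if self.n_pairs < 1:
            raise ConfigurationError("n_pairs must be >= 1")
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if len(self.cell_types) < 1:
            raise ConfigurationError("cell_types must be non-empty")
        if len(set(self.cell_types)) != len(self.cell_types):
            raise ConfigurationError("cell_types contains duplicate labels")
        c = self.cells_per_type_per_sample
        if isinstance(c, int):
            if c < 1:
                raise ConfigurationError("cells_per_type_per_sample must be >= 1")
        else:
            lo, hi = c
            if lo < 1 or hi < lo:
                raise ConfigurationError(
                    "cells_per_type_per_sample range must satisfy 1 <= lo <= hi"
                )
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be > 0")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ConfigurationError("dropout_rate must be in [0, 1]")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ConfigurationError("female_fraction must be in [0, 1]")
        genes = set(self.gene_names)
        cts = set(self.cell_types)
        for eff in self.planted_effects:
            if eff.gene not in genes:
                raise ConfigurationError(f"planted_effects references unknown gene {eff.gene!r}")
            if eff.cell_type not in cts:
                raise ConfigurationError(
                    f"planted_effects references unknown cell_type {eff.cell_type!r}"
                )
        for mod in self.planted_modules:
            unknown = set(mod.genes) - genes
            if unknown:
                raise ConfigurationError(
                    f"planted_modules module {mod.name!r} references unknown genes "
                    f"{sorted(unknown)[:3]}"
                )
            if mod.cell_types is not None:
                bad = set(mod.cell_types) - cts
                if bad:
                    raise ConfigurationError(
                        f"planted_modules module {mod.name!r} references unknown "
                        f"cell_types {sorted(bad)}"
                    )
            if mod.trait is not None and mod.trait not in ("disease", "sex") and mod.trait not in cts:
                raise ConfigurationError(
                    f"planted_modules module {mod.name!r} trait {mod.trait!r} is not "
                    "'disease', 'sex', or a cell-type label"
                )
        names = [m.name for m in self.planted_modules]
        if len(set(names)) != len(names):
            raise ConfigurationError("planted_modules names must be unique")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cell_types"] = list(self.cell_types)
        return d
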