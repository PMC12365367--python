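"""End-to-end orchestration: simulate -> DE -> importance -> modules -> ORA.

Every stage is a pure function of (inputs, config); all randomness flows
through named seeds, so rerunning a pipeline with the same config and
inputs reproduces byte-identical TSV outputs. Stage tables land in the run
directory together with a JSON report summarizing informative fractions,
DE counts, the importance ranking, module sizes, module-trait correlations
and enrichment results.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import de as de_mod
from . import enrichment as enr_mod
from . import expression as expr_mod
from . import importance as imp_mod
from . import network as net_mod
from .config import CohortConfig, ConfigurationError, PlantedEffect, PlantedModule
from .io import read_cohort, write_cohort
from .simulate import simulate_cohort

logger = logging.getLogger("pairedsc")

FLOAT_FORMAT = "%.6g"


@dataclass
class PipelineConfig:
    """All stage parameters in one place.

    Defaults follow the emulated study: Wilcoxon + BH with FDR < 0.05
    replicated in >= 2 pairs; a 100-tree random forest (unlimited depth,
    min_samples_split 2, random_state 42, 0.8/0.2 split, 5-fold CV, 1000
    permutations); a signed network at soft power 6 cut with deepSplit 2
    and minimum module size 30.
    """

    cohort_dir: Optional[str] = None  # read an existing cohort ...
    simulate: Optional[dict] = None  # ... or generate one from CohortConfig kwargs
    gmt: Optional[str] = None
    out_dir: str = "results/run"
    min_cells: int = 3
    pseudocount: float = 1.0
    scale_factor: float = 1e4
    fdr_threshold: float = 0.05
    min_supporting_pairs: int = 2
    rf: dict = field(
        default_factory=lambda: {
            "n_estimators": 100,
            "max_depth": None,
            "min_samples_split": 2,
            "seed": 42,
            "test_size": 0.2,
            "cv_folds": 5,
            "n_perm": 1000,
            "perm_seed": 42,
        }
    )
    network: dict = field(
        default_factory=lambda: {
            "beta": 6.0,
            "deep_split": 2,
            "min_module_size": 30,
            "network_type": "signed",
        }
    )
    sex_stratified: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for sub, defaults in (("rf", cls().rf), ("network", cls().network)):
            merged = dict(defaults)
            bad = set(getattr(cfg, sub)) - set(defaults)
            if bad:
                raise ConfigurationError(f"unknown {sub} config keys: {sorted(bad)}")
            merged.update(getattr(cfg, sub))
            setattr(cfg, sub, merged)
        return cfg


def _cohort_config_from_dict(d: dict) -> CohortConfig:
    d = dict(d)
    effects = [PlantedEffect(**e) for e in d.pop("planted_effects", [])]
    modules = [
        PlantedModule(**{**m, "genes": tuple(m["genes"])}) for m in d.pop("planted_modules", [])
    ]
    return CohortConfig(planted_effects=tuple(effects), planted_modules=tuple(modules), **d)


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all stages; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    report: dict = {"stages": []}
    try:
        # ---- cohort ----------------------------------------------------
        if config.simulate is not None:
            cohort_cfg = _cohort_config_from_dict(config.simulate)
            logger.info("simulate: %d pairs, %d genes, %d cell types, seed %d",
                        cohort_cfg.n_pairs, cohort_cfg.n_genes,
                        len(cohort_cfg.cell_types), cohort_cfg.seed)
            adata, truth = simulate_cohort(cohort_cfg)
            write_cohort(adata, out / "cohort", truth)
        elif config.cohort_dir is not None:
            adata, truth = read_cohort(config.cohort_dir)
        else:
            raise ConfigurationError("config needs either 'simulate' or 'cohort_dir'")
        report["n_cells"] = int(adata.n_obs)
        report["n_genes"] = int(adata.n_vars)
        report["n_pairs"] = int(adata.obs["pair_id"].nunique())
        report["stages"].append("cohort")

        # ---- normalization + informative fractions ---------------------
        norm = expr_mod.log_normalize(adata, config.scale_factor)
        informative = imp_mod.informative_mask(adata, config.min_cells)
        _write_tsv(informative.reset_index(), out / "informative_cell_types.tsv")
        report["informative_fraction"] = {
            ct: round(float(v), 4) for ct, v in informative["informative_fraction"].items()
        }
        report["stages"].append("informative")

        # ---- pairwise DE ------------------------------------------------
        logger.info("pairwise DE: min_cells=%d", config.min_cells)
        tables = de_mod.run_pairwise_de(norm, config.min_cells, config.pseudocount)
        _write_tsv(tables, out / "de_pairwise.tsv")
        calls = de_mod.replicated_de(tables, config.fdr_threshold, config.min_supporting_pairs)
        _write_tsv(calls, out / "replicated_de.tsv")
        opposite = de_mod.opposite_direction_genes(calls)
        _write_tsv(opposite, out / "opposite_direction.tsv")
        report["n_replicated_de"] = int(len(calls))
        report["de_counts_per_cell_type"] = (
            calls.groupby("cell_type").size().astype(int).to_dict() if len(calls) else {}
        )
        report["n_opposite_direction_genes"] = int(opposite["gene"].nunique()) if len(opposite) else 0
        report["stages"].append("de")

        # ---- fold-change matrix + importance ---------------------------
        matrix = imp_mod.assemble_fc_matrix(tables)
        _write_tsv(matrix.values.reset_index(), out / "fc_matrix.tsv")
        _write_tsv(matrix.provenance.reset_index(), out / "fc_provenance.tsv")
        target = imp_mod.pseudobulk_response(norm, matrix, config.pseudocount)
        rf = config.rf
        result = imp_mod.fit_importance(
            matrix, target, seed=rf["seed"], n_estimators=rf["n_estimators"],
            max_depth=rf["max_depth"], min_samples_split=rf["min_samples_split"],
            test_size=rf["test_size"], cv_folds=rf["cv_folds"],
        )
        pvals = imp_mod.permutation_pvalues(result, rf["n_perm"], rf["perm_seed"])
        imp_table = pd.DataFrame(
            {
                "cell_type": result.importances.index,
                "importance": result.importances.to_numpy(),
                "p_value": pvals.to_numpy(),
                "p_display": [imp_mod.format_pvalue(p, rf["n_perm"]) for p in pvals],
            }
        ).sort_values("importance", ascending=False)
        imp_table = imp_table.join(
            informative["informative_fraction"], on="cell_type"
        )
        _write_tsv(imp_table, out / "importance.tsv")
        diagnostics = {
            "cv_mse_mean": result.cv_mse_mean,
            "cv_mse_sd": result.cv_mse_sd,
            "test_mse": result.test_mse,
            "n_rows": int(len(matrix.values)),
        }
        (out / "importance_diagnostics.json").write_text(json.dumps(diagnostics, indent=1) + "\n")
        k4 = min(4, len(result.importances))
        report["importance_ranking"] = {
            ct: round(float(v), 6) for ct, v in result.ranking.items()
        }
        report["cumulative_importance_top4"] = round(imp_mod.cumulative_importance(result, k4), 4)
        report["importance_diagnostics"] = diagnostics
        report["stages"].append("importance")

        if config.sex_stratified:
            sex_by_pair = adata.obs.drop_duplicates("pair_id").set_index("pair_id")["sex"]
            row_sex = matrix.values.index.get_level_values("pair_id").map(sex_by_pair)
            for sex in ("F", "M"):
                mask = np.asarray(row_sex == sex)
                if mask.sum() < rf["cv_folds"]:
                    logger.warning("sex-stratified run skipped for %s: too few rows", sex)
                    continue
                res_s = imp_mod.fit_importance(
                    matrix, target, seed=rf["seed"], n_estimators=rf["n_estimators"],
                    max_depth=rf["max_depth"], min_samples_split=rf["min_samples_split"],
                    test_size=rf["test_size"], cv_folds=rf["cv_folds"], row_subset=mask,
                )
                report[f"importance_diagnostics_{sex}"] = {
                    "cv_mse_mean": res_s.cv_mse_mean,
                    "cv_mse_sd": res_s.cv_mse_sd,
                    "test_mse": res_s.test_mse,
                }

        # ---- co-expression modules -------------------------------------
        de_genes = sorted(calls["gene"].unique()) if len(calls) else []
        net = config.network
        module_result = None
        if len(de_genes) >= net["min_module_size"]:
            totals = net_mod.sample_gene_totals(adata)
            everywhere = net_mod.detected_everywhere_filter(totals.loc[de_genes])
            all_informative = informative.index[
                informative["informative_fraction"] >= 1.0
            ].tolist()
            report["n_de_genes_detected_everywhere"] = int(len(everywhere))
            report["n_cell_types_informative_everywhere"] = len(all_informative)
            if len(everywhere) >= net["min_module_size"] and len(all_informative) >= 1:
                pseudobulk = expr_mod.pseudobulk_table(norm, cell_types=all_informative)
                X = net_mod.build_profile_matrix(pseudobulk, everywhere, all_informative)
                X = X.loc[:, X.std(axis=0, ddof=0) > 0]
                adj = net_mod.signed_adjacency(X, net["beta"])
                tom = net_mod.tom_similarity(adj)
                labels = net_mod.cut_modules(
                    1.0 - tom, net["deep_split"], net["min_module_size"]
                )
                _write_tsv(labels.rename_axis("gene").reset_index(), out / "modules.tsv")
                if (labels != net_mod.UNASSIGNED).any():
                    eig = net_mod.module_eigengenes(X, labels)
                    sample_meta = adata.obs.drop_duplicates("sample_id")[
                        ["sample_id", "sex", "group"]
                    ]
                    traits = net_mod.trait_matrix(X.index, sample_meta)
                    r, p = net_mod.module_trait_correlation(eig, traits)
                    _write_tsv(eig.reset_index(), out / "eigengenes.tsv")
                    long = (
                        r.stack().rename("r").to_frame()
                        .join(p.stack().rename("p"))
                        .rename_axis(["module", "trait"]).reset_index()
                    )
                    _write_tsv(long, out / "module_trait.tsv")
                    module_result = net_mod.ModuleResult(labels, eig, r, p, dict(net))
                    report["module_sizes"] = labels.value_counts().astype(int).to_dict()
                report["stages"].append("modules")
        else:
            logger.info("modules: skipped (%d DE genes < min_module_size)", len(de_genes))

        # ---- enrichment -------------------------------------------------
        if config.gmt is not None and len(de_genes):
            collection = enr_mod.read_gmt(config.gmt)
            detected = list(adata.var_names)
            try:
                table = enr_mod.ora(de_genes, collection, detected)
                _write_tsv(table, out / "ora_de_genes.tsv")
                report["top_enrichment"] = table.iloc[0][["set", "qvalue"]].to_dict()
            except ValueError as exc:
                logger.warning("ORA on DE genes skipped: %s", exc)
            if module_result is not None:
                for m in module_result.eigengenes.columns:
                    genes_m = module_result.labels.index[module_result.labels == m]
                    try:
                        t_m = enr_mod.ora(genes_m, collection, detected)
                    except ValueError:
                        continue
                    _write_tsv(t_m, out / f"ora_module_{m}.tsv")
            report["stages"].append("ora")

        (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True) + "\n")
        logger.info("pipeline complete: %s", ", ".join(report["stages"]))
        return out
    except Exception:
        logger.exception("pipeline failed")
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
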