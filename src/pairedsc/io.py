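"""Reading and writing cohorts in a 10x-style directory layout.

Layout::

    <dir>/matrix.mtx     Matrix Market coordinate, genes x cells, 1-based
    <dir>/features.tsv   gene_id <TAB> gene_symbol
    <dir>/barcodes.tsv   one barcode per line
    <dir>/cells.tsv      per-cell metadata (barcode, sample_id, pair_id,
                         group, cell_type, sex, ancestry)
    <dir>/truth.json     optional planted ground truth
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .simulate import GroundTruth, OBS_COLUMNS


class CohortFormatError(ValueError):
    """Malformed cohort directory (dimension mismatch, bad metadata, ...)."""


def write_cohort(adata: ad.AnnData, out_dir, truth: Optional[GroundTruth] = None) -> Path:
    """Write a cohort to ``out_dir``; returns the directory path.

    The matrix is written genes x cells (10x convention); metadata and
    features as TSV. An empty cohort is rejected rather than silently
    producing empty files.
    """
    if adata.n_obs == 0 or adata.n_vars == 0:
        raise CohortFormatError("refusing to write an empty cohort (0 cells or 0 genes)")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mat = sp.coo_matrix(adata.X.T)  # genes x cells
    scipy.io.mmwrite(str(out / "matrix.mtx"), mat, field="integer")
    adata.var[["gene_id", "gene_symbol"]].to_csv(
        out / "features.tsv", sep="\t", header=False, index=False
    )
    (out / "barcodes.tsv").write_text("\n".join(adata.obs["barcode"]) + "\n")
    adata.obs[OBS_COLUMNS].to_csv(out / "cells.tsv", sep="\t", index=False)
    if truth is not None:
        (out / "truth.json").write_text(truth.to_json() + "\n")
    return out


def read_cohort(in_dir) -> tuple[ad.AnnData, Optional[GroundTruth]]:
    """Read a cohort directory written by :func:`write_cohort`.

    Round-trips exactly: counts, gene order, barcode order and metadata all
    match the written cohort. Raises :class:`CohortFormatError` with the
    offending file (and line, where known) on inconsistency.
    """
    d = Path(in_dir)
    mtx_path = d / "matrix.mtx"
    if not mtx_path.exists():
        raise CohortFormatError(f"{mtx_path} does not exist")
    try:
        mat = scipy.io.mmread(str(mtx_path))
    except Exception as exc:  # scipy raises plain ValueError on bad triplets
        raise CohortFormatError(f"malformed Matrix Market file {mtx_path}: {exc}") from exc
    mat = sp.csr_matrix(mat.T)  # cells x genes
    features = _read_tsv_lines(d / "features.tsv", expected_fields=2)
    barcodes = [row[0] for row in _read_tsv_lines(d / "barcodes.tsv", expected_fields=1)]
    if len(features) != mat.shape[1]:
        raise CohortFormatError(
            f"features.tsv has {len(features)} rows but matrix has {mat.shape[1]} genes"
        )
    if len(barcodes) != mat.shape[0]:
        raise CohortFormatError(
            f"barcodes.tsv has {len(barcodes)} rows but matrix has {mat.shape[0]} cells"
        )
    cells = pd.read_csv(d / "cells.tsv", sep="\t", dtype=str)
    missing = set(OBS_COLUMNS) - set(cells.columns)
    if missing:
        raise CohortFormatError(f"cells.tsv is missing columns {sorted(missing)}")
    if len(cells) != len(barcodes):
        raise CohortFormatError(
            f"cells.tsv has {len(cells)} rows but barcodes.tsv has {len(barcodes)}"
        )
    for lineno, (a, b) in enumerate(zip(cells["barcode"], barcodes), start=2):
        if a != b:
            raise CohortFormatError(
                f"cells.tsv line {lineno}: barcode {a!r} does not match barcodes.tsv ({b!r})"
            )
    bad_group = ~cells["group"].isin(["case", "control"])
    if bad_group.any():
        lineno = int(np.flatnonzero(bad_group)[0]) + 2
        raise CohortFormatError(f"cells.tsv line {lineno}: group must be 'case' or 'control'")
    gene_ids = [row[0] for row in features]
    obs = cells.copy()
    obs.index = pd.Index(obs["barcode"].to_numpy(), name="barcode_index")
    var = pd.DataFrame(
        {"gene_id": gene_ids, "gene_symbol": [row[1] for row in features]},
        index=pd.Index(gene_ids, name="gene"),
    )
    X = mat.astype(np.int64)
    X.sort_indices()
    adata = ad.AnnData(X=X, obs=obs, var=var)
    adata.layers["counts"] = adata.X.copy()
    truth = None
    truth_path = d / "truth.json"
    if truth_path.exists():
        truth = GroundTruth.from_json(truth_path.read_text())
    return adata, truth


def _read_tsv_lines(path: Path, expected_fields: int) -> list[list[str]]:
    if not path.exists():
        raise CohortFormatError(f"{path} does not exist")
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < expected_fields:
                raise CohortFormatError(
                    f"{path} line {lineno}: expected {expected_fields} fields, got {len(fields)}"
                )
            rows.append(fields)
    return rows
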