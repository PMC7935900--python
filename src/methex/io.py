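"""Readers and writers for the pipeline's tab-delimited and Matrix Market
formats, plus the flat key/value run configuration.

Conventions
-----------
* expression: TSV, first column gene symbol, header row of sample ids,
  log2-scale values (``linear=True`` applies log2(x+1) on load);
* clinical/survival: TSV with columns sample, time, event (+ covariates);
* metabolome: TSV, first column metabolite id, empty cells = missing;
* single cell: Matrix Market coordinate file (genes x cells) with two
  metadata TSVs (cells, genes), loaded into an AnnData (cells x genes).

All writers round-trip losslessly at full float precision (repr format).
"""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as scio
from scipy import sparse

from .exceptions import ConfigurationError, InputError

__all__ = [
    "read_expression",
    "write_expression",
    "read_survival",
    "write_survival",
    "read_metabolites",
    "write_metabolites",
    "read_single_cell",
    "write_single_cell",
    "read_table",
    "write_table",
    "read_config",
    "write_manifest",
]

_FLOAT_FMT = "%.17g"
_BAD = object()  # sentinel for unparseable cells


def _read_tsv_matrix(path, what: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"{what} file not found: {path}")
    if path.stat().st_size == 0:
        raise InputError(f"{what} file is empty (no data): {path}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    dup = pd.Index(header)[pd.Index(header).duplicated()].tolist()
    if dup:  # pandas would silently mangle these to S1.1 etc.
        raise InputError(f"duplicate sample ids in {what} file: {sorted(set(dup))}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[1] == 0 or df.shape[0] == 0:
        raise InputError(f"{what} file has no data rows/columns: {path}")
    return df


def _to_numeric(df: pd.DataFrame, what: str, allow_missing: bool) -> pd.DataFrame:
    def parse(v):
        # Python's float() is correctly rounded, unlike the default C parser,
        # so writer/reader round-trip exactly at %.17g
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return np.nan
        try:
            return float(v)
        except ValueError:
            return _BAD

    out = df.map(parse)
    bad = out == _BAD
    if bad.any().any():
        row = bad.any(axis=1).idxmax()
        col = bad.loc[row].idxmax()
        raise InputError(f"non-numeric value in {what} at row '{row}', column '{col}': "
                         f"'{df.loc[row, col]}'")
    if not allow_missing and out.isna().any().any():
        row = out.isna().any(axis=1).idxmax()
        col = out.loc[row].isna().idxmax()
        raise InputError(f"missing value in {what} at row '{row}', column '{col}'")
    return out.astype(float)


def read_expression(path, linear: bool = False) -> pd.DataFrame:
    """Load a genes x samples expression TSV.

    Duplicate gene rows are collapsed by their mean; duplicate sample ids or
    non-numeric cells are errors. ``linear=True`` applies log2(x+1) for
    matrices not already on the log scale.
    """
    df = _read_tsv_matrix(path, "expression")
    values = _to_numeric(df, "expression matrix", allow_missing=False)
    if values.index.duplicated().any():
        values = values.groupby(level=0, sort=False).mean()
    if linear:
        if (values < 0).any().any():
            raise InputError("negative values are incompatible with --linear log2(x+1) transform")
        values = np.log2(values + 1.0)
    if not np.isfinite(values.to_numpy()).all():
        raise InputError("expression matrix contains non-finite values after loading")
    return values


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene", float_format=_FLOAT_FMT)


def read_survival(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"clinical file not found: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    from .survival import validate_survival

    return validate_survival(df)


def write_survival(surv: pd.DataFrame, path) -> None:
    surv.to_csv(path, sep="\t", index_label="sample", float_format=_FLOAT_FMT)


def read_metabolites(path) -> pd.DataFrame:
    """Metabolite x sample abundances; empty cells become NaN (flagged
    missing, never silently zero)."""
    df = _read_tsv_matrix(path, "metabolite")
    values = _to_numeric(df, "metabolite table", allow_missing=True)
    if (values < 0).any().any():
        raise InputError("metabolite abundances must be non-negative")
    return values


def write_metabolites(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="metabolite", float_format=_FLOAT_FMT)


def read_table(path) -> pd.DataFrame:
    """Generic TSV with a header row (peak/DE/score tables)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"table not found: {path}")
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path, index: bool = True, index_label=None) -> None:
    df.to_csv(path, sep="\t", index=index, index_label=index_label, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# single cell
# ---------------------------------------------------------------------------

def read_single_cell(mtx_path, cells_path, genes_path) -> ad.AnnData:
    """Load a genes x cells Matrix Market file with cell/gene metadata into an
    AnnData (cells x genes).

    The cells table needs columns cell_id, cell_type, tumor (optional
    true_program); the genes table a gene column. Metadata row counts must
    match the matrix dimensions.
    """
    for p, what in ((mtx_path, "matrix"), (cells_path, "cells metadata"), (genes_path, "genes metadata")):
        if not Path(p).exists():
            raise InputError(f"{what} file not found: {p}")
    X = sparse.csr_matrix(scio.mmread(mtx_path))  # genes x cells
    cells = pd.read_csv(cells_path, sep="\t")
    genes = pd.read_csv(genes_path, sep="\t")
    if len(genes) != X.shape[0]:
        raise InputError(
            f"genes metadata rows ({len(genes)}) do not match matrix rows ({X.shape[0]})"
        )
    if len(cells) != X.shape[1]:
        raise InputError(
            f"cells metadata rows ({len(cells)}) do not match matrix columns ({X.shape[1]})"
        )
    for col in ("cell_id", "cell_type", "tumor"):
        if col not in cells.columns:
            raise InputError(f"cells metadata lacks required column '{col}'")
    if "gene" not in genes.columns:
        raise InputError("genes metadata lacks required column 'gene'")
    obs = cells.set_index("cell_id")
    var = genes.set_index("gene")
    adata = ad.AnnData(X=X.T.tocsr(), obs=obs, var=var)
    adata.obs_names = adata.obs_names.astype(str)
    adata.var_names = adata.var_names.astype(str)
    return adata


def write_single_cell(adata: ad.AnnData, out_dir) -> dict[str, Path]:
    """Write an AnnData as matrix.mtx (genes x cells) + cells.tsv + genes.tsv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mtx": out_dir / "matrix.mtx",
        "cells": out_dir / "cells.tsv",
        "genes": out_dir / "genes.tsv",
    }
    X = adata.X
    if not sparse.issparse(X):
        X = sparse.csr_matrix(np.asarray(X))
    scio.mmwrite(str(paths["mtx"]), X.T.tocoo(), precision=17)
    cells = adata.obs.copy()
    cells.insert(0, "cell_id", cells.index)
    cells.to_csv(paths["cells"], sep="\t", index=False)
    genes = adata.var.copy()
    genes.insert(0, "gene", genes.index)
    genes.to_csv(paths["genes"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# configuration and manifest
# ---------------------------------------------------------------------------

def read_config(path) -> dict[str, str]:
    """Parse a flat ``key = value`` configuration file.

    Blank lines and ``#`` comments are ignored; keys are lower-cased; a
    repeated key is an error.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    out: dict[str, str] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigurationError(f"{path}:{lineno}: expected 'key = value', got '{raw}'")
        key, value = line.split("=", 1)
        key = key.strip().lower()
        if key in out:
            raise ConfigurationError(f"{path}:{lineno}: duplicate key '{key}'")
        out[key] = value.strip()
    return out


def write_manifest(path, seed, parameters: dict, stages: list[str]) -> None:
    """JSON run manifest: seed, package version, parameters and stage list.

    Deliberately timestamp-free so that identical runs are byte-identical.
    """
    from . import __version__

    payload = {
        "package": "methex",
        "version": __version__,
        "seed": seed,
        "parameters": parameters,
        "stages": stages,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
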