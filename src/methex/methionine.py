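"""Methionine salvage / de novo pathway activity scoring.

Bulk tumors are scored by the cumulative (summed) expression of the six
salvage genes and the five de novo genes, summarised as the
salvage-to-de-novo *ratio*. Single malignant cells use the *difference* of
the two sums instead; cells above the mean difference of the whole malignant
population are salvage-high, the rest de-novo-high, and a tumor is
salvage-dominant when a strict majority of its malignant cells are
salvage-high.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .exceptions import InputError
from .genes import DENOVO_GENES, SALVAGE_GENES

__all__ = [
    "bulk_pathway_scores",
    "sc_pathway_difference",
    "classify_cells",
    "tumor_dominance",
    "geneset_group_compare",
]


def _available(genes, index, set_name: str) -> list[str]:
    present = [g for g in genes if g in index]
    if not present:
        raise InputError(f"no {set_name} pathway gene present in the matrix")
    missing = sorted(set(genes) - set(present))
    if missing:
        warnings.warn(f"{set_name} pathway genes missing, skipped: {missing}", stacklevel=3)
    return present


def bulk_pathway_scores(expr: pd.DataFrame, aggregate: str = "sum") -> pd.DataFrame:
    """Per-sample salvage and de novo cumulative expression and their ratio.

    ``aggregate="mean"`` averages instead of summing, for users worried about
    the unequal set sizes (6 vs 5); the default follows the cumulative-sum
    reading. An undefined ratio (de novo sum 0) is returned as NaN and
    flagged in the ``ratio_defined`` column.
    """
    if aggregate not in ("sum", "mean"):
        raise InputError(f"aggregate must be 'sum' or 'mean', got '{aggregate}'")
    salv = _available(SALVAGE_GENES, expr.index, "salvage")
    deno = _available(DENOVO_GENES, expr.index, "de novo")
    agg = (lambda df: df.sum(axis=0)) if aggregate == "sum" else (lambda df: df.mean(axis=0))
    salvage = agg(expr.loc[salv].astype(float))
    denovo = agg(expr.loc[deno].astype(float))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(denovo != 0, salvage / denovo, np.nan)
    out = pd.DataFrame(
        {
            "salvage": salvage,
            "denovo": denovo,
            "ratio": ratio,
            "ratio_defined": denovo != 0,
        },
        index=expr.columns,
    )
    if (~out["ratio_defined"]).any():
        warnings.warn("zero de novo sum: ratio undefined for some samples", stacklevel=2)
    return out


def sc_pathway_difference(sc) -> pd.DataFrame:
    """Salvage-minus-de-novo expression difference per malignant cell.

    ``sc`` is an AnnData (cells x genes) whose ``obs['cell_type']`` marks
    malignant cells; log-normalised values are summed per pathway.
    """
    if "cell_type" not in sc.obs:
        raise InputError("single-cell dataset lacks obs['cell_type']")
    mal = sc[sc.obs["cell_type"] == "malignant"]
    if mal.n_obs == 0:
        raise InputError("no malignant cells in dataset")
    salv = _available(SALVAGE_GENES, mal.var_names, "salvage")
    deno = _available(DENOVO_GENES, mal.var_names, "de novo")

    def pathway_sum(genes):
        X = mal[:, genes].X
        if sparse.issparse(X):
            return np.asarray(X.sum(axis=1)).ravel()
        return np.asarray(X, dtype=float).sum(axis=1)

    salvage = pathway_sum(salv)
    denovo = pathway_sum(deno)
    return pd.DataFrame(
        {
            "salvage": salvage,
            "denovo": denovo,
            "difference": salvage - denovo,
            "tumor": mal.obs["tumor"].to_numpy() if "tumor" in mal.obs else "NA",
        },
        index=mal.obs_names,
    )


def classify_cells(scores: pd.DataFrame) -> pd.Series:
    """Label malignant cells salvage-high / de-novo-high.

    A cell is salvage-high iff its salvage-minus-de-novo difference is
    strictly above the mean difference of the whole malignant population;
    ties (including the all-equal case) fall to de-novo-high.
    """
    if len(scores) < 2:
        raise InputError("classify_cells needs at least 2 cells")
    diff = scores["difference"].astype(float)
    labels = np.where(diff > diff.mean(), "salvage-high", "de novo-high")
    return pd.Series(labels, index=scores.index, name="program")


def tumor_dominance(labels: pd.Series, tumor_ids: pd.Series) -> pd.DataFrame:
    """Per-tumor composition and metabolic dominance.

    A tumor is salvage-dominant iff its fraction of salvage-high malignant
    cells strictly exceeds 0.5. Tumors contributing zero labelled cells are
    excluded with a warning.
    """
    labels = pd.Series(labels)
    tumor_ids = pd.Series(tumor_ids).reindex(labels.index)
    if tumor_ids.isna().any():
        raise InputError("every labelled cell needs a tumor id")
    rows = []
    for tumor, idx in labels.groupby(tumor_ids).groups.items():
        sub = labels.loc[idx]
        n_s = int((sub == "salvage-high").sum())
        n_d = int((sub == "de novo-high").sum())
        total = n_s + n_d
        if total == 0:
            warnings.warn(f"tumor {tumor} has no labelled malignant cells; excluded", stacklevel=2)
            continue
        frac = n_s / total
        rows.append(
            {
                "tumor": tumor,
                "n_salvage_high": n_s,
                "n_denovo_high": n_d,
                "salvage_fraction": frac,
                "dominance": "salvage-dominant" if frac > 0.5 else "de novo-dominant",
            }
        )
    return pd.DataFrame(rows).set_index("tumor")


def geneset_group_compare(
    sc,
    gene_set,
    dominance: pd.DataFrame,
    cell_type: str = "T",
    equal_var: bool = True,
) -> dict:
    """Compare mean gene-set expression of T cells between tumor groups.

    Per-cell mean over ``gene_set`` (symbols matched case-insensitively), then
    a two-sided t test between cells from salvage-dominant and
    de-novo-dominant tumors. Student's equal-variance t is the default;
    ``equal_var=False`` switches to Welch.
    """
    upper = {str(g).upper(): g for g in sc.var_names}
    matched = [upper[str(g).upper()] for g in gene_set if str(g).upper() in upper]
    if not matched:
        raise InputError("no gene of the requested set is present in the dataset")
    cells = sc[sc.obs["cell_type"] == cell_type]
    if "tumor" not in cells.obs:
        raise InputError("single-cell dataset lacks obs['tumor']")
    dom = dominance["dominance"].reindex(cells.obs["tumor"]).to_numpy()
    X = cells[:, matched].X
    if sparse.issparse(X):
        X = np.asarray(X.todense())
    per_cell = np.asarray(X, dtype=float).mean(axis=1)

    a = per_cell[dom == "salvage-dominant"]
    b = per_cell[dom == "de novo-dominant"]
    if len(a) < 2 or len(b) < 2:
        raise InputError("both dominance groups need >=2 cells for the t test")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        # degenerate: no within-group variability; identical means -> no effect
        t, p = (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
    else:
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return {
        "genes_used": matched,
        "mean_salvage_dominant": float(a.mean()),
        "mean_denovo_dominant": float(b.mean()),
        "n_salvage_dominant": int(len(a)),
        "n_denovo_dominant": int(len(b)),
        "t": float(t),
        "p": float(p),
        "test": "student" if equal_var else "welch",
    }
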