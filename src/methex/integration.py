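"""Copy-number / expression integration and the SAM-MTA-driven gene rule.

Two downstream integration steps: (1) associate per-gene copy-number summary
values (log-ratio scale, as emitted by segmentation software) with expression
by Pearson correlation and call amplification / deep deletion at +-0.8; and
(2) intersect a differential chromatin-accessibility table with a
differential-expression table to define the SAM/MTA-driven T-cell genes.
Both differential tables are inputs — peak calling and differential testing
are handled by the established upstream tools.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InputError
from .genes import METHIONINE_GENES

__all__ = ["cnv_expression_assoc", "intersect_driven_genes"]

AMP_THRESHOLD = 0.8
DEL_THRESHOLD = -0.8


def _call(value: float) -> str:
    if value >= AMP_THRESHOLD:
        return "amplification"
    if value <= DEL_THRESHOLD:
        return "deep deletion"
    return "none"


def cnv_expression_assoc(
    cnv: pd.DataFrame, expr: pd.DataFrame, genes=None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Associate per-gene copy-number summary values with expression.

    Parameters
    ----------
    cnv : DataFrame, genes x samples
        Per-gene summary (median probe) values on a log-ratio scale.
    expr : DataFrame, genes x samples (log2 expression)
    genes : optional iterable
        Genes to analyse; defaults to the 11 methionine recycling genes.

    Returns
    -------
    summary : DataFrame indexed by gene
        Pearson r with expression, its p-value, n shared samples, and counts
        of amplification / deep-deletion calls at the +-0.8 thresholds.
    calls : DataFrame (gene, sample, value, call) in long form
    """
    genes = list(genes) if genes is not None else [g for g in METHIONINE_GENES if g in cnv.index]
    if not genes:
        raise InputError("no genes to analyse in the copy-number table")
    shared = [s for s in cnv.columns if s in expr.columns]
    rows = []
    call_rows = []
    for g in genes:
        if g not in cnv.index:
            warnings.warn(f"gene {g} absent from copy-number table; skipped", stacklevel=2)
            continue
        values = cnv.loc[g, shared].astype(float) if shared else pd.Series(dtype=float)
        for s in cnv.columns:
            v = float(cnv.loc[g, s])
            call_rows.append({"gene": g, "sample": s, "value": v, "call": _call(v)})
        r = p = np.nan
        n_used = 0
        if g in expr.index and len(shared) >= 3:
            e = expr.loc[g, shared].astype(float)
            mask = values.notna() & e.notna()
            n_used = int(mask.sum())
            if n_used >= 3 and values[mask].nunique() > 1 and e[mask].nunique() > 1:
                r, p = stats.pearsonr(values[mask], e[mask])
        else:
            warnings.warn(f"gene {g}: <3 shared samples or no expression; correlation skipped",
                          stacklevel=2)
        all_calls = pd.Series([_call(float(v)) for v in cnv.loc[g]])
        rows.append(
            {
                "gene": g,
                "expr_corr": float(r) if np.isfinite(r) else np.nan,
                "corr_p": float(p) if np.isfinite(p) else np.nan,
                "n_shared": n_used,
                "n_amplification": int((all_calls == "amplification").sum()),
                "n_deep_deletion": int((all_calls == "deep deletion").sum()),
            }
        )
    summary = pd.DataFrame(rows).set_index("gene")
    calls = pd.DataFrame(call_rows)
    return summary, calls


def intersect_driven_genes(
    peak_table: pd.DataFrame,
    de_table: pd.DataFrame,
    peak_fdr: float = 0.05,
    peak_fc: float = 1.5,
    expr_fdr: float = 0.05,
    exclusion_list=(),
) -> pd.DataFrame:
    """SAM/MTA-driven T-cell genes by table intersection.

    A gene qualifies when its chromatin peak is differential
    (``q < peak_fdr`` and fold change magnitude ``> peak_fc``), its expression
    is significantly *upregulated* in salvage-dominant tumors
    (``q < expr_fdr`` with positive log2 fold change), the two directions
    agree (more accessible and upregulated), and it is not on the
    tumor-specific exclusion list.

    Both tables need columns ``gene``, ``log2fc`` and ``fdr``.
    """
    for name, tab in (("peak_table", peak_table), ("de_table", de_table)):
        for col in ("gene", "log2fc", "fdr"):
            if col not in tab.columns:
                raise InputError(f"{name} lacks required column '{col}'")
    peaks = peak_table.set_index("gene")
    de = de_table.set_index("gene")
    exclusion = set(exclusion_list)

    lfc_cut = np.log2(peak_fc)
    peak_pass = peaks[(peaks["fdr"] < peak_fdr) & (peaks["log2fc"].abs() > lfc_cut)]
    de_pass = de[(de["fdr"] < expr_fdr) & (de["log2fc"] > 0)]

    rows = []
    for g in peak_pass.index:
        if g in exclusion or g not in de_pass.index:
            continue
        if peak_pass.loc[g, "log2fc"] <= 0:  # direction concordance
            continue
        rows.append(
            {
                "gene": g,
                "peak_log2fc": float(peak_pass.loc[g, "log2fc"]),
                "peak_fdr": float(peak_pass.loc[g, "fdr"]),
                "expr_log2fc": float(de_pass.loc[g, "log2fc"]),
                "expr_fdr": float(de_pass.loc[g, "fdr"]),
            }
        )
    out = pd.DataFrame(rows, columns=["gene", "peak_log2fc", "peak_fdr", "expr_log2fc", "expr_fdr"])
    return out.sort_values("gene").reset_index(drop=True)
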