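"""Metabolome handling: minimum-imputation, tumor/non-tumor ratios, the
ES-metabolite Spearman screen and serum MTA normalisation.

Metabolite tables are pandas DataFrames (metabolite x sample) of non-negative
abundances with NaN marking missing measurements.
"""

from __future__ import annotations

import math
import warnings
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import InputError

__all__ = [
    "impute_min",
    "tumor_nontumor_ratio",
    "spearman_with_p",
    "es_metabolite_screen",
    "serum_mta_normalize",
]

#: Sample sizes at or below this use the exact permutation null for Spearman p.
EXACT_PERMUTATION_N = 9


def impute_min(table: pd.DataFrame) -> pd.DataFrame:
    """Replace each metabolite's missing values by its observed minimum.

    Metabolites with no observed value at all are dropped with a warning.
    """
    table = table.astype(float)
    all_missing = table.isna().all(axis=1)
    if all_missing.any():
        dropped = table.index[all_missing].tolist()
        warnings.warn(f"metabolites with no observed value dropped: {dropped}", stacklevel=2)
        table = table[~all_missing]
    mins = table.min(axis=1)
    return table.apply(lambda row: row.fillna(mins[row.name]), axis=1)


def tumor_nontumor_ratio(tumor: pd.DataFrame, nontumor: pd.DataFrame) -> pd.DataFrame:
    """Per-metabolite tumor/non-tumor abundance ratio over matched samples.

    Samples present in only one compartment are excluded with a warning; a
    zero non-tumor denominator yields NaN (flagged missing ratio). Apply
    :func:`impute_min` first.
    """
    shared = [s for s in tumor.columns if s in nontumor.columns]
    unpaired = sorted(set(tumor.columns).symmetric_difference(nontumor.columns))
    if unpaired:
        warnings.warn(f"unpaired samples excluded from T/N ratio: {unpaired}", stacklevel=2)
    if not shared:
        raise InputError("no matched tumor/non-tumor sample pairs")
    metabolites = [m for m in tumor.index if m in nontumor.index]
    t = tumor.loc[metabolites, shared].astype(float)
    n = nontumor.loc[metabolites, shared].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = t / n.where(n != 0)
    return ratio


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman rho at small n."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(rx)
    rx = (rx - rx.mean()) / rx.std()
    count = 0
    total = math.factorial(n)
    thresh = abs(rho_obs) - 1e-12
    for perm in permutations(ry):
        ryp = np.asarray(perm)
        r = float(np.mean(rx * (ryp - ryp.mean()) / ryp.std()))
        if abs(r) >= thresh:
            count += 1
    return count / total


def spearman_with_p(x, y) -> tuple[float, float]:
    """Spearman rho with a two-sided p-value: exact permutation null for
    n <= 9, t-approximation otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise InputError("spearman_with_p needs two equal-length vectors of n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InputError("Spearman correlation undefined for a constant vector")
    rho = float(stats.spearmanr(x, y).statistic)
    if len(x) <= EXACT_PERMUTATION_N:
        p = _exact_spearman_p(x, y, rho)
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return rho, p


def es_metabolite_screen(
    es: pd.Series | pd.DataFrame,
    ratios: pd.DataFrame,
    fdr_max: float = 0.05,
    min_overlap: int = 8,
) -> pd.DataFrame:
    """Screen metabolite T/N ratios against the exhaustion score.

    Spearman rank correlation per metabolite over the samples shared with the
    score table, BH adjustment across all tested metabolites, hits at
    ``q < fdr_max``. Returns a waterfall-ordered table (|rho| descending)
    with columns rho, p, q, n_used, hit. Constant metabolite vectors and
    metabolites with fewer than ``min_overlap`` paired samples are excluded
    with a note.
    """
    if isinstance(es, pd.DataFrame):
        es = es["ES"]
    es = es.astype(float)
    rows = []
    skipped: list[str] = []
    for met, values in ratios.iterrows():
        paired = pd.concat([es, values.astype(float)], axis=1, join="inner").dropna()
        if len(paired) < min_overlap:
            skipped.append(f"{met} (n={len(paired)})")
            continue
        x = paired.iloc[:, 0].to_numpy()
        y = paired.iloc[:, 1].to_numpy()
        if np.ptp(y) == 0 or np.ptp(x) == 0:
            skipped.append(f"{met} (constant)")
            continue
        rho, p = spearman_with_p(x, y)
        rows.append({"metabolite": met, "rho": rho, "p": p, "n_used": len(paired)})
    if skipped:
        warnings.warn(f"metabolites excluded from screen: {skipped}", stacklevel=2)
    if not rows:
        raise InputError("no metabolite eligible for the screen")
    out = pd.DataFrame(rows).set_index("metabolite")
    _, q, _, _ = multipletests(out["p"].to_numpy(), method="fdr_bh")
    out["q"] = q
    out["hit"] = out["q"] < fdr_max
    return out.sort_values("rho", key=lambda s: s.abs(), ascending=False)


def serum_mta_normalize(
    serum: pd.DataFrame, mta_id: str = "MTA", methionine_id: str = "methionine"
) -> pd.Series:
    """Serum MTA normalised to serum methionine, per sample.

    Samples missing the methionine measurement (or with zero methionine) are
    flagged NaN with a warning rather than dropped.
    """
    for mid in (mta_id, methionine_id):
        if mid not in serum.index:
            raise InputError(f"serum table lacks metabolite '{mid}'")
    mta = serum.loc[mta_id].astype(float)
    met = serum.loc[methionine_id].astype(float)
    bad = met.isna() | (met == 0)
    if bad.any():
        warnings.warn(
            f"samples with missing/zero serum methionine flagged NaN: {list(met.index[bad])}",
            stacklevel=2,
        )
    out = mta / met.where(~bad)
    out.name = "serum_MTA_normalized"
    return out
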