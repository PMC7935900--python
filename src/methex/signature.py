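"""Exhaustion-signature derivation and CD3 normalisation.

A T-cell exhaustion signature is the set of genes specifically upregulated in
the exhausted T-cell cluster of a clustered single-cell dataset. In bulk
tumors, signature-gene expression is normalised to T-cell content by
subtracting the per-sample mean of CD3D/CD3E/CD3G on the log2 scale
(equivalently, a ratio on the linear scale).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, stats
from statsmodels.stats.multitest import multipletests

from .exceptions import InputError, MissingGeneError
from .genes import CD3_GENES

__all__ = ["GeneSignature", "derive_signature", "cd3_normalize"]


@dataclass
class GeneSignature:
    """An ordered, unique gene list with its derivation statistics."""

    genes: list[str]
    stats: pd.DataFrame  # index gene; columns lfc, p, q

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def to_frame(self) -> pd.DataFrame:
        out = self.stats.copy()
        out.insert(0, "gene", out.index)
        return out.reset_index(drop=True)

    @classmethod
    def from_genes(cls, genes) -> "GeneSignature":
        genes = list(dict.fromkeys(genes))
        empty = pd.DataFrame(index=genes, columns=["lfc", "p", "q"], dtype=float)
        return cls(genes=genes, stats=empty)


def _dense(sc) -> np.ndarray:
    """cells x genes dense expression from an AnnData."""
    X = sc.X
    if sparse.issparse(X):
        return np.asarray(X.todense(), dtype=float)
    return np.asarray(X, dtype=float)


def derive_signature(
    sc,
    cluster_labels,
    exhausted_cluster_id,
    lfc_min: float = 1.0,
    fdr_max: float = 0.05,
) -> GeneSignature:
    """Genes specifically upregulated in the exhausted cluster.

    A gene enters the signature when (i) the two-sided rank-sum test of
    exhausted cells against all other cells pooled survives BH adjustment at
    ``fdr_max``, (ii) its log2 fold change (mean difference on the log scale)
    is at least ``lfc_min``, and (iii) its fold change against *every* other
    cluster individually is positive — the "specifically" criterion.

    Parameters
    ----------
    sc : AnnData
        Cells x genes, log-scale values. Typically T cells only.
    cluster_labels : array-like aligned to ``sc.obs``
    exhausted_cluster_id : label of the exhausted cluster
    """
    labels = np.asarray(pd.Series(cluster_labels))
    if labels.shape[0] != sc.n_obs:
        raise InputError(
            f"cluster_labels length {labels.shape[0]} != number of cells {sc.n_obs}"
        )
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise InputError("derive_signature needs at least 2 clusters")
    if exhausted_cluster_id not in set(uniq):
        raise InputError(f"exhausted cluster '{exhausted_cluster_id}' not present in labels")

    X = _dense(sc)
    genes = np.asarray(sc.var_names)
    exh = labels == exhausted_cluster_id
    if exh.sum() < 3:
        raise InputError("exhausted cluster has fewer than 3 cells")

    a = X[exh]
    b = X[~exh]
    pvals = np.ones(X.shape[1])
    for j in range(X.shape[1]):
        if np.ptp(X[:, j]) == 0:
            continue
        pvals[j] = stats.mannwhitneyu(a[:, j], b[:, j], alternative="two-sided").pvalue
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    lfc = a.mean(axis=0) - b.mean(axis=0)

    # positive fold change against each other cluster individually
    specific = np.ones(X.shape[1], dtype=bool)
    for cl in uniq:
        if cl == exhausted_cluster_id:
            continue
        other = X[labels == cl]
        specific &= a.mean(axis=0) > other.mean(axis=0)

    keep = (qvals < fdr_max) & (lfc >= lfc_min) & specific
    table = pd.DataFrame({"lfc": lfc, "p": pvals, "q": qvals}, index=genes)[keep]
    table = table.sort_values(["q", "lfc"], ascending=[True, False])
    if table.empty:
        warnings.warn("derive_signature: no gene passed the thresholds", stacklevel=2)
    return GeneSignature(genes=table.index.tolist(), stats=table)


def cd3_normalize(expr: pd.DataFrame, signature) -> pd.DataFrame:
    """Subtract the per-sample CD3D/E/G mean from each signature gene.

    ``expr`` is a genes x samples log2 matrix. Non-signature genes pass
    through untouched; genes of the signature absent from the matrix are
    skipped with a warning.
    """
    missing_cd3 = [g for g in CD3_GENES if g not in expr.index]
    if missing_cd3:
        raise MissingGeneError(f"CD3 normaliser genes missing from matrix: {missing_cd3}")
    sig_genes = list(signature)
    present = [g for g in sig_genes if g in expr.index]
    absent = sorted(set(sig_genes) - set(present))
    if absent:
        warnings.warn(f"cd3_normalize: {len(absent)} signature genes absent, skipped: {absent[:10]}",
                      stacklevel=2)
    out = expr.copy()
    cd3_mean = expr.loc[list(CD3_GENES)].mean(axis=0)
    out.loc[present] = expr.loc[present].sub(cd3_mean, axis=1)
    return out
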