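"""Vectorised single-covariate Cox partial-likelihood machinery.

The supervised-PC score fit screens every candidate gene with a univariate
Cox model and refits inside every leave-one-out fold and permutation
replicate, so the screen must cost microseconds, not the milliseconds of a
general fitting package. This module implements Newton–Raphson maximisation
of the Breslow partial likelihood simultaneously for a whole matrix of
covariates. Event times in the intended uses are continuous (no ties), where
Breslow and Efron coincide; the general-purpose :func:`methex.survival.cox_fit`
delegates to statsmodels and supports both tie conventions.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["univariate_cox_batch", "logrank_2group"]

_MAX_ITER = 40
_TOL = 1e-10
_STEP_CAP = 4.0


def _risk_set_ends(time_desc: np.ndarray) -> np.ndarray:
    """Per position (times sorted descending), the index of the last member of
    its tie block — i.e. the end of the prefix forming the Breslow risk set."""
    n = time_desc.shape[0]
    changed = np.concatenate([time_desc[1:] != time_desc[:-1], [True]])
    ends = np.flatnonzero(changed)
    block_id = np.concatenate([[0], np.cumsum(time_desc[1:] != time_desc[:-1])])
    return ends[block_id]


def univariate_cox_batch(
    x: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    max_iter: int = _MAX_ITER,
    tol: float = _TOL,
):
    """Fit a univariate Cox model to every column of ``x`` at once.

    Parameters
    ----------
    x : (n, g) array
        One covariate per column.
    time, event : (n,) arrays
        Follow-up time and event indicator (1 = death).

    Returns
    -------
    beta, se, p : (g,) arrays
        Maximum partial-likelihood estimate, its standard error from the
        observed information, and the two-sided Wald p-value. Columns with no
        usable information (constant covariate or no events) come back as
        ``beta=0, se=inf, p=1``.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.ndim == 1:
        x = x[:, None]
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    n, g = x.shape

    order = np.argsort(-time, kind="stable")
    t = time[order]
    d = event[order].astype(bool)
    X = x[order]
    # centring leaves beta invariant and keeps exp() well scaled
    X = X - X.mean(axis=0)

    ends = _risk_set_ends(t)
    ev = np.flatnonzero(d)
    if ev.size == 0:
        return np.zeros(g), np.full(g, np.inf), np.ones(g)
    ev_ends = ends[ev]
    sum_x_events = X[ev].sum(axis=0)

    beta = np.zeros(g)
    info = np.full(g, np.nan)
    active = np.ones(g, dtype=bool)
    for _ in range(max_iter):
        eta = np.clip(X * beta, -60.0, 60.0)
        w = np.exp(eta)
        c0 = np.cumsum(w, axis=0)
        c1 = np.cumsum(w * X, axis=0)
        c2 = np.cumsum(w * X * X, axis=0)
        s0 = c0[ev_ends]
        r1 = c1[ev_ends] / s0
        score = sum_x_events - r1.sum(axis=0)
        info = (c2[ev_ends] / s0 - r1 * r1).sum(axis=0)
        ok = info > 1e-12
        step = np.zeros(g)
        step[ok] = score[ok] / info[ok]
        np.clip(step, -_STEP_CAP, _STEP_CAP, out=step)
        step[~active] = 0.0
        beta = beta + step
        active = active & (np.abs(step) >= tol)
        if not active.any():
            break

    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.where(info > 1e-12, 1.0 / np.sqrt(np.maximum(info, 1e-300)), np.inf)
    z = np.where(np.isfinite(se), beta / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    degenerate = ~np.isfinite(se)
    beta = np.where(degenerate, 0.0, beta)
    p = np.where(degenerate, 1.0, p)
    return beta, se, p


def logrank_2group(time, event, in_group1) -> float:
    """Mantel–Cox log-rank chi-square for a two-group comparison.

    Returns 0.0 when one group is empty or the pooled variance vanishes; the
    LOOCV permutation wrapper relies on this degenerate value rather than an
    exception so that null permutations with a constant score still compare.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    g1 = np.asarray(in_group1).astype(bool)
    if g1.all() or (~g1).all():
        return 0.0

    order = np.argsort(time, kind="stable")
    t = time[order]
    d = event[order]
    g = g1[order]
    n = t.shape[0]

    event_times = np.unique(t[d])
    o_minus_e = 0.0
    var = 0.0
    for et in event_times:
        at_risk = t >= et
        n_tot = int(at_risk.sum())
        n1 = int((at_risk & g).sum())
        dying = d & (t == et)
        d_tot = int(dying.sum())
        d1 = int((dying & g).sum())
        if n_tot < 2:
            continue
        e1 = d_tot * n1 / n_tot
        v = d_tot * (n_tot - d_tot) / (n_tot - 1) * n1 * (n_tot - n1) / n_tot**2
        o_minus_e += d1 - e1
        var += v
    if var <= 0:
        return 0.0
    return float(o_minus_e**2 / var)
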