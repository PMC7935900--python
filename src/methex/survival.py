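"""Survival statistics: median-split stratification, Kaplan–Meier estimation,
log-rank testing and Cox proportional-hazards fits.

Survival tables are pandas DataFrames with at least columns ``time``
(positive follow-up time) and ``event`` (1 = death, 0 = censored), indexed by
sample id. Estimation is delegated to lifelines (KM, log-rank) and
statsmodels PHReg (Cox; it exposes both Efron and Breslow tie handling).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.duration.hazard_regression import PHReg

from .exceptions import InputError

__all__ = [
    "KMEstimate",
    "CoxFit",
    "median_split",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "validate_survival",
]


def validate_survival(surv: pd.DataFrame) -> pd.DataFrame:
    """Check the time/event contract and return the table unchanged."""
    for col in ("time", "event"):
        if col not in surv.columns:
            raise InputError(f"survival table lacks required column '{col}'")
    if (surv["time"] <= 0).any():
        bad = surv.index[surv["time"] <= 0].tolist()
        raise InputError(f"non-positive survival times for samples {bad}")
    if not surv["event"].isin([0, 1]).all():
        raise InputError("event indicator must be 0/1")
    return surv


def median_split(values: pd.Series) -> pd.Series:
    """Label each sample ``high`` or ``low`` by the cohort median.

    Ties at the median go to the low group (deterministic and conservative,
    shared with the exhaustion-score risk grouping).
    """
    values = pd.Series(values).astype(float)
    if len(values) < 2:
        raise InputError("median_split needs at least 2 samples")
    if values.nunique() == 1:
        raise InputError("all values identical; no median split possible")
    med = values.median()
    return pd.Series(np.where(values > med, "high", "low"), index=values.index, name="risk_group")


@dataclass
class KMEstimate:
    """Product-limit estimate for one group: S(t) at observed event times."""

    group: str
    times: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "at_risk": self.at_risk,
                "events": self.n_events,
                "survival": self.survival,
                "group": self.group,
            }
        )

    def plot(self, ax=None, **kwargs):
        """Step plot of the survival curve (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        xs = np.concatenate([[0.0], self.times])
        ys = np.concatenate([[1.0], self.survival])
        ax.step(xs, ys, where="post", label=self.group, **kwargs)
        ax.set_xlabel("time")
        ax.set_ylabel("S(t)")
        ax.set_ylim(0, 1.05)
        return ax


def km_estimate(surv: pd.DataFrame, groups: pd.Series | None = None) -> dict[str, KMEstimate]:
    """Kaplan–Meier estimate per group (a single group when ``groups`` is None)."""
    validate_survival(surv)
    if groups is None:
        groups = pd.Series("all", index=surv.index)
    groups = pd.Series(groups).reindex(surv.index)
    if groups.isna().any():
        raise InputError("every sample needs a group label for km_estimate")

    out: dict[str, KMEstimate] = {}
    for label, idx in surv.groupby(groups).groups.items():
        sub = surv.loc[idx]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"])
        tab = kmf.event_table
        ev = tab[tab["observed"] > 0]
        surv_at = kmf.survival_function_.loc[ev.index, kmf.survival_function_.columns[0]]
        out[str(label)] = KMEstimate(
            group=str(label),
            times=ev.index.to_numpy(dtype=float),
            at_risk=ev["at_risk"].to_numpy(dtype=int),
            n_events=ev["observed"].to_numpy(dtype=int),
            survival=surv_at.to_numpy(dtype=float),
        )
    return out


def logrank_test(surv: pd.DataFrame, groups: pd.Series) -> tuple[float, float]:
    """Mantel–Cox log-rank chi-square across groups; two-sided p with
    ``df = n_groups - 1``."""
    validate_survival(surv)
    groups = pd.Series(groups).reindex(surv.index)
    if groups.isna().any():
        raise InputError("every sample needs a group label for logrank_test")
    counts = groups.value_counts()
    if len(counts) < 2:
        raise InputError("logrank_test needs at least 2 non-empty groups")
    if surv["event"].sum() < 1:
        raise InputError("logrank_test needs at least one event")
    res = multivariate_logrank_test(surv["time"], groups, surv["event"])
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CoxFit:
    """Cox proportional-hazards fit summary."""

    coef: pd.Series
    se: pd.Series
    hr: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    p: pd.Series
    n: int
    n_events: int
    ties: str
    converged: bool = True
    warnings_: list[str] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "se": self.se,
                "HR": self.hr,
                "HR 95% low": self.ci_low,
                "HR 95% high": self.ci_high,
                "p": self.p,
            }
        )

    def to_dict(self) -> dict:
        return {
            "coef": self.coef.to_dict(),
            "se": self.se.to_dict(),
            "hr": self.hr.to_dict(),
            "ci_low": self.ci_low.to_dict(),
            "ci_high": self.ci_high.to_dict(),
            "p": self.p.to_dict(),
            "n": self.n,
            "n_events": self.n_events,
            "ties": self.ties,
            "converged": self.converged,
        }


def cox_fit(surv: pd.DataFrame, covariates: pd.DataFrame | pd.Series, ties: str = "efron") -> CoxFit:
    """Maximum partial-likelihood Cox regression with Wald CIs and p-values.

    ``covariates`` may be a Series (univariable) or DataFrame (multivariable
    adjustment, e.g. stage/cirrhosis/subtype dummies). ``ties`` is ``"efron"``
    (default) or ``"breslow"``.
    """
    validate_survival(surv)
    if ties not in ("efron", "breslow"):
        raise InputError(f"unknown tie-handling method '{ties}'")
    if isinstance(covariates, pd.Series):
        covariates = covariates.to_frame()
    covariates = covariates.reindex(surv.index)
    if covariates.shape[1] < 1:
        raise InputError("cox_fit needs at least one covariate")
    if covariates.isna().any().any():
        raise InputError("covariates contain missing values after aligning to survival table")
    n_events = int(surv["event"].sum())
    if n_events < covariates.shape[1] + 1:
        raise InputError(
            f"too few events ({n_events}) for {covariates.shape[1]} covariate(s)"
        )

    model = PHReg(
        surv["time"].to_numpy(dtype=float),
        covariates.to_numpy(dtype=float),
        status=surv["event"].to_numpy(dtype=int),
        ties=ties,
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        res = model.fit(disp=False)
    msgs = [str(w.message) for w in caught]

    names = covariates.columns
    coef = pd.Series(res.params, index=names)
    se = pd.Series(res.bse, index=names)
    converged = bool(np.all(np.isfinite(coef)) and np.all(np.abs(coef) < 20))
    if not converged:
        msgs.append("possible monotone likelihood (perfect separation): estimates unreliable")
        warnings.warn(msgs[-1], stacklevel=2)
    zcrit = stats.norm.ppf(0.975)
    hr = np.exp(coef)
    return CoxFit(
        coef=coef,
        se=se,
        hr=hr,
        ci_low=np.exp(coef - zcrit * se),
        ci_high=np.exp(coef + zcrit * se),
        p=pd.Series(2 * stats.norm.sf(np.abs(coef / se)), index=names),
        n=len(surv),
        n_events=n_events,
        ties=ties,
        converged=converged,
        warnings_=msgs,
    )
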