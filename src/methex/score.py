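"""The survival-weighted Exhaustion Score (ES) and the cytolytic score (CYT).

The ES is a supervised principal-components Cox model built on CD3-normalised
exhaustion-signature expression:

1. screen genes with univariate Cox models, keeping Wald ``p < alpha``;
2. standardise the selected features and take their first principal component;
3. fit a univariate Cox model to the PC score (coefficient ``beta``);
4. weight each feature ``w_i = beta * loading_i / sd_i`` so the sample-level
   score ``ES_j = sum_i w_i x_ij - offset`` reproduces ``beta * PC_j`` up to
   centring; the offset is the training mean of ``sum_i w_i x_ij`` so the
   training-set mean ES is exactly 0.

Higher ES means higher hazard by construction (the Cox coefficient absorbs
the direction of the PC). The published model uses features YARS, PKM2, TPI1
and MTHFD2 with offset 12.77237; its weights are loaded via
:meth:`ExhaustionScoreResults.from_weights` when available.

The module follows the statsmodels convention: build an
:class:`ExhaustionScoreModel` from data, call :meth:`~ExhaustionScoreModel.fit`
to obtain an :class:`ExhaustionScoreResults`, and predict / cross-validate
from there. Thin functional wrappers (:func:`select_features`,
:func:`fit_score_model`, :func:`apply_score`, :func:`loocv_validate`) expose
the same operations.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._cox import logrank_2group, univariate_cox_batch
from .exceptions import InputError, MissingGeneError
from .genes import CYTOLYTIC_GENES, PUBLISHED_OFFSET, resolve_symbol
from .survival import validate_survival

__all__ = [
    "ExhaustionScoreModel",
    "ExhaustionScoreResults",
    "LoocvResult",
    "select_features",
    "fit_score_model",
    "apply_score",
    "loocv_validate",
    "cytolytic_score",
    "PUBLISHED_OFFSET",
]


# ---------------------------------------------------------------------------
# array-level fitting core (shared by fit, LOOCV folds and permutations)
# ---------------------------------------------------------------------------

def _screen_arrays(X: np.ndarray, time: np.ndarray, event: np.ndarray, alpha: float):
    """Univariate Cox screen; returns selected column indices sorted by p."""
    beta, se, p = univariate_cox_batch(X, time, event)
    sel = np.flatnonzero(p < alpha)
    sel = sel[np.argsort(p[sel], kind="stable")]
    return sel, beta, se, p


def _fit_arrays(X: np.ndarray, time: np.ndarray, event: np.ndarray, alpha: float):
    """Supervised-PC fit on raw arrays.

    Returns (selected_idx, weights, offset, pc_beta, fallback_note).
    A zero-feature screen yields the degenerate all-zero model (score = 0).
    """
    sel, beta_u, se_u, p_u = _screen_arrays(X, time, event, alpha)
    note = None
    if sel.size == 0:
        return sel, np.zeros(0), 0.0, 0.0, "no feature passed the screen; zero model"
    sub = X[:, sel]
    sd = sub.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.all():
        sel = sel[keep]
        sub = sub[:, keep]
        sd = sd[keep]
        note = "constant selected feature(s) dropped"
    if sel.size == 0:
        return sel, np.zeros(0), 0.0, 0.0, "all selected features constant; zero model"
    if sel.size == 1:
        note = note or "single feature: univariate Cox weight fallback"
    m = sub.mean(axis=0)
    Z = (sub - m) / sd
    if sel.size == 1:
        v = np.ones(1)
        scores = Z[:, 0]
    else:
        _, _, vt = np.linalg.svd(Z, full_matrices=False)
        v = vt[0]
        scores = Z @ v
    pc_beta = univariate_cox_batch(scores[:, None], time, event)[0][0]
    w = pc_beta * v / sd
    offset = float((sub @ w).mean())
    return sel, w, offset, float(pc_beta), note


# ---------------------------------------------------------------------------
# results object
# ---------------------------------------------------------------------------

@dataclass
class ExhaustionScoreResults:
    """A fitted (or published) exhaustion-score model.

    ``ES_j = sum_i weights[i] * x_ij - offset`` over the model features, on
    CD3-normalised log2 expression.
    """

    features: list[str]
    weights: pd.Series
    offset: float
    alpha: float | None = None
    screen: pd.DataFrame | None = None  # per-feature univariate Cox stats
    pc_beta: float | None = None
    n: int | None = None
    n_events: int | None = None
    note: str | None = None

    @classmethod
    def from_weights(cls, features, weights, offset: float = PUBLISHED_OFFSET):
        """Build a scoring model from externally supplied weights, e.g. the
        published four-feature model once its weights are at hand."""
        features = list(features)
        weights = pd.Series(np.asarray(weights, dtype=float), index=features)
        if len(features) != len(weights) or len(features) == 0:
            raise InputError("features and weights must be non-empty and equal length")
        if not np.isfinite(offset):
            raise InputError("offset must be finite")
        return cls(features=features, weights=weights, offset=float(offset))

    def _resolve(self, expr: pd.DataFrame) -> dict[str, str]:
        mapping: dict[str, str] = {}
        missing: list[str] = []
        for g in self.features:
            found = resolve_symbol(g, expr.index)
            if found is None:
                missing.append(g)
            else:
                mapping[g] = found
        if missing:
            raise MissingGeneError(f"model features missing from matrix (after aliasing): {missing}")
        return mapping

    def predict(self, expr: pd.DataFrame) -> pd.DataFrame:
        """Score every sample of a genes x samples matrix.

        Returns a ScoreTable: one row per sample with column ``ES``. Feature
        symbols are resolved through the PKM/PKM2, YARS/YARS1 alias table
        before a missing-feature error is raised.
        """
        if len(self.features) == 0:
            es = pd.Series(-self.offset, index=expr.columns, name="ES")
            return es.to_frame()
        mapping = self._resolve(expr)
        sub = expr.loc[[mapping[g] for g in self.features]]
        es = sub.T.to_numpy(dtype=float) @ self.weights.to_numpy() - self.offset
        return pd.DataFrame({"ES": es}, index=expr.columns)

    def risk_groups(self, expr: pd.DataFrame) -> pd.Series:
        """Median-split high/low risk groups of the predicted scores."""
        from .survival import median_split

        return median_split(self.predict(expr)["ES"])

    def summary(self) -> str:
        lines = ["Exhaustion score model", "=" * 30]
        lines.append(f"features ({len(self.features)}): {', '.join(self.features) or '(none)'}")
        for g in self.features:
            lines.append(f"  w[{g}] = {self.weights[g]: .6f}")
        lines.append(f"offset = {self.offset:.5f}")
        if self.alpha is not None:
            lines.append(f"screen alpha = {self.alpha}")
        if self.n is not None:
            lines.append(f"training n = {self.n}, events = {self.n_events}")
        if self.pc_beta is not None:
            lines.append(f"Cox coefficient on PC1 = {self.pc_beta:.6f}")
        if self.note:
            lines.append(f"note: {self.note}")
        return "\n".join(lines)

    def to_json(self, path=None) -> str:
        payload = {
            "features": self.features,
            "weights": self.weights.tolist(),
            "offset": self.offset,
            "alpha": self.alpha,
            "pc_beta": self.pc_beta,
            "n": self.n,
            "n_events": self.n_events,
            "note": self.note,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, path) -> "ExhaustionScoreResults":
        with open(path) as fh:
            payload = json.load(fh)
        res = cls.from_weights(payload["features"], payload["weights"], payload["offset"])
        res.alpha = payload.get("alpha")
        res.pc_beta = payload.get("pc_beta")
        res.n = payload.get("n")
        res.n_events = payload.get("n_events")
        res.note = payload.get("note")
        return res


@dataclass
class LoocvResult:
    """Leave-one-out cross-validated risk groups and their log-rank test."""

    groups: pd.Series
    statistic: float
    p_chi2: float
    permutation_p: float | None
    n_permutations: int
    fold_notes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# model object
# ---------------------------------------------------------------------------

class ExhaustionScoreModel:
    """Supervised-PC Cox exhaustion-score model.

    Parameters
    ----------
    normalized_expr : DataFrame, genes x samples
        CD3-normalised log2 expression of candidate signature genes.
    surv : DataFrame indexed by sample id with columns time, event
    alpha : float
        Univariate Cox screen threshold (published training used 0.001).
    """

    def __init__(self, normalized_expr: pd.DataFrame, surv: pd.DataFrame, alpha: float = 0.001):
        validate_survival(surv)
        if not 0 < alpha <= 1:
            raise InputError(f"alpha must be in (0, 1], got {alpha}")
        common = [s for s in normalized_expr.columns if s in surv.index]
        if len(common) < 10:
            raise InputError(f"need >=10 samples shared by expression and survival, got {len(common)}")
        self.expr = normalized_expr[common]
        self.surv = surv.loc[common]
        if int(self.surv["event"].sum()) < 3:
            raise InputError("need >=3 events to fit a score model")
        self.alpha = float(alpha)
        self.gene_names = np.asarray(self.expr.index)
        self._X = self.expr.T.to_numpy(dtype=float)
        self._time = self.surv["time"].to_numpy(dtype=float)
        self._event = self.surv["event"].to_numpy(dtype=int)

    @classmethod
    def from_dataframe(cls, expr: pd.DataFrame, clinical: pd.DataFrame, alpha: float = 0.001):
        return cls(expr, clinical, alpha=alpha)

    # -- operations ---------------------------------------------------------
    def select_features(self) -> tuple[list[str], pd.DataFrame]:
        """Univariate Cox screen at ``alpha``; genes ordered by ascending p."""
        sel, beta, se, p = _screen_arrays(self._X, self._time, self._event, self.alpha)
        table = pd.DataFrame(
            {"beta": beta, "se": se, "p": p}, index=self.gene_names
        ).iloc[sel]
        if sel.size == 0:
            warnings.warn(f"no gene passed the Cox screen at alpha={self.alpha}", stacklevel=2)
        return list(self.gene_names[sel]), table

    def fit(self) -> ExhaustionScoreResults:
        sel, w, offset, pc_beta, note = _fit_arrays(self._X, self._time, self._event, self.alpha)
        if note is not None:
            warnings.warn(f"fit_score_model: {note}", stacklevel=2)
        features = list(self.gene_names[sel])
        _, _, p_all = univariate_cox_batch(self._X[:, sel], self._time, self._event) if sel.size else (
            np.zeros(0), np.zeros(0), np.zeros(0))
        screen = pd.DataFrame({"p": p_all}, index=features)
        return ExhaustionScoreResults(
            features=features,
            weights=pd.Series(w, index=features),
            offset=offset,
            alpha=self.alpha,
            screen=screen,
            pc_beta=pc_beta,
            n=len(self.surv),
            n_events=int(self._event.sum()),
            note=note,
        )

    def loocv(self, n_permutations: int = 0, seed: int | None = None) -> LoocvResult:
        """Leave-one-out cross-validated risk grouping with optional
        permutation p-value.

        Each sample is scored by a model refit on the other n-1 samples and
        assigned high/low against the training-fold median score (ties go
        low). The log-rank statistic of the cross-validated groups is compared
        against ``n_permutations`` survival-label shuffles of the whole
        procedure.
        """
        n = self._X.shape[0]
        if n < 20:
            raise InputError(f"LOOCV needs n >= 20 samples, got {n}")

        def cv_stat(time, event, collect=False):
            group_high = np.zeros(n, dtype=bool)
            notes = []
            for i in range(n):
                mask = np.ones(n, dtype=bool)
                mask[i] = False
                if event[mask].sum() == 0:
                    notes.append(f"fold {i}: no events; zero model")
                    continue
                sel, w, offset, _, note = _fit_arrays(
                    self._X[mask], time[mask], event[mask], self.alpha
                )
                if note is not None and collect:
                    notes.append(f"fold {i}: {note}")
                if sel.size == 0:
                    continue  # score 0 vs training median 0: tie -> low
                train_scores = self._X[mask][:, sel] @ w - offset
                held = self._X[i, sel] @ w - offset
                group_high[i] = held > np.median(train_scores)
            stat = logrank_2group(time, event, group_high)
            return stat, group_high, notes

        stat_obs, groups_obs, notes = cv_stat(self._time, self._event, collect=True)
        from scipy import stats as sps

        p_chi2 = float(sps.chi2.sf(stat_obs, df=1)) if stat_obs > 0 else 1.0

        perm_p = None
        if n_permutations > 0:
            rng = np.random.default_rng(seed)
            count = 0
            for _ in range(n_permutations):
                perm = rng.permutation(n)
                stat_b, _, _ = cv_stat(self._time[perm], self._event[perm])
                if stat_b >= stat_obs - 1e-12:
                    count += 1
            perm_p = (1 + count) / (1 + n_permutations)

        groups = pd.Series(
            np.where(groups_obs, "high", "low"), index=self.surv.index, name="cv_risk_group"
        )
        return LoocvResult(
            groups=groups,
            statistic=float(stat_obs),
            p_chi2=p_chi2,
            permutation_p=perm_p,
            n_permutations=n_permutations,
            fold_notes=notes,
        )


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def select_features(normalized_expr: pd.DataFrame, surv: pd.DataFrame, alpha: float = 0.001):
    return ExhaustionScoreModel(normalized_expr, surv, alpha=alpha).select_features()


def fit_score_model(normalized_expr: pd.DataFrame, surv: pd.DataFrame, alpha: float = 0.001):
    return ExhaustionScoreModel(normalized_expr, surv, alpha=alpha).fit()


def apply_score(model: ExhaustionScoreResults, normalized_expr: pd.DataFrame) -> pd.DataFrame:
    return model.predict(normalized_expr)


def loocv_validate(
    normalized_expr: pd.DataFrame,
    surv: pd.DataFrame,
    alpha: float = 0.001,
    n_permutations: int = 0,
    seed: int | None = None,
) -> LoocvResult:
    return ExhaustionScoreModel(normalized_expr, surv, alpha=alpha).loocv(
        n_permutations=n_permutations, seed=seed
    )


def cytolytic_score(expr: pd.DataFrame, log_scale: bool = True) -> pd.Series:
    """CYT: per-sample geometric mean of GZMA and PRF1 on the linear scale.

    ``expr`` is genes x samples. With ``log_scale=True`` (default) values are
    taken as log2 intensities and exponentiated first; linear input must be
    strictly positive.
    """
    missing = [g for g in CYTOLYTIC_GENES if g not in expr.index]
    if missing:
        raise MissingGeneError(f"cytolytic effector genes missing: {missing}")
    sub = expr.loc[list(CYTOLYTIC_GENES)].astype(float)
    lin = np.power(2.0, sub) if log_scale else sub
    if (lin <= 0).any().any():
        raise InputError("cytolytic_score requires strictly positive linear-scale values")
    cyt = np.sqrt(lin.iloc[0] * lin.iloc[1])
    cyt.name = "CYT"
    return cyt
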