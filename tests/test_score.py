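import warnings

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from methex import (
    CohortConfig,
    ExhaustionScoreModel,
    ExhaustionScoreResults,
    InputError,
    MissingGeneError,
    apply_score,
    cytolytic_score,
    fit_score_model,
    generate_bulk_cohort,
    loocv_validate,
    select_features,
)
from methex._cox import logrank_2group, univariate_cox_batch
from methex.genes import PUBLISHED_FEATURES, PUBLISHED_OFFSET


def _cohort_frames(n=200, seed=0, n_genes=6, log_hr=1.5):
    """Genes x samples matrix with gene 0 driving the hazard."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_genes, n))
    hazard = 0.2 * np.exp(log_hr * X[0])
    t = rng.exponential(1 / hazard)
    cut = np.quantile(t, 0.8)
    samples = [f"S{i}" for i in range(n)]
    expr = pd.DataFrame(X, index=[f"G{i}" for i in range(n_genes)], columns=samples)
    surv = pd.DataFrame({"time": np.minimum(t, cut), "event": (t <= cut).astype(int)},
                        index=samples)
    return expr, surv


class TestUnivariateCoxSolver:
    """The in-package vectorised Cox screen against lifelines as the oracle."""

    def test_matches_lifelines_beta_and_p(self):
        expr, surv = _cohort_frames(n=120, seed=3, n_genes=4)
        beta, se, p = univariate_cox_batch(expr.T.to_numpy(), surv["time"].to_numpy(),
                                           surv["event"].to_numpy())
        for j, g in enumerate(expr.index):
            df = pd.DataFrame({"time": surv["time"], "event": surv["event"],
                               "x": expr.loc[g]})
            cph = CoxPHFitter().fit(df, "time", "event")
            assert beta[j] == pytest.approx(cph.params_["x"], abs=1e-4)
            assert se[j] == pytest.approx(cph.standard_errors_["x"], rel=1e-3)

    def test_degenerate_covariate_is_null(self):
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.array([1, 1, 0, 1])
        beta, se, p = univariate_cox_batch(np.ones((4, 1)), time, event)
        assert beta[0] == 0.0 and p[0] == 1.0


class TestSelectFeatures:
    def test_strong_planted_gene_selected(self):
        expr, surv = _cohort_frames()
        genes, stats = select_features(expr, surv, alpha=0.001)
        assert "G0" in genes
        assert stats.loc["G0", "p"] < 1e-6

    def test_alpha_one_returns_all_genes(self):
        expr, surv = _cohort_frames(n_genes=5)
        genes, _ = select_features(expr, surv, alpha=1.0)
        assert sorted(genes) == sorted(expr.index)

    def test_null_gene_rarely_selected(self):
        """A survival-independent gene passes alpha=0.001 in <=1% of null
        replicates (Wald test calibration)."""
        rng = np.random.default_rng(8)
        hits = 0
        reps = 400
        for _ in range(reps):
            n = 60
            x = rng.standard_normal((n, 1))
            t = rng.exponential(5, n)
            e = np.ones(n, dtype=int)
            _, _, p = univariate_cox_batch(x, t, e)
            hits += p[0] < 0.001
        assert hits / reps <= 0.01

    def test_ordering_by_p_ascending(self):
        expr, surv = _cohort_frames()
        genes, stats = select_features(expr, surv, alpha=1.0)
        assert list(stats["p"]) == sorted(stats["p"])


class TestFitScoreModel:
    def test_single_feature_weight_is_univariate_cox_over_sd(self):
        expr, surv = _cohort_frames(n_genes=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_score_model(expr, surv, alpha=1.0)
        x = expr.loc["G0"].to_numpy()
        z = (x - x.mean()) / x.std()
        beta_std = univariate_cox_batch(z[:, None], surv["time"].to_numpy(),
                                        surv["event"].to_numpy())[0][0]
        assert model.weights["G0"] == pytest.approx(beta_std / x.std(), rel=1e-6)

    def test_training_mean_score_is_zero(self):
        expr, surv = _cohort_frames(n_genes=6)
        model = fit_score_model(expr, surv, alpha=1.0)
        assert apply_score(model, expr)["ES"].mean() == pytest.approx(0.0, abs=1e-9)

    def test_redundant_informative_features_share_hazard_sign(self):
        rng = np.random.default_rng(77)
        n = 500
        latent = rng.standard_normal(n)
        X = np.vstack([latent + 0.3 * rng.standard_normal(n),
                       latent + 0.3 * rng.standard_normal(n)])
        hazard = 0.2 * np.exp(1.0 * latent)
        t = rng.exponential(1 / hazard)
        samples = [f"S{i}" for i in range(n)]
        expr = pd.DataFrame(X, index=["A", "B"], columns=samples)
        surv = pd.DataFrame({"time": t, "event": 1}, index=samples)
        model = fit_score_model(expr, surv, alpha=0.001)
        assert set(model.features) == {"A", "B"}
        assert (model.weights > 0).all()  # higher expression -> higher hazard

    def test_hazard_reversal_flips_weight_signs(self):
        expr, surv = _cohort_frames(n_genes=3)
        model = fit_score_model(expr, surv, alpha=1.0)
        rev = surv.copy()
        rev["time"] = surv["time"].max() + surv["time"].min() - surv["time"]
        rev["event"] = 1  # rank-reversed, fully observed
        fwd = fit_score_model(expr, pd.DataFrame({"time": surv["time"], "event": 1},
                                                 index=surv.index), alpha=1.0)
        back = fit_score_model(expr, rev, alpha=1.0)
        common = fwd.weights.index.intersection(back.weights.index)
        assert (np.sign(fwd.weights[common]) == -np.sign(back.weights[common])).all()


class TestApplyScore:
    def test_published_offset_worked_example(self):
        """Four zero-valued features under the published offset score -12.77237."""
        model = ExhaustionScoreResults.from_weights(
            PUBLISHED_FEATURES, [0.3, -0.2, 0.1, 0.4], offset=PUBLISHED_OFFSET
        )
        expr = pd.DataFrame(0.0, index=list(PUBLISHED_FEATURES), columns=["S1"])
        assert apply_score(model, expr)["ES"].iloc[0] == pytest.approx(-12.77237, abs=1e-12)

    def test_zero_weights_give_negative_offset_everywhere(self):
        model = ExhaustionScoreResults.from_weights(["A"], [0.0], offset=2.5)
        expr = pd.DataFrame([[1.0, 7.0, -3.0]], index=["A"], columns=["S1", "S2", "S3"])
        assert (apply_score(model, expr)["ES"] == -2.5).all()

    def test_bilinearity_doubling_weights_and_values(self):
        model = ExhaustionScoreResults.from_weights(["A", "B"], [0.5, -1.0], offset=3.0)
        expr = pd.DataFrame([[1.0, 2.0], [3.0, -1.0]], index=["A", "B"],
                            columns=["S1", "S2"])
        base = apply_score(model, expr)["ES"] + 3.0
        doubled = ExhaustionScoreResults.from_weights(["A", "B"], [1.0, -2.0], offset=3.0)
        quad = apply_score(doubled, 2 * expr)["ES"] + 3.0
        pd.testing.assert_series_equal(quad, 4 * base)

    def test_sample_permutation_permutes_scores(self):
        model = ExhaustionScoreResults.from_weights(["A", "B"], [1.0, 2.0], offset=0.0)
        expr = pd.DataFrame(np.arange(6.0).reshape(2, 3), index=["A", "B"],
                            columns=["S1", "S2", "S3"])
        direct = apply_score(model, expr)["ES"]
        permuted = apply_score(model, expr[["S3", "S1", "S2"]])["ES"]
        pd.testing.assert_series_equal(direct.loc[permuted.index], permuted)

    def test_pkm_alias_resolves_before_error(self):
        model = ExhaustionScoreResults.from_weights(["PKM2"], [1.0], offset=0.0)
        expr = pd.DataFrame([[2.0]], index=["PKM"], columns=["S1"])
        assert apply_score(model, expr)["ES"].iloc[0] == 2.0
        with pytest.raises(MissingGeneError, match="PKM2"):
            apply_score(model, pd.DataFrame([[1.0]], index=["XYZ"], columns=["S1"]))


class TestLoocv:
    def test_strong_signature_detected(self):
        expr, surv = _cohort_frames(n=60, seed=5, log_hr=2.0)
        res = loocv_validate(expr, surv, alpha=0.05, n_permutations=0)
        assert res.permutation_p is None  # not computed
        assert set(res.groups.unique()) <= {"high", "low"}
        assert res.statistic > 3.84  # chi2(1) at 0.05

    def test_permutation_p_small_for_planted_effect(self):
        expr, surv = _cohort_frames(n=50, seed=6, log_hr=2.0)
        res = loocv_validate(expr, surv, alpha=0.05, n_permutations=19, seed=1)
        assert res.permutation_p == pytest.approx(1 / 20)

    def test_small_n_rejected(self):
        expr, surv = _cohort_frames(n=10)
        with pytest.raises(InputError, match="n >= 20"):
            loocv_validate(expr, surv)


class TestCytolyticScore:
    def test_geometric_mean_arithmetic(self):
        expr = pd.DataFrame([[4.0], [9.0]], index=["GZMA", "PRF1"], columns=["S1"])
        assert cytolytic_score(expr, log_scale=False).iloc[0] == 6.0

    def test_identity_when_equal(self):
        expr = pd.DataFrame([[7.0], [7.0]], index=["GZMA", "PRF1"], columns=["S1"])
        assert cytolytic_score(expr, log_scale=False).iloc[0] == 7.0

    def test_matches_exp_mean_log_oracle(self, rng):
        expr = pd.DataFrame(rng.normal(6, 1, (2, 20)), index=["GZMA", "PRF1"],
                            columns=[f"S{i}" for i in range(20)])
        cyt = cytolytic_score(expr)  # log2 input
        lin = np.power(2.0, expr)
        oracle = np.exp(np.log(lin).mean(axis=0))
        np.testing.assert_allclose(cyt, oracle, rtol=1e-12)

    def test_nonpositive_linear_rejected(self):
        expr = pd.DataFrame([[0.0], [1.0]], index=["GZMA", "PRF1"], columns=["S1"])
        with pytest.raises(InputError, match="positive"):
            cytolytic_score(expr, log_scale=False)


class TestLogrankInternal:
    def test_identical_groups_statistic_zero(self):
        time = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        event = np.array([1, 1, 0, 1, 1, 0])
        grp = np.array([True, True, True, False, False, False])
        assert logrank_2group(time, event, grp) == pytest.approx(0.0, abs=1e-12)


class TestModelObject:
    def test_fit_on_synthetic_cohort_recovers_exhaustion(self):
        from methex import cd3_normalize

        b = generate_bulk_cohort(CohortConfig(n_samples=200, seed=9, n_null_metabolites=5))
        norm = cd3_normalize(b.bulk_expression, b.signature_genes)
        res = ExhaustionScoreModel(norm.loc[b.signature_genes], b.clinical).fit()
        es = res.predict(norm)["ES"]
        from scipy.stats import spearmanr

        assert spearmanr(es, b.truth.latent_exhaustion).statistic > 0.5

    def test_json_round_trip(self, tmp_path):
        res = ExhaustionScoreResults.from_weights(["A", "B"], [0.1, -0.2], offset=1.5)
        res.to_json(tmp_path / "m.json")
        back = ExhaustionScoreResults.from_json(tmp_path / "m.json")
        assert back.features == ["A", "B"]
        assert back.offset == 1.5
        pd.testing.assert_series_equal(back.weights, res.weights)
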