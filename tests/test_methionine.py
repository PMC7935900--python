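import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from methex import (
    CohortConfig,
    InputError,
    bulk_pathway_scores,
    classify_cells,
    generate_single_cell,
    geneset_group_compare,
    sc_pathway_difference,
    tumor_dominance,
)
from methex.genes import DENOVO_GENES, METHIONINE_GENES, SALVAGE_GENES


def _bulk(values_by_gene, samples=("S1",)):
    return pd.DataFrame(values_by_gene, index=list(samples)).T


class TestBulkPathwayScores:
    def test_all_ones_gives_6_5_ratio(self):
        expr = _bulk({g: [1.0] for g in METHIONINE_GENES})
        out = bulk_pathway_scores(expr)
        assert out.loc["S1", "salvage"] == 6.0
        assert out.loc["S1", "denovo"] == 5.0
        assert out.loc["S1", "ratio"] == pytest.approx(1.2)

    def test_zero_denovo_flagged_undefined(self):
        vals = {g: [1.0] for g in SALVAGE_GENES}
        vals.update({g: [0.0] for g in DENOVO_GENES})
        with pytest.warns(UserWarning, match="undefined"):
            out = bulk_pathway_scores(_bulk(vals))
        assert np.isnan(out.loc["S1", "ratio"]) and not out.loc["S1", "ratio_defined"]

    def test_matches_per_gene_loop_oracle(self, rng):
        expr = pd.DataFrame(rng.normal(5, 2, (11, 9)), index=list(METHIONINE_GENES),
                            columns=[f"S{i}" for i in range(9)])
        out = bulk_pathway_scores(expr)
        for s in expr.columns:
            salv = sum(expr.loc[g, s] for g in SALVAGE_GENES)
            deno = sum(expr.loc[g, s] for g in DENOVO_GENES)
            assert out.loc[s, "salvage"] == pytest.approx(salv, abs=1e-12)
            assert out.loc[s, "ratio"] == pytest.approx(salv / deno, abs=1e-12)

    def test_whole_pathway_missing_is_error(self):
        expr = _bulk({g: [1.0] for g in SALVAGE_GENES})
        with pytest.raises(InputError, match="de novo"):
            bulk_pathway_scores(expr)

    def test_monotone_in_pathway_genes(self):
        expr = pd.DataFrame(1.0, index=list(METHIONINE_GENES), columns=["S1"])
        base = bulk_pathway_scores(expr).loc["S1"]
        up = expr.copy()
        up.loc["AMD1"] += 1.0  # salvage gene up
        assert bulk_pathway_scores(up).loc["S1", "ratio"] > base["ratio"]
        dn = expr.copy()
        dn.loc["GNMT"] += 1.0  # de novo gene up
        assert bulk_pathway_scores(dn).loc["S1", "ratio"] < base["ratio"]


def _sc_from_matrix(X, cell_types, tumors, genes):
    obs = pd.DataFrame({"cell_type": cell_types, "tumor": tumors},
                       index=[f"c{i}" for i in range(len(cell_types))])
    return ad.AnnData(X=sparse.csr_matrix(np.asarray(X, dtype=float)), obs=obs,
                      var=pd.DataFrame(index=genes))


class TestScPathwayDifference:
    def test_salvage_two_denovo_zero_gives_twelve(self):
        X = np.zeros((1, 11))
        X[0, :6] = 2.0  # the six salvage genes
        sc = _sc_from_matrix(X, ["malignant"], ["T1"], list(METHIONINE_GENES))
        out = sc_pathway_difference(sc)
        assert out["difference"].iloc[0] == 12.0

    def test_balanced_sums_give_zero(self):
        X = np.zeros((1, 11))
        X[0, :6] = 5.0
        X[0, 6:] = 6.0  # 6*5 == 5*6
        sc = _sc_from_matrix(X, ["malignant"], ["T1"], list(METHIONINE_GENES))
        assert sc_pathway_difference(sc)["difference"].iloc[0] == 0.0

    def test_matches_loop_oracle(self, rng):
        X = rng.normal(2, 1, (8, 11))
        sc = _sc_from_matrix(X, ["malignant"] * 8, ["T1"] * 8, list(METHIONINE_GENES))
        out = sc_pathway_difference(sc)
        for i in range(8):
            expected = X[i, :6].sum() - X[i, 6:].sum()
            assert out["difference"].iloc[i] == pytest.approx(expected, abs=1e-6)

    def test_no_malignant_cells_is_error(self):
        sc = _sc_from_matrix(np.zeros((2, 11)), ["T", "T"], ["T1", "T1"],
                             list(METHIONINE_GENES))
        with pytest.raises(InputError, match="malignant"):
            sc_pathway_difference(sc)


class TestClassifyCells:
    def test_mean_threshold_examples(self):
        scores = pd.DataFrame({"difference": [1.0, 3.0]}, index=["a", "b"])
        labels = classify_cells(scores)
        assert list(labels) == ["de novo-high", "salvage-high"]

    def test_all_equal_none_above_mean(self):
        scores = pd.DataFrame({"difference": [2.0, 2.0, 2.0]}, index=list("abc"))
        assert (classify_cells(scores) == "de novo-high").all()

    def test_order_invariant_partition(self, rng):
        scores = pd.DataFrame({"difference": rng.normal(size=20)},
                              index=[f"c{i}" for i in range(20)])
        labels = classify_cells(scores)
        shuffled = classify_cells(scores.sample(frac=1, random_state=1))
        assert (labels.loc[shuffled.index] == shuffled).all()
        assert labels.isin(["salvage-high", "de novo-high"]).all()

    def test_two_program_simulation_accuracy(self):
        sc = generate_single_cell(
            CohortConfig(seed=13, noise_sd=1.0),  # program shift defaults to 2*noise_sd
            n_tumors=2, cells_per_tumor=100,
            salvage_fraction_per_tumor=(0.7, 0.3), t_cells_per_tumor=5,
        )
        labels = classify_cells(sc_pathway_difference(sc))
        truth = sc.obs.loc[labels.index, "true_program"]
        assert (labels == truth).mean() >= 0.95


class TestTumorDominance:
    def test_fraction_rule(self):
        labels = pd.Series(
            ["salvage-high"] * 9 + ["de novo-high"] * 1
            + ["salvage-high"] * 6 + ["de novo-high"] * 4
            + ["salvage-high"] * 2 + ["de novo-high"] * 8,
            index=[f"c{i}" for i in range(30)],
        )
        tumors = pd.Series(["A"] * 10 + ["B"] * 10 + ["C"] * 10, index=labels.index)
        comp = tumor_dominance(labels, tumors)
        assert comp.loc["A", "dominance"] == "salvage-dominant"
        assert comp.loc["B", "dominance"] == "salvage-dominant"
        assert comp.loc["C", "dominance"] == "de novo-dominant"
        assert (comp["n_salvage_high"] + comp["n_denovo_high"] == 10).all()

    def test_exact_half_is_denovo_dominant(self):
        labels = pd.Series(["salvage-high", "de novo-high"], index=["a", "b"])
        comp = tumor_dominance(labels, pd.Series(["T", "T"], index=["a", "b"]))
        assert comp.loc["T", "dominance"] == "de novo-dominant"

    def test_planted_fractions_recovered(self):
        sc = generate_single_cell(CohortConfig(seed=4), n_tumors=4, cells_per_tumor=80,
                                  salvage_fraction_per_tumor=(0.9, 0.6, 0.2, 0.8),
                                  t_cells_per_tumor=5)
        diffs = sc_pathway_difference(sc)
        comp = tumor_dominance(classify_cells(diffs), diffs["tumor"])
        expected = ["salvage-dominant", "salvage-dominant", "de novo-dominant",
                    "salvage-dominant"]
        assert list(comp.loc[["T1", "T2", "T3", "T4"], "dominance"]) == expected


class TestGenesetGroupCompare:
    def _toy(self, shift):
        genes = ["E1", "E2"]
        X = np.ones((12, 2))
        X[:6] += shift  # cells of the salvage-dominant tumor
        sc = _sc_from_matrix(X, ["T"] * 12, ["A"] * 6 + ["B"] * 6, genes)
        dom = pd.DataFrame({"dominance": ["salvage-dominant", "de novo-dominant"]},
                           index=pd.Index(["A", "B"], name="tumor"))
        return sc, dom

    def test_identical_groups_t_zero_p_one(self):
        sc, dom = self._toy(shift=0.0)
        res = geneset_group_compare(sc, ["E1", "E2"], dom)
        assert res["t"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)

    def test_student_t_matches_closed_form_3v3(self):
        genes = ["G"]
        X = np.array([[1.0], [2.0], [3.0], [2.0], [4.0], [6.0]])
        sc = _sc_from_matrix(X, ["T"] * 6, ["A"] * 3 + ["B"] * 3, genes)
        dom = pd.DataFrame({"dominance": ["salvage-dominant", "de novo-dominant"]},
                           index=pd.Index(["A", "B"], name="tumor"))
        res = geneset_group_compare(sc, ["G"], dom)
        a, b = np.array([1.0, 2.0, 3.0]), np.array([2.0, 4.0, 6.0])
        sp = np.sqrt(((a.var(ddof=1) + b.var(ddof=1)) / 2) * (2 / 3))
        t_hand = (a.mean() - b.mean()) / sp
        assert res["t"] == pytest.approx(t_hand, abs=1e-12)

    def test_case_insensitive_symbol_matching(self):
        """DNMT3a/DNMT3b style lower-case suffixes match upper-case entries."""
        sc, dom = self._toy(shift=1.0)
        sc.var_names = ["DNMT3A", "DNMT3B"]
        res = geneset_group_compare(sc, ["DNMT3a", "DNMT3b"], dom)
        assert res["genes_used"] == ["DNMT3A", "DNMT3B"]

    def test_empty_gene_set_after_matching_is_error(self):
        sc, dom = self._toy(shift=0.0)
        with pytest.raises(InputError, match="no gene"):
            geneset_group_compare(sc, ["NOPE"], dom)
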