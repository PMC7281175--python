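import math

import numpy as np
import pytest
from scipy.stats import t as t_dist

from triotrace import DemCriteria, call_dem, fold_change_report, pairwise_compare
from triotrace.differential import PairwiseResult
from triotrace.liver_study import GENES, METABOLITES, metabolite_mean_table

from conftest import make_table


class TestPairwiseCompare:
    def test_identical_groups(self):
        table = make_table([[1.0] * 6], ["W"] * 3 + ["P"] * 3)
        (r,) = pairwise_compare(table, "W", "P")
        assert r.fold_change == 1.0
        assert r.relation == "="

    def test_hand_computed_student_t(self):
        # pooled-variance t computed from first principles as the oracle
        w, p = [10.0, 12.0, 11.0, 9.0], [5.0, 6.0, 5.0, 6.0]
        sp2 = (np.var(w, ddof=1) * 3 + np.var(p, ddof=1) * 3) / 6
        t_stat = (np.mean(w) - np.mean(p)) / math.sqrt(sp2 * (1 / 4 + 1 / 4))
        p_expected = 2 * t_dist.sf(abs(t_stat), df=6)
        table = make_table([w + p], ["W"] * 4 + ["P"] * 4)
        (r,) = pairwise_compare(table, "W", "P", test="student")
        assert r.fold_change == pytest.approx(10.5 / 5.5)
        assert r.p_value == pytest.approx(p_expected, rel=1e-12)
        assert r.relation == ">"

    def test_equal_means_not_significant_under_both_tests(self):
        rng = np.random.default_rng(0)
        a = 5.0 + rng.normal(0, 0.01, 6)
        b = 5.0 + rng.normal(0, 2.0, 6)
        b = b - b.mean() + a.mean()  # force exactly equal means
        b = np.abs(b)
        table = make_table([np.concatenate([a, b])], ["W"] * 6 + ["P"] * 6)
        for test in ("student", "welch"):
            (r,) = pairwise_compare(table, "W", "P", test=test)
            assert r.relation in ("=",) or r.p_value > 0.4

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_fold_antisymmetry_and_relation_mirror(self, seed):
        rng = np.random.default_rng(seed)
        table = make_table(rng.lognormal(0, 0.5, (30, 8)), ["W"] * 4 + ["P"] * 4)
        ab = pairwise_compare(table, "W", "P")
        ba = pairwise_compare(table, "P", "W")
        mirror = {">": "<", "<": ">", "=": "="}
        for r1, r2 in zip(ab, ba):
            assert r1.fold_change * r2.fold_change == pytest.approx(1.0, abs=1e-12)
            assert r1.relation == mirror[r2.relation]

    def test_student_welch_agree_under_equal_variance(self):
        # 1000 equal-variance analytes at n=8: relations agree >= 99%
        rng = np.random.default_rng(42)
        data = rng.lognormal(0, 0.2, (1000, 16))
        table = make_table(data, ["W"] * 8 + ["P"] * 8)
        student = pairwise_compare(table, "W", "P", test="student")
        welch = pairwise_compare(table, "W", "P", test="welch")
        agree = sum(s.relation == w.relation for s, w in zip(student, welch))
        assert agree >= 990

    def test_small_group_rejected(self):
        table = make_table([[1.0, 2.0, 3.0]], ["W", "P", "P"])
        with pytest.raises(Exception):
            pairwise_compare(table, "W", "P")


class TestCallDem:
    def _result(self, fold, p):
        return PairwiseResult(
            analyte_id="x", group_a="W", group_b="P",
            mean_a=fold, mean_b=1.0, fold_change=fold, p_value=p,
            relation=">" if p < 0.05 and fold > 1 else ("<" if p < 0.05 else "="),
        )

    def test_gene_mode_needs_fold_window(self):
        r = self._result(1.2, 0.001)
        assert call_dem([r], mode="gene") == []
        assert call_dem([r], mode="metabolite") == [r]

    def test_published_gene_example_included(self):
        # Abat W vs P: fold 1.72, p 2.31e-3 passes the gene criterion
        row = GENES.loc["Abat"]
        r = self._result(row["fold_W_vs_P"], row["p_W_vs_P"])
        assert call_dem([r], mode="gene") == [r]

    def test_alpha_boundary_is_strict(self):
        assert call_dem([self._result(3.0, 0.0501)], mode="metabolite") == []
        assert call_dem([self._result(3.0, 0.05)], mode="metabolite") == []
        assert call_dem([self._result(3.0, 0.0499)], mode="metabolite") != []

    def test_metabolite_mode_superset_of_gene_mode(self):
        rng = np.random.default_rng(9)
        results = [
            self._result(float(f), float(p))
            for f, p in zip(rng.lognormal(0, 0.7, 100), rng.uniform(0, 0.2, 100))
        ]
        gene = {id(r) for r in call_dem(results, mode="gene")}
        metab = {id(r) for r in call_dem(results, mode="metabolite")}
        assert gene <= metab


class TestFoldChangeReport:
    def test_published_group_means_reproduce_folds(self):
        report = fold_change_report(metabolite_mean_table())
        row = report.loc["Glucose-1p"]
        assert (row["fold_W_vs_P_2dp"], row["fold_P_vs_T_2dp"], row["fold_W_vs_T_2dp"]) == (
            0.74, 0.69, 0.51,
        )
        assert report.loc["Xanthosine", "fold_W_vs_T_2dp"] == 3.81
        assert report.loc["Malate", "fold_P_vs_T_2dp"] == 0.53

    def test_identical_means_give_unit_folds(self):
        table = make_table([[2.5] * 6], ["W", "W", "P", "P", "T", "T"])
        report = fold_change_report(table)
        assert report.iloc[0][["fold_W_vs_P_2dp", "fold_P_vs_T_2dp", "fold_W_vs_T_2dp"]].tolist() == [1.0, 1.0, 1.0]

    def test_criteria_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            DemCriteria(alpha=1.5)
        with pytest.raises(ValueError):
            DemCriteria(fc_low=1.2)
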