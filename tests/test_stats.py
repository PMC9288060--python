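"""Cohort statistics: normalization, differential calling, correlates,
Cox survival, panel selection, stratification."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from lctseq import stats as S
from lctseq.simulate import simulate_cohort, simulate_survival

from .oracles import cox_grid_beta, fisher_two_sided, stratify_brute_force


@pytest.fixture(scope="module")
def cohort():
    return simulate_cohort(seed=77)


class TestNormalize:
    def test_closed_form(self):
        counts = pd.DataFrame({"s1": [5, 0]}, index=["e1", "e2"])
        depth = pd.Series({"s1": 1_000_000})
        norm = S.normalize_log_rpm(counts, depth)
        assert norm.loc["e1", "s1"] == pytest.approx(np.log2(6))
        assert norm.loc["e2", "s1"] == 0.0

    def test_depth_doubling_halves_rpm(self):
        counts = pd.DataFrame({"a": [8], "b": [8]}, index=["e"])
        depth = pd.Series({"a": 1e6, "b": 2e6})
        norm = S.normalize_log_rpm(counts, depth, pseudocount=0)
        assert 2 ** norm.loc["e", "a"] == pytest.approx(2 * 2 ** norm.loc["e", "b"])

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError, match="depth"):
            S.normalize_log_rpm(pd.DataFrame({"s": [1]}), pd.Series({"s": 0}))


class TestDiffExpression:
    def _groups(self, nt=4, nn=4):
        cols = [f"t{i}" for i in range(nt)] + [f"n{i}" for i in range(nn)]
        return cols, pd.Series(["tumor"] * nt + ["normal"] * nn, index=cols)

    def test_identical_means_not_called(self):
        cols, g = self._groups()
        df = pd.DataFrame([[3.0] * 8], columns=cols, index=["e"])
        res = S.diff_expression_test(df, g)
        assert res.loc["e", "log2_fc"] == 0 and not res.loc["e", "called_expression"]

    def test_separated_groups_called_with_welch_statistic(self):
        cols, g = self._groups()
        vals = [5.0, 5.1, 4.9, 5.0, 1.0, 1.1, 0.9, 1.0]
        df = pd.DataFrame([vals], columns=cols, index=["e"])
        res = S.diff_expression_test(df, g)
        # Welch t oracle computed directly from the definition
        a, b = np.array(vals[:4]), np.array(vals[4:])
        se = np.sqrt(a.var(ddof=1) / 4 + b.var(ddof=1) / 4)
        t = (a.mean() - b.mean()) / se
        assert res.loc["e", "log2_fc"] == pytest.approx(4.0)
        assert res.loc["e", "called_expression"]
        assert t > 10  # far beyond any 0.05 critical value

    def test_downregulated_event_filtered_by_direction(self):
        cols, g = self._groups()
        vals = [1.0, 1.1, 0.9, 1.0, 5.0, 5.1, 4.9, 5.0]
        res = S.diff_expression_test(pd.DataFrame([vals], columns=cols, index=["e"]), g)
        assert res.loc["e", "p_expression"] < 0.05
        assert not res.loc["e", "called_expression"]


class TestFisher:
    @pytest.mark.parametrize("table", [
        (10, 10, 0, 20), (1, 1, 1, 1), (5, 5, 5, 5), (3, 17, 12, 8),
        (0, 12, 7, 5), (15, 0, 2, 13), (8, 22, 1, 29),
    ])
    def test_matches_hypergeometric_enumeration(self, table):
        a, b, c, d = table
        from scipy.stats import fisher_exact

        p_scipy = fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
        assert p_scipy == pytest.approx(fisher_two_sided(a, b, c, d), abs=1e-12)

    def test_equal_proportions_give_p_one(self):
        cols = [f"t{i}" for i in range(4)] + [f"n{i}" for i in range(4)]
        g = pd.Series(["tumor"] * 4 + ["normal"] * 4, index=cols)
        pres = pd.DataFrame([[1, 1, 0, 0, 1, 1, 0, 0]], columns=cols, index=["e"]).astype(bool)
        res = S.diff_occurrence_fisher(pres, g)
        assert res.loc["e", "p_fisher"] == pytest.approx(1.0)

    def test_empty_group_is_an_error(self):
        cols = ["t0", "t1"]
        g = pd.Series(["tumor", "tumor"], index=cols)
        with pytest.raises(ValueError):
            S.diff_occurrence_fisher(pd.DataFrame([[1, 0]], columns=cols), g)


class TestUnion:
    def _tables(self):
        idx = ["e1", "e2", "e3", "e4"]
        expr = pd.DataFrame(
            {"p_expression": [0.01, 0.5, 0.01, 0.9], "log2_fc": [1, 1, 1, 0],
             "called_expression": [True, False, True, False]}, index=idx)
        fish = pd.DataFrame(
            {"p_fisher": [0.5, 0.01, 0.01, 0.9],
             "called_fisher": [False, True, True, False]}, index=idx)
        return expr, fish

    def test_union_is_or_of_strategies(self):
        expr, fish = self._tables()
        res = S.union_differential(expr, fish)
        assert res["called_union"].tolist() == [True, True, True, False]

    def test_mismatched_event_sets_rejected(self):
        expr, fish = self._tables()
        with pytest.raises(ValueError):
            S.union_differential(expr, fish.iloc[:2])


class TestActivityAndCorrelates:
    def test_activity_closed_form_and_permutation_invariance(self):
        counts = pd.DataFrame({"s": [3, 2]}, index=["e1", "e2"])
        act = S.sample_activity(counts, pd.Series({"s": 1e6}))
        assert act["s"] == pytest.approx(5.0)
        shuffled = counts.iloc[::-1]
        assert S.sample_activity(shuffled, pd.Series({"s": 1e6}))["s"] == act["s"]

    def test_all_zero_sample_has_zero_activity(self):
        counts = pd.DataFrame({"s": [0, 0]}, index=["e1", "e2"])
        assert S.sample_activity(counts, pd.Series({"s": 1e6}))["s"] == 0

    def test_m_value_closed_form(self):
        assert S.methylation_m(0.5) == 0
        assert S.methylation_m(0.8) == pytest.approx(2.0)

    def test_cnv_burden_sums_absolute_values(self):
        g = pd.DataFrame({"s": [1.0, -2.0]}, index=["g1", "g2"])
        assert S.cnv_burden(g)["s"] == pytest.approx(3.0)

    def test_proportional_feature_has_r_one(self):
        rng = np.random.default_rng(0)
        act = pd.Series(rng.uniform(1, 5, 10), index=[f"s{i}" for i in range(10)])
        feats = pd.DataFrame([act * 3.0], index=["g"])
        res = S.correlate_activity(act, feats)
        assert res.loc["g", "r"] == pytest.approx(1.0)
        assert res.loc["g", "selected"] and res.loc["g", "direction"] == "positive"

    def test_constant_feature_skipped(self):
        act = pd.Series([1.0, 2, 3, 4], index=list("abcd"))
        feats = pd.DataFrame([[5.0, 5, 5, 5]], columns=list("abcd"), index=["g"])
        res = S.correlate_activity(act, feats)
        assert np.isnan(res.loc["g", "r"]) and not res.loc["g", "selected"]


class TestCox:
    def test_toy_fit_matches_grid_search_oracle(self):
        x = [0.5, -1.2, 1.4, 2.0, -0.7, 0.3]
        time = [5.0, 12.0, 8.0, 2.0, 20.0, 4.0]
        status = [1, 0, 1, 1, 0, 1]
        fit = S.fit_univariate_cox(x, time, status)
        assert fit["beta"] == pytest.approx(cox_grid_beta(x, time, status), abs=1e-4)

    def test_permuted_covariate_gives_null_beta(self):
        df = simulate_survival(n=150, beta=0.8, seed=5)
        rng = np.random.default_rng(6)
        fit = S.fit_univariate_cox(rng.permutation(df.x), df.time, df.status)
        assert abs(fit["beta"]) < 0.25
        assert fit["p"] > 0.01

    def test_covariate_rescaling_rescales_beta(self):
        df = simulate_survival(n=120, beta=0.6, seed=7)
        f1 = S.fit_univariate_cox(df.x, df.time, df.status)
        f2 = S.fit_univariate_cox(2 * df.x, df.time, df.status)
        assert f2["beta"] == pytest.approx(f1["beta"] / 2, rel=1e-6)

    def test_agrees_with_lifelines_on_tie_free_data(self):
        from lifelines import CoxPHFitter

        df = simulate_survival(n=100, beta=0.5, seed=8)
        fit = S.fit_univariate_cox(df.x, df.time, df.status)
        cph = CoxPHFitter().fit(df[["x", "time", "status"]], "time", "status")
        assert fit["beta"] == pytest.approx(cph.params_["x"], abs=1e-6)

    @pytest.mark.parametrize("beta", [0.0, 0.5, 1.0])
    def test_recovers_true_log_hazard(self, beta):
        df = simulate_survival(n=200, beta=beta, seed=int(beta * 10) + 1)
        fit = S.fit_univariate_cox(df.x, df.time, df.status)
        assert abs(fit["beta"] - beta) < 0.1

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError):
            S.fit_univariate_cox([1, 1, 1], [1, 2, 3], [1, 1, 0])


class TestPanelSelection:
    def test_thresholds_and_strict_comparison_count(self):
        corr = pd.DataFrame(
            {"r": [0.3, 0.4, -0.5, 0.2], "p": [1e-5, 1e-5, 1e-6, 1e-3]},
            index=["g_in", "g_three", "g_neg", "g_weak"],
        )
        sc = pd.Series({"g_in": 4, "g_three": 3, "g_neg": 10, "g_weak": 10})
        assert S.select_panel_genes(corr, sc) == ["g_in"]


class TestStratification:
    def test_single_gene_z_scores(self):
        expr = pd.DataFrame([[1.0, 2.0, 3.0]], columns=list("abc"), index=["g"])
        score = S.aggregate_gene_score(expr)
        assert score.tolist() == pytest.approx([-1.0, 0.0, 1.0])

    def _toy(self):
        samples = [f"s{i}" for i in range(8)]
        rng = np.random.default_rng(11)
        expr = pd.DataFrame(rng.normal(size=(3, 8)), columns=samples,
                            index=["g1", "g2", "g3"])
        lct = pd.Series(rng.uniform(0, 4, 8), index=samples)
        # two constructed high/high deaths inside 36 months
        score = S.aggregate_gene_score(expr)
        order = np.argsort(-(score.to_numpy() + lct.to_numpy()))
        time = pd.Series(50.0, index=samples)
        status = pd.Series(0, index=samples)
        top = [samples[i] for i in order[:2]]
        time[top] = [10.0, 20.0]
        status[top] = 1
        return expr, lct, time, status

    def test_matches_exhaustive_oracle(self):
        expr, lct, time, status = self._toy()
        res = S.stratify_patients(expr, lct, time, status)
        score = S.aggregate_gene_score(expr)
        s_thr, l_thr, met = stratify_brute_force(
            score.tolist(), lct.tolist(), time.tolist(), status.tolist()
        )
        assert (res.score_threshold, res.lct_threshold) == (s_thr, l_thr)
        assert res.target_met is met
        assert res.group_rates[4] >= 0.5

    def test_all_survivors_cannot_meet_target(self):
        expr, lct, time, status = self._toy()
        status[:] = 0
        res = S.stratify_patients(expr, lct, time, status)
        assert not res.target_met

    def test_invariant_to_sample_order(self):
        expr, lct, time, status = self._toy()
        res1 = S.stratify_patients(expr, lct, time, status)
        perm = list(expr.columns[::-1])
        res2 = S.stratify_patients(expr[perm], lct[perm], time[perm], status[perm])
        assert res1.score_threshold == res2.score_threshold
        assert res1.lct_threshold == res2.lct_threshold
        assert res1.groups.sort_index().equals(res2.groups.sort_index())

    def test_groups_partition_samples(self):
        expr, lct, time, status = self._toy()
        res = S.stratify_patients(expr, lct, time, status)
        assert sum(res.group_counts.values()) == 8
        assert set(res.groups.unique()) <= {1, 2, 3, 4}


class TestCohortRecovery:
    def test_enriched_events_all_called_and_null_fp_controlled(self, cohort):
        counts, depth, pheno, truth = cohort
        norm = S.normalize_log_rpm(counts, depth)
        expr = S.diff_expression_test(norm, pheno["group"])
        fish = S.diff_occurrence_fisher(counts > 0, pheno["group"])
        uni = S.union_differential(expr, fish)
        enriched = set(truth["enriched_events"])
        assert enriched <= set(uni.index[uni.called_union])
        null = [e for e in uni.index if e not in enriched]
        fp = int(uni.loc[null, "called_fisher"].sum())
        # 95% binomial interval for Binomial(n_null, 0.05)
        from scipy.stats import binom

        lo, hi = binom.ppf([0.025, 0.975], len(null), 0.05)
        assert lo <= fp <= hi
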