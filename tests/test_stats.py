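import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from tumortex import (
    ClassificationError,
    DesignError,
    GradeModel,
    ParameterError,
    SeparationError,
    assign_grade,
    backward_eliminate,
    clinical_model_from_counts,
    cohen_kappa,
    compare_2x2,
    delong_compare,
    fit_logistic,
    roc_analysis,
    univariate_screen,
)
from tumortex.stats import expand_2x2

from oracles import fisher_two_sided_oracle

TABLE2 = [[68, 13], [45, 22]]  # smoking (never/smoker) x grade (int/high)


class TestAssignGrade:
    @pytest.mark.parametrize(
        "subtype,grade",
        [
            ("lepidic predominant", "intermediate"),
            ("acinar predominant", "intermediate"),
            ("papillary predominant", "intermediate"),
            ("micropapillary predominant", "high"),
            ("solid predominant", "high"),
            ("colloid predominant", "high"),
            ("invasive mucinous adenocarcinoma", "high"),
            ("adenocarcinoma in situ", "low"),
            ("minimally invasive adenocarcinoma", "low"),
        ],
    )
    def test_grouping_rule(self, subtype, grade):
        assert assign_grade(subtype) == grade

    def test_cohort_subtype_counts_give_113_and_35(self):
        counts = {
            "acinar": 65,
            "lepidic": 36,
            "papillary": 12,
            "micropapillary": 6,
            "solid": 27,
            "invasive mucinous adenocarcinoma": 2,
        }
        groups = {"intermediate": 0, "high": 0, "low": 0}
        for subtype, n in counts.items():
            groups[assign_grade(subtype)] += n
        assert groups == {"intermediate": 113, "high": 35, "low": 0}

    def test_unknown_subtype_raises(self):
        with pytest.raises(ClassificationError):
            assign_grade("small cell carcinoma")


class TestKappa:
    def test_perfect_agreement(self):
        r = cohen_kappa([[10, 0], [0, 10]])
        assert r.kappa == pytest.approx(1.0)
        assert r.band == "excellent"

    def test_independence_gives_zero(self):
        r = cohen_kappa([[25, 25], [25, 25]])
        assert r.kappa == pytest.approx(0.0)
        assert r.band == "poor"

    def test_hand_computed_table(self):
        # po = 52/60, pe = (45*43 + 15*17)/60^2 -> kappa = 930/1410
        r = cohen_kappa([[40, 5], [3, 12]])
        assert r.po == pytest.approx(52 / 60)
        assert r.pe == pytest.approx(2190 / 3600)
        assert r.kappa == pytest.approx(930 / 1410, abs=1e-12)
        assert r.band == "substantial"

    def test_degenerate_marginals(self):
        # both raters constant and equal: pe = 1 but agreement is perfect
        assert cohen_kappa([[5, 0], [0, 0]]).kappa == 1.0
        # one rater constant: chance-corrected agreement collapses to 0
        assert cohen_kappa([[3, 2], [0, 0]]).kappa == pytest.approx(0.0)


class TestCompare2x2:
    def test_smoking_table_uses_chi_square(self):
        r = compare_2x2(TABLE2)
        assert r.method == "chi-square"
        assert r.statistic == pytest.approx(5.722, abs=0.01)
        assert r.p == pytest.approx(0.0168, abs=0.001)

    def test_low_counts_use_fisher(self):
        table = [[9, 1], [0, 10]]  # min expected cell 4.5 < 5
        r = compare_2x2(table)
        assert r.method == "fisher"
        assert r.p == pytest.approx(fisher_two_sided_oracle(table), rel=1e-9)

    def test_fisher_matches_enumeration_on_small_tables(self, rng):
        for _ in range(20):
            t = rng.integers(0, 8, size=(2, 2))
            if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
                continue
            _, p = sps.fisher_exact(t)
            assert p == pytest.approx(fisher_two_sided_oracle(t), rel=1e-9)

    def test_balanced_table_has_p_one(self):
        assert compare_2x2([[5, 5], [5, 5]]).p == pytest.approx(1.0)

    def test_zero_margin_flagged_degenerate(self):
        assert compare_2x2([[0, 0], [5, 5]]).method == "degenerate"


def _screen_frame(a, b):
    return pd.DataFrame(
        {
            "F1": np.concatenate([a, b]),
            "grade": ["intermediate"] * len(a) + ["high"] * len(b),
        }
    )


class TestUnivariateScreen:
    def test_identical_feature_never_significant(self):
        df = _screen_frame([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        out = univariate_screen(df, ["F1"])
        assert out.loc["F1", "degenerate"]
        assert out.loc["F1", "p"] == 1.0
        assert not out.loc["F1", "significant"]

    def test_mean_ranks_and_exact_u(self):
        df = _screen_frame([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        # force the rank branch to check the exact U p-value and mean ranks
        out = univariate_screen(df, ["F1"], normality_alpha=1.0)
        assert out.loc["F1", "test"] == "mann-whitney"
        assert out.loc["F1", "mean_rank_intermediate"] == pytest.approx(2.0)
        assert out.loc["F1", "mean_rank_high"] == pytest.approx(5.0)
        assert out.loc["F1", "p"] == pytest.approx(0.1)  # 2/C(6,3)

    def test_normal_groups_take_t_test(self, rng):
        df = _screen_frame(rng.normal(0, 1, 40), rng.normal(1, 1, 30))
        out = univariate_screen(df, ["F1"])
        assert out.loc["F1", "test"] == "t"
        ref = sps.ttest_ind(
            df[df.grade == "intermediate"]["F1"],
            df[df.grade == "high"]["F1"],
            equal_var=False,
        )
        assert out.loc["F1", "p"] == pytest.approx(ref.pvalue)

    def test_skewed_groups_take_mann_whitney(self, rng):
        df = _screen_frame(rng.lognormal(0, 1, 60), rng.lognormal(0.5, 1, 40))
        out = univariate_screen(df, ["F1"])
        assert out.loc["F1", "test"] == "mann-whitney"

    def test_benjamini_hochberg_is_more_conservative(self, rng):
        cols = {f"F{i}": rng.normal(0, 1, 30) for i in range(1, 21)}
        cols["F1"] += np.r_[np.zeros(15), np.ones(15) * 3]
        df = pd.DataFrame(cols)
        df["grade"] = ["intermediate"] * 15 + ["high"] * 15
        raw = univariate_screen(df, list(cols), adjust="none")
        bh = univariate_screen(df, list(cols), adjust="bh")
        assert bh["significant"].sum() <= raw["significant"].sum()
        assert (bh["q"] >= bh["p"] - 1e-12).all()


class TestFitLogistic:
    def test_2x2_closed_form_identity(self):
        smoker, y = expand_2x2(TABLE2)
        m = fit_logistic(smoker[:, None], y, names=["smoking"])
        beta = np.log((45 * 13) / (68 * 22))
        se = np.sqrt(1 / 68 + 1 / 13 + 1 / 45 + 1 / 22)
        assert m.params[1] == pytest.approx(beta, abs=1e-8)
        assert m.bse[1] == pytest.approx(se, abs=1e-8)

    def test_reproduces_printed_clinical_odds_ratio(self):
        m, _, _ = clinical_model_from_counts(TABLE2)
        sf = m.summary_frame().loc["smoking"]
        assert sf["odds_ratio"] == pytest.approx(0.391, abs=5e-4)
        assert sf["or_ci_low"] == pytest.approx(0.179, abs=5e-4)
        assert sf["or_ci_high"] == pytest.approx(0.855, abs=5e-4)
        assert sf["p"] == pytest.approx(0.019, abs=2e-3)

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        X = rng.normal(size=(300, 3))
        y = (rng.random(300) < 1 / (1 + np.exp(-(0.5 + X @ [1.0, -0.5, 0.0])))).astype(
            float
        )
        ours = fit_logistic(X, y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(ours.params, ref.params, atol=1e-6)
        np.testing.assert_allclose(ours.bse, ref.bse, atol=1e-6)

    def test_parameter_recovery(self, rng):
        n = 2000
        x = rng.normal(size=n)
        eta = -1.0 + 0.8 * x
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        m = fit_logistic(x[:, None], y)
        assert abs(m.params[0] - (-1.0)) < 3 * m.bse[0]
        assert abs(m.params[1] - 0.8) < 3 * m.bse[1]

    def test_perfect_separation_detected(self):
        x = np.r_[np.zeros(20), np.ones(20)]
        y = x.copy()
        with pytest.raises(SeparationError):
            fit_logistic(x[:, None], y)

    def test_rank_deficiency_detected(self, rng):
        x = rng.normal(size=50)
        X = np.column_stack([x, 2 * x])
        y = (rng.random(50) < 0.5).astype(float)
        with pytest.raises(DesignError):
            fit_logistic(X, y)

    def test_single_class_rejected(self):
        with pytest.raises(ParameterError):
            fit_logistic(np.ones((5, 1)), np.ones(5))


class TestBackwardElimination:
    def test_single_weak_candidate_gives_intercept_only(self, rng):
        x = rng.normal(size=200)
        y = (rng.random(200) < 0.4).astype(float)  # no association
        X = pd.DataFrame({"F1": x})
        m = backward_eliminate(X, y)
        assert m.predictor_names == []
        assert m.removed and m.removed[0][0] == "F1"

    def test_retains_signal_discards_noise(self, rng):
        kept_signal = 0
        for _ in range(100):
            n = 1000
            signal = rng.normal(size=n)
            noise = rng.normal(size=n)
            eta = signal  # beta = 1 on the signal, 0 on noise
            y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
            m = backward_eliminate(pd.DataFrame({"F1": signal, "F2": noise}), y)
            if m.predictor_names == ["F1"]:
                kept_signal += 1
        assert kept_signal >= 95

    def test_final_model_invariant_to_input_order(self, rng):
        n = 400
        X = pd.DataFrame(rng.normal(size=(n, 4)), columns=["F4", "F2", "F9", "F1"])
        eta = 0.8 * X["F2"] - 0.6 * X["F9"]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        m1 = backward_eliminate(X, y)
        m2 = backward_eliminate(X[["F1", "F9", "F2", "F4"]], y)
        assert m1.predictor_names == m2.predictor_names
        np.testing.assert_allclose(m1.params, m2.params)

    def test_never_removes_significant_predictor(self, rng):
        n = 500
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=["F1", "F2", "F3"])
        eta = 1.2 * X["F1"]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        m = backward_eliminate(X, y)
        for name, p in m.removed:
            assert np.isnan(p) or p > 0.05


class TestROC:
    def test_smoking_predictor_auc_and_youden(self):
        _, roc, _ = clinical_model_from_counts(TABLE2)
        assert roc.auc == pytest.approx(0.615, abs=5e-4)
        assert roc.sensitivity == pytest.approx(0.629, abs=5e-4)
        assert roc.specificity == pytest.approx(0.602, abs=5e-4)

    def test_perfect_separation_gives_auc_one(self):
        scores = np.r_[np.zeros(10), np.ones(10)]
        labels = scores.astype(int)
        r = roc_analysis(scores, labels)
        assert r.auc == 1.0
        assert r.sensitivity == 1.0 and r.specificity == 1.0

    def test_auc_equals_mann_whitney_identity(self, rng):
        for _ in range(10):
            scores = rng.integers(0, 6, size=80).astype(float)  # heavy ties
            labels = (rng.random(80) < 0.4).astype(int)
            if labels.min() == labels.max():
                continue
            r = roc_analysis(scores, labels)
            n1, n0 = labels.sum(), (1 - labels).sum()
            u = sps.mannwhitneyu(
                scores[labels == 1], scores[labels == 0], alternative="two-sided"
            ).statistic
            assert r.auc == pytest.approx(u / (n1 * n0), rel=1e-12)

    def test_null_scores_have_auc_near_half(self, rng):
        scores = rng.normal(size=200)
        labels = np.r_[np.ones(100), np.zeros(100)].astype(int)
        r = roc_analysis(scores, labels)
        se = np.sqrt(r.auc * (1 - r.auc) * (1 / 100 + 1 / 100) / 2)
        assert abs(r.auc - 0.5) < 3 * max(se, 0.04)

    def test_single_class_rejected(self):
        with pytest.raises(ParameterError):
            roc_analysis([1.0, 2.0], [1, 1])


class TestDeLong:
    def test_self_comparison_is_null(self, rng):
        scores = rng.normal(size=60)
        labels = (rng.random(60) < 0.5).astype(int)
        r = delong_compare(scores, scores, labels)
        assert r.delta == 0.0
        assert r.p == 1.0

    def test_detects_a_true_difference(self, rng):
        n = 400
        labels = (rng.random(n) < 0.4).astype(int)
        good = labels + rng.normal(0, 0.5, n)
        bad = rng.normal(size=n)
        r = delong_compare(good, bad, labels)
        assert r.auc_a > r.auc_b
        assert r.p < 1e-6

    def test_symmetry(self, rng):
        labels = (rng.random(100) < 0.5).astype(int)
        a, b = rng.normal(size=100), rng.normal(size=100)
        r1 = delong_compare(a, b, labels)
        r2 = delong_compare(b, a, labels)
        assert r1.delta == pytest.approx(-r2.delta)
        assert r1.p == pytest.approx(r2.p)


class TestGradeModel:
    def _cohort(self, rng, n1=60, n0=40, effect=1.5):
        f33 = np.r_[rng.normal(0.4, 0.05, n1), rng.normal(0.4 - 0.05 * effect, 0.05, n0)]
        f1 = rng.normal(5e6, 1e6, n1 + n0)
        smoking = np.r_[
            np.where(rng.random(n1) < 0.4, "smoker", "never"),
            np.where(rng.random(n0) < 0.6, "smoker", "never"),
        ]
        return pd.DataFrame(
            {
                "F33": f33,
                "F1": f1,
                "smoking": smoking,
                "age": rng.integers(40, 80, n1 + n0),
                "grade": ["intermediate"] * n1 + ["high"] * n0,
            }
        )

    def test_fit_produces_models_roc_and_delong(self, rng):
        res = GradeModel(self._cohort(rng)).fit()
        assert res.univariate is not None
        assert res.univariate.loc["F33", "significant"]
        assert "F33" in res.texture_model.predictor_names
        assert res.texture_roc.auc > res.clinical_roc.auc
        assert 0 <= res.delong.p <= 1
        s = res.summary()
        assert "Texture model" in s and "DeLong" in s

    def test_threshold_validation(self, rng):
        df = self._cohort(rng)
        with pytest.raises(ParameterError):
            GradeModel(df, entry_p=0.05, removal_p=0.15)
        with pytest.raises(ParameterError):
            GradeModel(df, entry_p=1.5)
        GradeModel(df, entry_p=0.05, removal_p=0.05)  # boundary is valid

    def test_single_class_cohort_rejected(self, rng):
        df = self._cohort(rng)
        with pytest.raises(ParameterError):
            GradeModel(df[df.grade == "intermediate"])
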