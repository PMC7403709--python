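"""Splitting, discrimination, calibration, decision curves, baseline tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pathosig import evaluation


def brute_force_auc(scores, labels):
    """Average over all positive-negative pairs; ties count one half."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestSplit:
    def test_study_sized_split(self):
        pats = pd.DataFrame(
            {"patient_id": range(151), "label": ["PR"] * 79 + ["non-PR"] * 72}
        )
        primary, validation = evaluation.split_cohort(pats, ratio=0.8, seed=0)
        assert (len(primary), len(validation)) == (120, 31)

    def test_small_split(self):
        pats = pd.DataFrame({"patient_id": range(10), "label": ["PR", "non-PR"] * 5})
        primary, validation = evaluation.split_cohort(pats, ratio=0.8, seed=1)
        assert (len(primary), len(validation)) == (8, 2)

    def test_disjoint_exhaustive_and_deterministic(self):
        pats = pd.DataFrame({"patient_id": range(37), "label": ["PR", "non-PR", "PR"] * 12 + ["PR"]})
        a1, b1 = evaluation.split_cohort(pats, seed=5)
        a2, b2 = evaluation.split_cohort(pats, seed=5)
        assert set(a1["patient_id"]) == set(a2["patient_id"])
        assert not (set(a1["patient_id"]) & set(b1["patient_id"]))
        assert set(a1["patient_id"]) | set(b1["patient_id"]) == set(range(37))

    def test_stratification_preserves_prevalence(self):
        pats = pd.DataFrame(
            {"patient_id": range(100), "label": ["PR"] * 40 + ["non-PR"] * 60}
        )
        primary, validation = evaluation.split_cohort(pats, ratio=0.8, seed=2)
        assert (primary["label"] == "PR").sum() == 32
        assert (validation["label"] == "PR").sum() == 8

    def test_invalid_ratio(self):
        pats = pd.DataFrame({"patient_id": range(10), "label": ["PR", "non-PR"] * 5})
        with pytest.raises(ValueError):
            evaluation.split_cohort(pats, ratio=1.2)


class TestAuc:
    def test_perfect_ranking(self):
        roc = evaluation.compute_auc([0.9, 0.8, 0.7], [1, 1, 0])
        assert roc.auc == 1.0

    def test_total_ties_give_half(self):
        roc = evaluation.compute_auc([0.5] * 8, [1, 0, 1, 0, 1, 0, 1, 0])
        assert roc.auc == pytest.approx(0.5)

    def test_matches_pairwise_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(8, 50))
            scores = np.round(rng.uniform(size=n), 2)  # rounding induces ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            roc = evaluation.compute_auc(scores, labels)
            assert roc.auc == pytest.approx(brute_force_auc(scores, labels))

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.uniform(size=30)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        a = evaluation.compute_auc(scores, labels).auc
        b = evaluation.compute_auc(np.exp(5 * scores), labels).auc
        assert a == pytest.approx(b)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            evaluation.compute_auc([0.1, 0.2], [1, 1])

    def test_delong_and_bootstrap_cis_bracket_auc(self, rng):
        scores = np.r_[rng.normal(1, 1, 40), rng.normal(0, 1, 40)]
        labels = np.r_[np.ones(40), np.zeros(40)]
        for method in ("bootstrap", "delong"):
            roc = evaluation.compute_auc(scores, labels, ci=method, B=300, seed=0)
            lo, hi = roc.ci
            assert 0 <= lo <= roc.auc <= hi <= 1


class TestBootstrap:
    def test_constant_metric_zero_width(self, rng):
        ci = evaluation.bootstrap_ci(
            lambda s, l: 0.7, rng.uniform(size=30), rng.integers(0, 2, 30), B=200, seed=0
        )
        assert ci == (0.7, 0.7)

    def test_deterministic_for_seed(self, rng):
        scores = rng.uniform(size=40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        from sklearn.metrics import roc_auc_score

        fn = lambda s, l: roc_auc_score(l, s)
        a = evaluation.bootstrap_ci(fn, scores, labels, B=200, seed=9)
        b = evaluation.bootstrap_ci(fn, scores, labels, B=200, seed=9)
        assert a == b

    def test_small_B_rejected(self):
        with pytest.raises(ValueError):
            evaluation.bootstrap_ci(lambda s, l: 0.5, [0.1], [1], B=10)


class TestThresholdMetrics:
    def test_printed_confusion_toy(self):
        # TP=7, FN=3, TN=8, FP=2 at threshold 0.5
        scores = np.r_[np.full(7, 0.9), np.full(3, 0.1), np.full(8, 0.1), np.full(2, 0.9)]
        labels = np.r_[np.ones(10), np.zeros(10)]
        tm = evaluation.threshold_metrics(scores, labels, 0.5)
        assert (tm.tp, tm.fn, tm.tn, tm.fp) == (7, 3, 8, 2)
        assert tm.sensitivity == pytest.approx(0.7)
        assert tm.specificity == pytest.approx(0.8)
        assert tm.accuracy == pytest.approx(0.75)
        assert tm.f1 == pytest.approx(0.737, abs=5e-4)

    def test_perfect_scores(self):
        tm = evaluation.threshold_metrics([0.9, 0.9, 0.1], [1, 1, 0], 0.5)
        assert tm.accuracy == tm.sensitivity == tm.specificity == tm.f1 == 1.0

    def test_predict_all_positive(self):
        tm = evaluation.threshold_metrics([0.9, 0.9, 0.9], [1, 0, 1], 0.5)
        assert tm.sensitivity == 1.0 and tm.specificity == 0.0

    def test_youden_threshold_separates(self):
        scores = np.r_[np.full(10, 0.8), np.full(10, 0.2)]
        labels = np.r_[np.ones(10), np.zeros(10)]
        thr = evaluation.youden_threshold(scores, labels)
        tm = evaluation.threshold_metrics(scores, labels, thr)
        assert tm.sensitivity == 1.0 and tm.specificity == 1.0


class TestCalibration:
    def test_bin_sizes_sum_to_n(self, rng):
        scores = rng.uniform(size=97)
        labels = rng.integers(0, 2, 97)
        cal = evaluation.calibration_curve(scores, labels, g=10)
        assert cal["n"].sum() == 97

    def test_constant_score_single_bin(self):
        with pytest.warns(UserWarning):
            cal = evaluation.calibration_curve(np.full(30, 0.4), np.zeros(30), g=10)
        assert len(cal) == 1

    def test_calibrated_model_bins_close(self):
        gen = np.random.default_rng(3)
        p = gen.uniform(0.05, 0.95, size=4000)
        y = gen.binomial(1, p)
        cal = evaluation.calibration_curve(p, y, g=10)
        gaps = (cal["mean_predicted"] - cal["observed_fraction"]).abs()
        assert gaps.max() < 0.08


class TestHosmerLemeshow:
    def test_observed_equals_expected_gives_zero(self):
        # 4 bins of 5 with constant score p and exactly 5p observed events
        ps = [0.2, 0.4, 0.6, 0.8]
        scores = np.repeat(ps, 5)
        labels = np.concatenate(
            [np.r_[np.ones(int(5 * p)), np.zeros(5 - int(5 * p))] for p in ps]
        )
        hl = evaluation.hosmer_lemeshow(scores, labels, g=4)
        assert hl.statistic == pytest.approx(0.0, abs=1e-9)
        assert hl.p_value == pytest.approx(1.0)

    def test_three_bin_hand_computation(self):
        # bins: n=4 p=0.25 obs=2 | n=4 p=0.5 obs=2 | n=4 p=0.75 obs=2
        scores = np.repeat([0.25, 0.5, 0.75], 4)
        labels = np.tile([1, 1, 0, 0], 3)
        hl = evaluation.hosmer_lemeshow(scores, labels, g=3)
        # hand: bin1 (2-1)^2/(1*(1-.25)) = 4/3; bin2 0; bin3 (2-3)^2/(3*(1-.75)) = 4/3
        assert hl.statistic == pytest.approx(8 / 3)
        assert hl.df == 1
        assert hl.p_value == pytest.approx(stats.chi2.sf(8 / 3, 1))

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            evaluation.hosmer_lemeshow(np.full(5, 0.5), np.ones(5), g=10)

    def test_null_pvalues_roughly_uniform_for_fitted_model(self):
        # chi-square(g-2) calibration holds for probabilities fitted on the
        # same data by a correctly specified model
        import statsmodels.api as sm
        from scipy.special import expit

        gen = np.random.default_rng(7)
        pvals = []
        for _ in range(100):
            x = gen.normal(size=400)
            y = gen.binomial(1, expit(-0.3 + 0.8 * x))
            fit = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
            pvals.append(evaluation.hosmer_lemeshow(fit.predict(), y, g=10).p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestDecisionCurve:
    def test_treat_all_closed_form(self, rng):
        scores = rng.uniform(size=200)
        labels = rng.integers(0, 2, 200)
        labels[:2] = [0, 1]
        pi = labels.mean()
        dc = evaluation.decision_curve(scores, labels)
        t = dc["threshold"].to_numpy()
        assert np.allclose(dc["net_benefit_all"], pi - (1 - pi) * t / (1 - t))
        assert (dc["net_benefit_none"] == 0).all()

    def test_perfect_classifier_net_benefit_is_prevalence(self):
        labels = np.r_[np.ones(30), np.zeros(70)]
        scores = labels.astype(float)
        dc = evaluation.decision_curve(scores, labels, thresholds=np.arange(0.05, 1.0, 0.05))
        assert np.allclose(dc["net_benefit_model"], 0.3)

    def test_all_positive_at_half_prevalence_is_zero(self):
        labels = np.r_[np.ones(50), np.zeros(50)]
        dc = evaluation.decision_curve(np.ones(100), labels, thresholds=[0.5])
        assert dc["net_benefit_model"].iloc[0] == pytest.approx(0.0)

    def test_net_benefit_bounded_by_prevalence(self, rng):
        scores = rng.uniform(size=150)
        labels = (scores + rng.normal(0, 0.3, 150) > 0.5).astype(int)
        dc = evaluation.decision_curve(scores, labels)
        assert (dc["net_benefit_model"] <= labels.mean() + 1e-12).all()


def expand_counts(counts: dict[str, dict[str, int]], variable: str) -> pd.DataFrame:
    """Patient-level table from a {group: {level: count}} spec."""
    rows = []
    for grp, levels in counts.items():
        for level, n in levels.items():
            rows.extend({"label": grp, variable: level} for _ in range(n))
    return pd.DataFrame(rows)


class TestUnivariable:
    def test_n_staging_chi_square(self):
        tab = expand_counts(
            {"non-PR": {"N0": 6, "N1": 46, "N2": 9}, "PR": {"N0": 17, "N1": 31, "N2": 11}},
            "n_stage",
        )
        res = evaluation.univariable_tests(tab)[0]
        assert res.test == "chi-square"
        assert res.statistic == pytest.approx(8.35, abs=0.01)
        assert res.df == 2
        assert res.p_value == pytest.approx(0.015, abs=5e-4)

    def test_gender_chi_square_with_continuity(self):
        tab = expand_counts(
            {"non-PR": {"male": 38, "female": 23}, "PR": {"male": 42, "female": 17}},
            "gender",
        )
        res = evaluation.univariable_tests(tab)[0]
        assert res.p_value == pytest.approx(0.401, abs=5e-4)

    def test_identical_columns_give_p_one(self):
        tab = expand_counts(
            {"non-PR": {"normal": 10, "abnormal": 10}, "PR": {"normal": 10, "abnormal": 10}},
            "cea",
        )
        res = evaluation.univariable_tests(tab)[0]
        assert res.p_value == pytest.approx(1.0)

    def test_sparse_2x2_uses_fisher(self):
        tab = expand_counts(
            {"non-PR": {"normal": 2, "abnormal": 12}, "PR": {"normal": 1, "abnormal": 13}},
            "cea",
        )
        res = evaluation.univariable_tests(tab)[0]
        assert res.test == "fisher"

    def test_single_category_variable_skipped(self):
        tab = expand_counts(
            {"non-PR": {"normal": 10}, "PR": {"normal": 12}}, "cea"
        )
        with pytest.warns(UserWarning, match="single-category"):
            assert evaluation.univariable_tests(tab) == []

    def test_continuous_tests(self, rng):
        tab = pd.DataFrame(
            {"label": ["PR"] * 30 + ["non-PR"] * 30, "age": rng.normal(55, 10, 60)}
        )
        mw = evaluation.univariable_tests(tab)[0]
        assert mw.test == "mann-whitney"
        tt = evaluation.univariable_tests(tab, continuous_test="t")[0]
        assert tt.test == "t"


class TestSummarize:
    def test_percentages_within_columns(self):
        tab = expand_counts(
            {"non-PR": {"male": 38, "female": 23}, "PR": {"male": 42, "female": 17}},
            "gender",
        )
        summary = evaluation.summarize_cohort(tab)
        male = summary[(summary["variable"] == "gender") & (summary["level"] == "male")]
        assert male["non-PR_pct"].iloc[0] == pytest.approx(100 * 38 / 61, abs=0.05)
        assert male["PR_pct"].iloc[0] == pytest.approx(100 * 42 / 59, abs=0.05)
        assert male["non-PR"].iloc[0] == "38 (62.3%)"
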