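import itertools

import numpy as np
import pandas as pd
import pytest

from mrcomplexity.prediction import (auc_rank, auc_with_ci, classifier_spec,
                                     compare_classifiers, evaluate_classifier,
                                     loocv_predict, model_aic, pearson_screen,
                                     threshold_metrics, variable_importance,
                                     CLASSIFIER_SETS)


def auc_pair_counting(probs, outcomes):
    """Exhaustive concordant/tied pair enumeration."""
    pos = [p for p, y in zip(probs, outcomes) if y == 1]
    neg = [p for p, y in zip(probs, outcomes) if y == 0]
    wins = sum(1.0 if p > q else 0.5 if p == q else 0.0
               for p, q in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


class TestAuc:
    def test_perfect_probabilities_score_one(self):
        y = np.array([0, 1, 0, 1.0])
        assert auc_rank(y, y) == 1.0

    def test_four_point_examples(self):
        probs = np.array([0.9, 0.8, 0.3, 0.2])
        assert auc_rank(probs, np.array([1, 1, 0, 0.0])) == 1.0
        assert auc_rank(probs, np.array([1, 0, 1, 0.0])) == 0.75

    def test_rank_statistic_equals_pair_counting_up_to_n50(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 51))
            probs = rng.choice(np.linspace(0, 1, 11), size=n)  # force ties
            outcomes = rng.integers(0, 2, size=n).astype(float)
            if outcomes.sum() in (0, n):
                continue
            assert auc_rank(probs, outcomes) == pytest.approx(
                auc_pair_counting(probs, outcomes), abs=1e-12)

    def test_single_class_is_an_error(self):
        with pytest.raises(ValueError):
            auc_rank(np.array([0.2, 0.4]), np.array([1.0, 1.0]))

    def test_bootstrap_ci_is_bit_reproducible(self, rng):
        probs = rng.random(60)
        outcomes = rng.integers(0, 2, 60).astype(float)
        first = auc_with_ci(probs, outcomes, repetitions=500, seed=9)
        second = auc_with_ci(probs, outcomes, repetitions=500, seed=9)
        assert first == second
        third = auc_with_ci(probs, outcomes, repetitions=500, seed=10)
        assert third != first


class TestThresholdMetrics:
    def test_perfect_classifier(self):
        y = np.array([0, 0, 1, 1.0])
        sens, spec, _ = threshold_metrics(np.array([0.1, 0.2, 0.8, 0.9]), y)
        assert (sens, spec) == (1.0, 1.0)

    def test_all_positive_predictions_at_fixed_zero_threshold(self):
        y = np.array([0, 0, 1, 1.0])
        sens, spec, _ = threshold_metrics(
            np.array([0.6, 0.7, 0.8, 0.9]), y, rule="fixed", fixed_threshold=0.0)
        assert (sens, spec) == (1.0, 0.0)

    def test_fixed_half_threshold_matches_confusion_matrix_oracle(self):
        probs = np.array([0.9, 0.8, 0.3, 0.2])
        outcomes = np.array([1, 0, 1, 0.0])
        sens, spec, _ = threshold_metrics(probs, outcomes, rule="fixed",
                                          fixed_threshold=0.5)
        # predictions: 1,1,0,0 -> TP=1 FN=1 TN=1 FP=1
        assert (sens, spec) == (0.5, 0.5)

    def test_youden_threshold_maximizes_j(self, rng):
        probs = rng.random(80)
        outcomes = (probs + rng.normal(0, 0.3, 80) > 0.5).astype(float)
        sens, spec, threshold = threshold_metrics(probs, outcomes)
        js = []
        for t in np.unique(probs):
            pred = probs >= t
            js.append(((pred & (outcomes == 1)).sum() / outcomes.sum())
                      + ((~pred & (outcomes == 0)).sum() / (1 - outcomes).sum()) - 1)
        assert sens + spec - 1 == pytest.approx(max(js), abs=1e-12)


class TestLoocv:
    def test_separable_toy_data_reaches_high_auc(self):
        rng = np.random.default_rng(5)
        n = 60
        y = np.r_[np.ones(30), np.zeros(30)]
        table = pd.DataFrame({
            "age": 50 + 10 * y + rng.normal(0, 1, n),  # strong signal
            "sex_male": rng.integers(0, 2, n).astype(float),
            "height": rng.normal(170, 10, n),
            "weight": rng.normal(80, 10, n),
            "bmi": rng.normal(28, 4, n),
            "race_white": rng.integers(0, 2, n).astype(float),
            "race_black": 0.0,
            "race_hispanic": 0.0,
            "race_asian": 0.0,
            "mrci_24h": rng.normal(60, 10, n),
            "mrci_48h": rng.normal(70, 10, n),
            "mortality": y,
        })
        spec = classifier_spec("mrci", "mortality")
        probs, yv, _ = loocv_predict(spec, table)
        assert auc_rank(probs, yv) > 0.95

    def test_minimum_cohort_size_enforced(self):
        table = pd.DataFrame({c: np.random.default_rng(0).normal(size=3)
                              for c in classifier_spec("mrci", "mv").variables})
        table["mv"] = [0.0, 1.0, 0.0]
        with pytest.raises(ValueError, match="at least 20"):
            loocv_predict(classifier_spec("mrci", "mv"), table)

    def test_probabilities_are_deterministic(self, pipeline_result):
        spec = classifier_spec("mrc_icu", "mortality")
        first, y1, _ = loocv_predict(spec, pipeline_result.analysis_table)
        second, y2, _ = loocv_predict(spec, pipeline_result.analysis_table)
        assert np.array_equal(first, second)


class TestImportanceAndAic:
    def test_dominant_predictor_ranks_first(self, rng):
        n = 400
        x = rng.normal(0, 1, n)
        table = pd.DataFrame({
            "age": x, "sex_male": rng.integers(0, 2, n).astype(float),
            "height": rng.normal(0, 1, n), "weight": rng.normal(0, 1, n),
            "bmi": rng.normal(0, 1, n), "race_white": rng.integers(0, 2, n).astype(float),
            "race_black": rng.integers(0, 2, n).astype(float),
            "race_hispanic": rng.integers(0, 2, n).astype(float),
            "race_asian": rng.integers(0, 2, n).astype(float),
            "mrc_icu_24h": rng.normal(0, 1, n), "mrc_icu_48h": rng.normal(0, 1, n),
        })
        logits = 3.0 * table["mrc_icu_24h"] + 0.3 * x
        table["mortality"] = (rng.random(n) < 1 / (1 + np.exp(-logits))).astype(float)
        ranking = variable_importance(classifier_spec("mrc_icu", "mortality"), table)
        assert ranking.index[0] == "mrc_icu_24h"

    def test_equal_importances_rank_alphabetically(self):
        from mrcomplexity.prediction import rank_importance

        ranking = rank_importance({"weight": 0.5, "age": 0.5,
                                   "saps2": 0.9, "bmi": 0.5})
        assert list(ranking.index) == ["saps2", "age", "bmi", "weight"]

    def test_aic_equals_deviance_plus_two_k(self, pipeline_result):
        import statsmodels.api as sm

        spec = classifier_spec("mrc_icu", "mortality")
        aic = model_aic(spec, pipeline_result.analysis_table)
        from mrcomplexity.prediction import _design

        X, y = _design(spec, pipeline_result.analysis_table)
        ref = sm.Logit(np.asarray(y), sm.add_constant(np.asarray(X))).fit(disp=0)
        assert aic == pytest.approx(ref.aic, rel=1e-6)

    def test_informative_predictor_beats_intercept_only_aic(self, rng):
        n = 300
        x = rng.normal(0, 1, n)
        y = (rng.random(n) < 1 / (1 + np.exp(-2 * x))).astype(float)
        import statsmodels.api as sm

        with_x = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        intercept_only = sm.Logit(y, np.ones((n, 1))).fit(disp=0)
        assert with_x.aic < intercept_only.aic


class TestCompare:
    def test_identical_specs_produce_identical_rows(self, pipeline_result):
        spec = classifier_spec("mrc_icu", "mortality")
        res = [evaluate_classifier(spec, pipeline_result.analysis_table,
                                   repetitions=200, seed=4) for _ in range(2)]
        frame = compare_classifiers(res)
        assert frame.iloc[0].drop("best3").equals(frame.iloc[1].drop("best3"))

    def test_best3_flags_three_models_per_outcome(self, pipeline_result):
        results = [evaluate_classifier(classifier_spec(name, "mortality"),
                                       pipeline_result.analysis_table,
                                       repetitions=100, seed=1)
                   for name in ("admission", "mrci", "mrc_icu", "medication")]
        frame = compare_classifiers(results)
        assert frame["best3"].sum() == 3

    def test_every_spec_includes_demographics(self):
        for name in CLASSIFIER_SETS:
            spec = classifier_spec(name, "mortality")
            assert {"age", "sex_male", "bmi"} <= set(spec.variables)

    def test_combined_severity_models_use_saps2_not_apache2(self):
        for name in ("mrci_saps2", "mrc_icu_saps2", "full"):
            variables = classifier_spec(name, "mv").variables
            assert "saps2" in variables
            assert "apache2" not in variables

    def test_pearson_screen_reports_strongly_correlated_pair(self, pipeline_result):
        table = pipeline_result.analysis_table.copy()
        table["apache2_like"] = table["apache2"] * 1.01 + 0.5
        report = pearson_screen(table, ("apache2", "apache2_like", "bmi"))
        pairs = set(map(tuple, report[["var_a", "var_b"]].to_numpy()))
        assert ("apache2", "apache2_like") in pairs
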