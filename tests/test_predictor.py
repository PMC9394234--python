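"""Risk predictor: importance ranking, pair rules, chr18→chr10, stress tests."""

import numpy as np
import pandas as pd
import pytest

from clonefish import (
    PredictorConfig,
    chr18_chr10_rule,
    classification_report,
    evaluate_pair_rules,
    gini_importance_loocv,
    stress_test,
)
from clonefish.predictor import FAVORABLE, UNFAVORABLE

CHROMS = ["X", "4", "6", "10", "14", "17", "18", "21"]
FAST = PredictorConfig(n_trees=50, seed=0)


def planted_cohort(rng, n=24, sd=5.0):
    """Outcome determined by (%+18 > 40) and (%+10 > 40), noise elsewhere."""
    y = np.array([FAVORABLE] * (n // 2) + [UNFAVORABLE] * (n // 2))
    X = pd.DataFrame(rng.uniform(10, 90, size=(n, 8)), columns=CHROMS)
    fav = y == FAVORABLE
    X.loc[fav, "18"] = rng.normal(65, sd, fav.sum()).clip(45, 95)
    X.loc[fav, "10"] = rng.normal(65, sd, fav.sum()).clip(45, 95)
    X.loc[~fav, "18"] = rng.normal(20, sd, (~fav).sum()).clip(2, 35)
    X.loc[~fav, "10"] = rng.normal(20, sd, (~fav).sum()).clip(2, 35)
    return X, y


class TestGiniImportance:
    def test_constant_feature_has_zero_importance(self, rng):
        X, y = planted_cohort(rng)
        X["4"] = 50.0
        imp, _ = gini_importance_loocv(X, y, FAST)
        assert (imp["4"] == 0.0).all()

    def test_perfect_separator_ranks_first_in_every_fold(self, rng):
        n = 20
        y = np.array([FAVORABLE] * 10 + [UNFAVORABLE] * 10)
        X = pd.DataFrame(rng.uniform(0, 100, size=(n, 8)), columns=CHROMS)
        X["18"] = np.where(y == FAVORABLE, 80.0, 10.0)
        imp, ranking = gini_importance_loocv(X, y, FAST)
        assert ranking[0] == "18"
        assert (imp.idxmax(axis=1) == "18").all()

    def test_planted_shift_puts_18_and_10_on_top(self, rng):
        X, y = planted_cohort(rng)
        _, ranking = gini_importance_loocv(X, y, FAST)
        assert set(ranking[:2]) == {"18", "10"}

    def test_single_class_rejected(self, rng):
        X, _ = planted_cohort(rng)
        with pytest.raises(ValueError):
            gini_importance_loocv(X, [FAVORABLE] * len(X), FAST)


class TestPairRules:
    def test_exact_rule_thresholds_recovered_to_data_resolution(self, rng):
        n = 200
        X = pd.DataFrame(rng.uniform(5, 95, size=(n, 8)), columns=CHROMS)
        y = np.where((X["18"] > 40) & (X["10"] > 40), FAVORABLE, UNFAVORABLE)
        out = evaluate_pair_rules(X, y, [("18", "10")], FAST)
        row = out.iloc[0]
        assert row.loocv_accuracy >= 0.97
        assert abs(row.threshold_1 - 40) <= 5
        assert abs(row.threshold_2 - 40) <= 5

    def test_random_labels_near_majority_rate(self, rng):
        n = 30
        X = pd.DataFrame(rng.uniform(0, 100, size=(n, 8)), columns=CHROMS)
        y = rng.permutation([FAVORABLE] * 15 + [UNFAVORABLE] * 15)
        out = evaluate_pair_rules(X, y, [("18", "10")], FAST)
        assert out.loocv_accuracy.iloc[0] <= 0.75  # no better than chance-ish

    def test_separating_feature_pair_wins(self, rng):
        n = 20
        y = np.array([FAVORABLE] * 10 + [UNFAVORABLE] * 10)
        X = pd.DataFrame(rng.uniform(0, 100, size=(n, 8)), columns=CHROMS)
        X["17"] = np.where(y == FAVORABLE, 80.0, 10.0)
        out = evaluate_pair_rules(X, y, [("17", "4"), ("X", "6")], FAST)
        assert out.iloc[0]["pair"] == "17-4"
        assert out.iloc[0].loocv_accuracy == 1.0


class TestRule:
    @pytest.mark.parametrize(
        "p18,p10,label,step",
        [
            (80, 80, FAVORABLE, None),
            (30, 90, UNFAVORABLE, "step1"),
            (90, 30, UNFAVORABLE, "step2"),
            (40, 40, UNFAVORABLE, "step1"),  # boundary: strict-greater favorable
        ],
    )
    def test_two_step_rule(self, p18, p10, label, step):
        call = chr18_chr10_rule({"18": p18, "10": p10})
        assert call.label == label
        if step:
            assert call.rule_trace.startswith(step)

    def test_missing_feature_errors(self):
        with pytest.raises(ValueError, match="chromosome-10"):
            chr18_chr10_rule({"18": 50.0})

    def test_inclusive_boundary_policy(self):
        config = PredictorConfig(strict_favorable=False)
        assert chr18_chr10_rule({"18": 40, "10": 40}, config).label == FAVORABLE


class TestClassificationReport:
    def test_perfect_calls(self):
        rep = classification_report([FAVORABLE, UNFAVORABLE], [FAVORABLE, UNFAVORABLE])
        assert rep["overall_accuracy"] == 100.0
        assert rep["favorable_accuracy"] == rep["unfavorable_accuracy"] == 100.0

    def test_one_miscall_among_22(self):
        truth = [FAVORABLE] * 10 + [UNFAVORABLE] * 12
        calls = [UNFAVORABLE] + [FAVORABLE] * 9 + [UNFAVORABLE] * 12
        rep = classification_report(calls, truth)
        assert rep["overall_accuracy"] == pytest.approx(100 * 21 / 22)
        assert rep["favorable_accuracy"] == pytest.approx(90.0)

    def test_degenerate_all_unfavorable_calls(self):
        truth = [FAVORABLE] * 5 + [UNFAVORABLE] * 5
        rep = classification_report([UNFAVORABLE] * 10, truth)
        assert rep["unfavorable_accuracy"] == 100.0
        assert rep["favorable_accuracy"] == 0.0

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            classification_report([FAVORABLE], [FAVORABLE, UNFAVORABLE])


class TestStressTest:
    def _features(self, rows):
        return pd.DataFrame(rows, columns=["18", "10"])

    def test_zero_noise_equals_noiseless_confusion(self, rng):
        X = self._features(rng.uniform(0, 100, size=(12, 2)))
        y = [chr18_chr10_rule(dict(r)).label for _, r in X.iterrows()]
        # flip two labels so the noiseless confusion is non-trivial
        y[0] = FAVORABLE if y[0] == UNFAVORABLE else UNFAVORABLE
        y[5] = FAVORABLE if y[5] == UNFAVORABLE else UNFAVORABLE
        res = stress_test(chr18_chr10_rule, X, y, noise_levels=[0.0], reps=20, seed=1)
        assert res.mean_correct[0] == 10.0 and res.mean_misclassified[0] == 2.0

    def test_margin_larger_than_noise_never_flips(self):
        X = self._features([[60.0, 60.0], [15.0, 15.0]])
        y = [FAVORABLE, UNFAVORABLE]
        res = stress_test(chr18_chr10_rule, X, y, noise_levels=[10.0], reps=50, seed=2)
        assert res.mean_correct[0] == 2.0

    def test_closed_form_flip_probability_at_margin_one(self):
        """A sample at threshold + 1 under Uniform(0, 10) noise flips with
        probability 0.5 * P(u > 1) = 0.45 per repetition (the chr10 feature
        is held far above threshold so only chr18 can flip)."""
        X = self._features([[41.0, 99.0]])
        y = [FAVORABLE]
        reps = 2000
        res = stress_test(chr18_chr10_rule, X, y, noise_levels=[10.0], reps=reps, seed=3)
        flip_rate = res.mean_misclassified[0]
        se = np.sqrt(0.45 * 0.55 / reps)
        assert abs(flip_rate - 0.45) < 3 * se

    def test_reproducible_given_seed(self, rng):
        X = self._features(rng.uniform(0, 100, size=(10, 2)))
        y = [chr18_chr10_rule(dict(r)).label for _, r in X.iterrows()]
        a = stress_test(chr18_chr10_rule, X, y, noise_levels=[5, 15], reps=30, seed=9)
        b = stress_test(chr18_chr10_rule, X, y, noise_levels=[5, 15], reps=30, seed=9)
        assert a.mean_correct == b.mean_correct

    def test_misclassification_monotone_in_noise_on_seed_average(self, rng):
        X, y = planted_cohort(rng, n=20, sd=8.0)
        feats = X[["18", "10"]]
        levels = [0, 5, 10, 20, 30]
        curves = []
        for seed in range(10):
            res = stress_test(chr18_chr10_rule, feats, y, noise_levels=levels,
                              reps=40, seed=seed)
            curves.append(res.mean_misclassified)
        avg = np.mean(curves, axis=0)
        assert all(avg[i] <= avg[i + 1] + 1e-9 for i in range(len(avg) - 1))

    def test_negative_noise_level_rejected(self):
        X = self._features([[50.0, 50.0]])
        with pytest.raises(ValueError):
            stress_test(chr18_chr10_rule, X, [FAVORABLE], noise_levels=[-1.0])
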