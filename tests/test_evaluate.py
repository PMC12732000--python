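"""Metric identities, cross-validation mechanics and attribution."""

import numpy as np
import pandas as pd
import pytest

from adentropy.evaluate import (
    classification_metrics,
    kfold_cv,
    permutation_delta_rmse,
    regression_metrics,
    rf_importance,
    rolling_window_eval,
)
from adentropy.models import RFSpec, SVMSpec, fit_model
from adentropy.synth import INPUT_VARIABLES

FEATURES = list(INPUT_VARIABLES)


class TestClassificationMetrics:
    def test_hand_worked_contingency(self):
        """TP=9, FP=1, FN=1, TN=9 gives 0.9 across the board."""
        labels = np.array([1] * 10 + [-1] * 10)
        preds = np.array([1] * 9 + [-1] + [1] + [-1] * 9)
        scores = preds.astype(float)
        m = classification_metrics(labels, preds, scores)
        assert (m.tp, m.fp, m.fn, m.tn) == (9, 1, 1, 9)
        for value in (m.accuracy, m.precision, m.recall, m.f1):
            assert value == pytest.approx(0.9, abs=1e-12)

    def test_perfect_prediction(self):
        labels = np.array([1, -1, 1, -1])
        m = classification_metrics(labels, labels, labels.astype(float))
        assert m.accuracy == m.precision == m.recall == m.f1 == m.auroc == 1.0

    def test_anti_perfect_ranking_gives_auroc_zero(self):
        labels = np.array([1, 1, -1, -1])
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        m = classification_metrics(labels, np.where(scores > 0.5, 1, -1), scores)
        assert m.auroc == 0.0

    def test_f1_harmonic_mean_identity(self):
        rng = np.random.default_rng(0)
        labels = rng.choice([-1, 1], 100)
        preds = rng.choice([-1, 1], 100)
        if len(np.unique(labels)) < 2:
            labels[0] = -labels[0]
        m = classification_metrics(labels, preds, rng.normal(size=100))
        if not np.isnan(m.f1):
            assert m.f1 == pytest.approx(
                2 * m.precision * m.recall / (m.precision + m.recall), abs=1e-12
            )
        assert m.tp + m.fp + m.fn + m.tn == 100
        assert m.accuracy == pytest.approx((m.tp + m.tn) / 100, abs=1e-12)

    def test_auroc_equals_brute_force_pair_ordering(self):
        """Mid-rank AUROC equals the fraction of correctly ordered
        positive/negative pairs (ties counted half) on <= 200 rows."""
        rng = np.random.default_rng(3)
        labels = rng.choice([-1, 1], 200)
        labels[:2] = [1, -1]
        scores = np.round(rng.normal(size=200), 1)  # deliberate ties
        m = classification_metrics(labels, np.sign(scores + 1e-9), scores)
        pos, neg = scores[labels == 1], scores[labels == -1]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert m.auroc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)

    def test_zero_denominator_flagged_nan(self):
        labels = np.array([1, -1, -1, -1])
        preds = np.array([-1, -1, -1, -1])  # no positive predictions
        m = classification_metrics(labels, preds, preds.astype(float))
        assert np.isnan(m.precision) and np.isnan(m.f1)

    def test_single_class_auroc_undefined(self):
        with pytest.raises(ValueError, match="single class"):
            classification_metrics([1, 1], [1, 1], [0.5, 0.7])


class TestRegressionMetrics:
    def test_perfect_fit(self):
        m = regression_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert m.rmse == 0.0 and m.r2 == 1.0

    def test_hand_worked_rmse(self):
        m = regression_metrics([0.0, 0.0], [1.0, -1.0])
        assert m.rmse == pytest.approx(1.0, abs=1e-12)

    def test_mean_prediction_gives_r2_zero(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        m = regression_metrics(y, np.full(4, y.mean()))
        assert m.r2 == pytest.approx(0.0, abs=1e-12)

    def test_constant_y_r2_flagged_undefined(self):
        m = regression_metrics([2.0, 2.0], [1.0, 3.0])
        assert m.rmse == pytest.approx(1.0) and np.isnan(m.r2)


class TestKFold:
    def test_leave_one_out_on_ten_rows(self, prepared):
        X = prepared["train_s"][FEATURES].iloc[:10]
        y = prepared["train_s"]["biogas_yield"].iloc[:10]
        per_fold, mean, sd = kfold_cv(RFSpec(n_trees=5), X, y, k=10)
        assert len(per_fold) == 10

    def test_folds_partition_rows(self):
        n, k = 23, 5
        bounds = np.linspace(0, n, k + 1).astype(int)
        pieces = [np.arange(bounds[i], bounds[i + 1]) for i in range(k)]
        assert sorted(np.concatenate(pieces)) == list(range(n))

    def test_noise_free_target_scores_better_than_noisy(self, prepared):
        X = prepared["train_s"][FEATURES].iloc[:600].reset_index(drop=True)
        clean_y = X["feed_solids"] * 2.0 + X["organic_matter"]
        noisy_y = clean_y + np.random.default_rng(0).normal(0, 0.5, len(X))
        _, mean_clean, _ = kfold_cv(RFSpec(n_trees=30), X, clean_y, k=5)
        _, mean_noisy, _ = kfold_cv(RFSpec(n_trees=30), X, noisy_y, k=5)
        assert mean_clean < mean_noisy


class TestRollingWindow:
    def test_window_count(self, prepared):
        X = prepared["train_s"][FEATURES].iloc[:30]
        y = prepared["train_s"]["biogas_yield"].iloc[:30]
        out = rolling_window_eval(RFSpec(n_trees=5), X, y, window=20, step=5)
        assert len(out) == 2

    def test_single_window_when_step_fills_remainder(self, prepared):
        X = prepared["train_s"][FEATURES].iloc[:30]
        y = prepared["train_s"]["biogas_yield"].iloc[:30]
        out = rolling_window_eval(RFSpec(n_trees=5), X, y, window=20, step=10)
        assert len(out) == 1

    def test_no_trend_on_stationary_series(self, prepared):
        """Window RMSE shows no monotone drift on stationary data (the
        slope's 95 % CI contains zero)."""
        from scipy import stats

        X = prepared["train_s"][FEATURES].iloc[:2100].reset_index(drop=True)
        y = prepared["train_s"]["biogas_yield"].iloc[:2100].reset_index(drop=True)
        out = rolling_window_eval(RFSpec(n_trees=30), X, y, window=600, step=150)
        res = stats.linregress(np.arange(len(out)), out.rmse)
        half = 1.96 * res.stderr
        assert res.slope - half <= 0 <= res.slope + half

    def test_oversized_window_rejected(self, prepared):
        with pytest.raises(ValueError):
            rolling_window_eval(
                RFSpec(), prepared["train_s"][FEATURES].iloc[:10],
                prepared["train_s"]["biogas_yield"].iloc[:10], window=8, step=5,
            )


class TestImportanceAndPermutation:
    def test_shares_sum_to_one(self, rf_model):
        assert rf_importance(rf_model).sum() == pytest.approx(1.0, abs=1e-9)

    def test_single_feature_share_is_one(self, prepared):
        X = prepared["train_s"][["feed_solids"]].iloc[:500]
        y = prepared["train_s"]["biogas_yield"].iloc[:500]
        model = fit_model(RFSpec(n_trees=20, mtry=1), X, y)
        assert rf_importance(model).iloc[0] == pytest.approx(1.0)

    def test_core_dominance_ordering(self, rf_model):
        imp = rf_importance(rf_model)
        assert imp["feed_solids"] > imp["organic_matter"] > imp["feed_rate"]

    def test_planted_noise_feature_ranks_last(self, prepared):
        """A pure-noise regressor earns less impurity importance than any
        causal core driver in >= 9/10 seeds."""
        wins = 0
        base = prepared["train_s"].iloc[:1500].reset_index(drop=True)
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = base[["feed_solids", "organic_matter", "feed_rate"]].copy()
            X["noise"] = rng.standard_normal(len(X))
            model = fit_model(RFSpec(n_trees=40, seed=seed), X, base["biogas_yield"])
            imp = rf_importance(model)
            wins += imp["noise"] < imp[["feed_solids", "organic_matter", "feed_rate"]].min()
        assert wins >= 9

    def test_non_rf_model_rejected(self, ann_model):
        with pytest.raises(TypeError):
            rf_importance(ann_model)

    def test_permuting_ignored_feature_changes_nothing(self, prepared):
        """A feature the model never saw contributes exactly zero."""
        X = prepared["train_s"][["feed_solids", "organic_matter"]].iloc[:800]
        y = prepared["train_s"]["biogas_yield"].iloc[:800]
        model = fit_model(RFSpec(n_trees=20, mtry=1), X[["feed_solids"]].assign(organic_matter=0.0), y)
        Xc = X.copy()
        Xc["organic_matter"] = 0.0
        d = permutation_delta_rmse(model, Xc, y, "organic_matter", n_perm=3, seed=0)
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_core_feature_beats_auxiliary(self, ann_model, prepared):
        X = prepared["test_s"][FEATURES]
        y = prepared["test_s"]["biogas_yield"]
        d_core = permutation_delta_rmse(ann_model, X, y, "feed_solids", seed=1, target="biogas_yield")
        d_aux = permutation_delta_rmse(ann_model, X, y, "dissolved_o2", seed=1, target="biogas_yield")
        assert d_core > d_aux

    def test_seeded_determinism(self, rf_model, prepared):
        X = prepared["test_s"][FEATURES]
        y = prepared["test_s"]["biogas_yield"]
        a = permutation_delta_rmse(rf_model, X, y, "feed_solids", n_perm=1, seed=7)
        b = permutation_delta_rmse(rf_model, X, y, "feed_solids", n_perm=1, seed=7)
        assert a == b
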