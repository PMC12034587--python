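"""Feature assembly, splitting, grid search, Youden thresholding, metrics,
and the repeated-evaluation protocol, each against small brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from plaqrisk import classify, schema, synthetic
from plaqrisk.classify import (binary_metrics, evaluate, fit_classifier,
                               oof_predictions, repeated_evaluation,
                               select_config, split_patients, youden_index,
                               youden_threshold)
from plaqrisk.synthetic import ClinicalGenConfig


def cohort(n_normal=50, n_abnormal=21, missing_rate=0.0, seed=0, **kw):
    return synthetic.generate_clinical_table(ClinicalGenConfig(
        n_normal=n_normal, n_abnormal=n_abnormal, missing_rate=missing_rate,
        seed=seed, **kw))


def with_risk(clinical, seed=1, shift=0.06):
    rng = np.random.default_rng(seed)
    labels = clinical[schema.LABEL_COLUMN].to_numpy()
    risk = pd.Series(
        np.clip(rng.normal(0.02 + shift * labels, 0.01), 0, None),
        index=clinical[schema.ID_COLUMN])
    return classify.assemble_features(clinical, risk)


class TestAssembleFeatures:
    def test_mean_imputation_of_missing_age(self):
        clinical = cohort(n_normal=2, n_abnormal=1)
        clinical.loc[0, "Age"] = 60.0
        clinical.loc[1, "Age"] = 70.0
        clinical.loc[2, "Age"] = np.nan
        out = classify.assemble_features(
            clinical, pd.Series(0.1, index=clinical[schema.ID_COLUMN]))
        assert out.loc[2, "Age"] == pytest.approx(65.0)

    def test_complete_table_only_gains_risk_column(self):
        clinical = cohort(n_normal=5, n_abnormal=3)
        risk = pd.Series(np.arange(8) / 10.0, index=clinical[schema.ID_COLUMN])
        out = classify.assemble_features(clinical, risk)
        features = [c for c in out.columns
                    if c not in (schema.ID_COLUMN, schema.LABEL_COLUMN)]
        assert len(features) == 19
        for col in schema.CLINICAL_COLUMNS:
            pd.testing.assert_series_equal(
                out.set_index(schema.ID_COLUMN)[col],
                clinical.set_index(schema.ID_COLUMN)[col], check_names=False)

    def test_patient_mismatch_rejected(self):
        clinical = cohort(n_normal=3, n_abnormal=2)
        short = pd.Series(0.1, index=clinical[schema.ID_COLUMN][:-1])
        with pytest.raises(ValueError):
            classify.assemble_features(clinical, short)


class TestSplitPatients:
    def test_71_patients_split_50_21(self):
        plan = split_patients(cohort(), ratio=0.7, seed=0)
        assert len(plan.train_ids) == 50 and len(plan.test_ids) == 21

    def test_disjoint_and_covering_for_any_seed(self):
        table = cohort()
        all_ids = set(table[schema.ID_COLUMN])
        for seed in range(25):
            plan = split_patients(table, seed=seed)
            assert not set(plan.train_ids) & set(plan.test_ids)
            assert set(plan.train_ids) | set(plan.test_ids) == all_ids

    def test_stratified_proportions_within_one_patient(self):
        table = cohort()
        labels = table.set_index(schema.ID_COLUMN)[schema.LABEL_COLUMN]
        for seed in range(100):
            plan = split_patients(table, seed=seed)
            n_pos = int(labels.loc[plan.train_ids].sum())
            assert abs(n_pos - 0.7 * 21) <= 1.0

    def test_too_few_patients_per_class_rejected(self):
        with pytest.raises(ValueError):
            split_patients(cohort(n_normal=5, n_abnormal=1))


class TestGridSearch:
    def test_mocked_losses_argmin(self):
        cfgs = [{"name": "A"}, {"name": "B"}, {"name": "C"}]
        losses = {"A": 0.60, "B": 0.45, "C": 0.52}
        best, _ = select_config(cfgs, lambda c: losses[c["name"]])
        assert best["name"] == "B"

    def test_separable_data_reaches_perfect_accuracy(self):
        table = with_risk(cohort(seed=3), shift=1.0)  # huge effect: separable
        plan = split_patients(table, seed=0)
        train = table[table[schema.ID_COLUMN].isin(plan.train_ids)]
        test = table[table[schema.ID_COLUMN].isin(plan.test_ids)]
        model, best_cfg, _ = fit_classifier(train, seed=0)
        oof = oof_predictions(train, "xgboost_like", best_cfg,
                              classify._default_features(train), seed=0)
        thr, _ = youden_threshold(oof, train[schema.LABEL_COLUMN])
        metrics = evaluate(model, test, thr)
        assert metrics["accuracy"] == 1.0

    def test_selected_config_matches_exhaustive_recomputation(self):
        table = with_risk(cohort(seed=4))
        plan = split_patients(table, seed=1)
        train = table[table[schema.ID_COLUMN].isin(plan.train_ids)]
        grid = {"max_depth": [2, 3], "learning_rate": [0.1, 0.5],
                "n_estimators": [30]}
        _, best_cfg, cv_losses = fit_classifier(train, grid=grid, seed=5)
        feats = classify._default_features(train)
        recomputed = {}
        for depth in grid["max_depth"]:
            for lr in grid["learning_rate"]:
                cfg = {"max_depth": depth, "learning_rate": lr, "n_estimators": 30}
                recomputed[str(cfg)] = classify.cv_log_loss(
                    train, "xgboost_like", cfg, feats, folds=5, seed=5)
        assert str(best_cfg) == min(recomputed, key=recomputed.get)
        for key, loss in recomputed.items():
            assert cv_losses[key] == pytest.approx(loss)

    @pytest.mark.parametrize("backend", ["xgboost_like", "lightgbm_like"])
    def test_both_backends_fit_and_predict(self, backend):
        table = with_risk(cohort(seed=6))
        plan = split_patients(table, seed=2)
        train = table[table[schema.ID_COLUMN].isin(plan.train_ids)]
        test = table[table[schema.ID_COLUMN].isin(plan.test_ids)]
        model, _, _ = fit_classifier(train, backend=backend,
                                     grid={"n_estimators": [30]}, seed=0)
        metrics = evaluate(model, test, 0.5)
        assert 0.0 <= metrics["roc_auc"] <= 1.0

    def test_single_class_training_rejected(self):
        table = with_risk(cohort(seed=7))
        normal_only = table[table[schema.LABEL_COLUMN] == 0]
        with pytest.raises(ValueError):
            fit_classifier(normal_only)


def brute_force_youden(scores, labels):
    scores = np.asarray(scores, float)
    uniq = np.unique(scores)
    cands = np.concatenate([[-np.inf], (uniq[:-1] + uniq[1:]) / 2, [np.inf]])
    best = max(((youden_index(scores, labels, t), t) for t in cands),
               key=lambda p: (p[0], p[1]))
    return best[1], best[0]


class TestYouden:
    def test_printed_example_matches_brute_force(self):
        scores, labels = [0.1, 0.3, 0.35, 0.8], [0, 0, 1, 1]
        thr, j = youden_threshold(scores, labels)
        bf_thr, bf_j = brute_force_youden(scores, labels)
        assert thr == pytest.approx(bf_thr) == pytest.approx(0.325)
        assert j == pytest.approx(bf_j) == pytest.approx(1.0)

    def test_perfectly_separated_scores(self):
        thr, j = youden_threshold([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert j == pytest.approx(1.0)
        assert thr == pytest.approx(0.5)

    def test_constant_scores_give_zero_j(self):
        _, j = youden_threshold([0.4, 0.4, 0.4, 0.4], [0, 1, 0, 1])
        assert j == pytest.approx(0.0)

    def test_random_instances_match_brute_force(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            n = int(rng.integers(4, 30))
            scores = np.round(rng.uniform(0, 1, n), 2)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            thr, j = youden_threshold(scores, labels)
            bf_thr, bf_j = brute_force_youden(scores, labels)
            assert j == pytest.approx(bf_j)
            assert thr == pytest.approx(bf_thr)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            youden_threshold([0.1, 0.2], [1, 1])


class TestMetrics:
    def test_confusion_matrix_arithmetic(self):
        # TP=5, FP=2, FN=1, TN=10 at threshold 0.5
        labels = [1] * 5 + [0] * 2 + [1] * 1 + [0] * 10
        probs = [0.9] * 5 + [0.9] * 2 + [0.1] * 1 + [0.1] * 10
        m = binary_metrics(np.array(labels), np.array(probs), 0.5)
        assert m["sensitivity"] == pytest.approx(5 / 6)
        assert m["specificity"] == pytest.approx(10 / 12)
        assert m["accuracy"] == pytest.approx(15 / 18)
        assert m["f1"] == pytest.approx(10 / 13)

    def test_perfect_predictions(self):
        m = binary_metrics(np.array([0, 0, 1, 1]), np.array([0.1, 0.2, 0.8, 0.9]), 0.5)
        assert all(m[k] == 1.0 for k in ("roc_auc", "accuracy", "sensitivity",
                                         "specificity", "f1"))

    def test_auc_equals_pairwise_concordance(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            n = int(rng.integers(6, 25))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            probs = np.round(rng.uniform(0, 1, n), 1)  # rounding forces ties
            m = binary_metrics(labels, probs, 0.5)
            pos, neg = probs[labels == 1], probs[labels == 0]
            pairs = [(0.5 if p == q else float(p > q)) for p in pos for q in neg]
            assert m["roc_auc"] == pytest.approx(np.mean(pairs))

    def test_single_class_auc_flagged_none(self):
        m = binary_metrics(np.array([1, 1]), np.array([0.5, 0.6]), 0.5)
        assert m["roc_auc"] is None


class TestRepeatedEvaluation:
    def test_reproducible_from_base_seed(self):
        table = with_risk(cohort(seed=10))
        a = repeated_evaluation(table, n_reps=5, base_seed=3)
        b = repeated_evaluation(table, n_reps=5, base_seed=3)
        pd.testing.assert_frame_equal(a.per_rep, b.per_rep)
        assert a.aggregates == b.aggregates

    def test_metric_bounds_and_lengths(self):
        table = with_risk(cohort(seed=11))
        rep = repeated_evaluation(table, n_reps=5, base_seed=0)
        assert len(rep.per_rep) == 5
        for m in ("roc_auc", "accuracy", "sensitivity", "specificity", "f1"):
            vals = rep.per_rep[m].dropna()
            assert ((vals >= 0) & (vals <= 1)).all()
            agg = rep.aggregates[m]
            assert agg["ci_lo"] <= agg["mean"] <= agg["ci_hi"]

    def test_ci_matches_direct_recomputation(self):
        table = with_risk(cohort(seed=12))
        rep = repeated_evaluation(table, n_reps=6, base_seed=1)
        vals = rep.per_rep["accuracy"].to_numpy()
        mean = vals.mean()
        half = 1.96 * vals.std(ddof=1) / np.sqrt(len(vals))
        agg = rep.aggregates["accuracy"]
        assert agg["mean"] == pytest.approx(mean)
        assert agg["ci_lo"] == pytest.approx(mean - half)
        assert agg["ci_hi"] == pytest.approx(mean + half)

    def test_too_few_repetitions_rejected(self):
        with pytest.raises(ValueError):
            repeated_evaluation(with_risk(cohort(seed=13)), n_reps=1)


def test_feature_importances_pass_through():
    table = with_risk(cohort(seed=14), shift=0.5)
    feats = classify._default_features(table)
    model, _, _ = fit_classifier(table, grid={"n_estimators": [30]}, seed=0)
    imp = classify.feature_importances(model, feats)
    assert set(imp.index) == set(feats)
    assert imp.iloc[0] >= imp.iloc[-1] >= 0
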