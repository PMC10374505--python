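"""Feature table assembly, confusion metrics, ROC/AUC, model evaluation and
Shapley attribution."""

import math

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from neurocoh.classify import (CLINICAL_FEATURES, GRAPH_FEATURES,
                               build_feature_table, confusion_metrics,
                               evaluate_models, rank_features_shap, roc_auc)
from neurocoh.graph import MEASURE_NAMES

import oracles

BANDS = ("delta", "theta", "alpha", "beta", "gamma")


def _fake_sources(rng, n_per_group=8):
    """Matched clinical table + long measure frame for table assembly."""
    clin_rows, meas_rows = [], []
    for group in ("ncse_like", "tme_like"):
        for i in range(n_per_group):
            sid = f"{group}_{i:03d}"
            clin_rows.append({
                "subject_id": sid, "group_label": group,
                "age": 60.0 + rng.standard_normal(),
                "sex_female": float(rng.random() < 0.5),
                "chronic_liver_disease": 0.0,
                "platelet": 200.0, "magnesium": 1.0,
                "blood_urea_nitrogen": 20.0, "creatinine": 1.0,
                "aspartate_transaminase": 30.0,
            })
            for band in BANDS:
                for name in MEASURE_NAMES:
                    meas_rows.append({
                        "subject_id": sid, "group_label": group, "band": band,
                        "measure": name, "value": rng.standard_normal(),
                    })
    clinical = pd.DataFrame(clin_rows).set_index("subject_id")
    return clinical, pd.DataFrame(meas_rows)


def _separable_table(rng, n_per_group=12, informative=6):
    """22-feature table with a strong group effect on a few features."""
    cols = list(CLINICAL_FEATURES + GRAPH_FEATURES)
    y = np.array([0] * n_per_group + [1] * n_per_group)
    X = rng.standard_normal((2 * n_per_group, len(cols)))
    X[y == 1, :informative] += 4.0
    return pd.DataFrame(X, columns=cols), pd.Series(y, name="label")


class TestBuildFeatureTable:
    def test_shape_and_columns(self, rng):
        clinical, measures = _fake_sources(rng, n_per_group=8)
        X, y = build_feature_table(clinical, measures)
        assert X.shape == (16, 22)
        assert tuple(X.columns) == CLINICAL_FEATURES + GRAPH_FEATURES
        assert y.sum() == 8  # tme_like is the positive class

    def test_subject_mismatch_listed(self, rng):
        clinical, measures = _fake_sources(rng, n_per_group=4)
        with pytest.raises(ValueError, match="ncse_like_003"):
            build_feature_table(clinical,
                               measures[measures.subject_id != "ncse_like_003"])


class TestConfusionMetrics:
    def test_perfect_classifier(self):
        m = confusion_metrics(5, 0, 5, 0)
        for name in ("ppv", "npv", "sensitivity", "specificity", "accuracy", "f1"):
            assert getattr(m, name) == 1.0

    def test_hand_worked_counts(self):
        m = confusion_metrics(3, 1, 4, 2)
        assert m.ppv == pytest.approx(0.75)
        assert m.sensitivity == pytest.approx(0.6)
        assert m.accuracy == pytest.approx(0.7)
        assert m.f1 == pytest.approx(2 * 0.75 * 0.6 / 1.35)
        assert m.npv == pytest.approx(4 / 6)
        assert m.specificity == pytest.approx(4 / 5)

    def test_zero_denominator_is_nan_for_that_metric_only(self):
        m = confusion_metrics(0, 0, 4, 2)
        assert math.isnan(m.ppv)
        assert m.npv == pytest.approx(4 / 6)
        assert m.accuracy == pytest.approx(4 / 6)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(-1, 0, 1, 0)


class TestRocAuc:
    def test_perfect_and_constant_scores(self):
        labels = np.array([0, 0, 1, 1])
        _, auc = roc_auc(np.array([0.1, 0.2, 0.8, 0.9]), labels)
        assert auc == 1.0
        _, auc = roc_auc(np.full(4, 0.5), labels)
        assert auc == 0.5

    def test_worked_example(self):
        _, auc = roc_auc(np.array([0.1, 0.4, 0.35, 0.8]),
                         np.array([0, 0, 1, 1]))
        assert auc == pytest.approx(0.75)

    def test_matches_pair_counting_and_sklearn(self, rng):
        for _ in range(10):
            scores = rng.standard_normal(30)
            scores[rng.random(30) < 0.3] = scores[0]  # inject ties
            labels = (rng.random(30) < 0.5).astype(int)
            if labels.sum() in (0, 30):
                continue
            _, auc = roc_auc(scores, labels)
            assert auc == pytest.approx(
                oracles.auc_pair_counting(scores, labels), abs=1e-12)
            assert auc == pytest.approx(roc_auc_score(labels, scores),
                                        abs=1e-12)

    def test_curve_monotone(self, rng):
        points, _ = roc_auc(rng.standard_normal(40),
                            (rng.random(40) < 0.5).astype(int))
        assert np.all(np.diff(points[:, 0]) >= 0)
        assert np.all(np.diff(points[:, 1]) >= 0)
        assert np.allclose(points[0], [0, 0]) and np.allclose(points[-1], [1, 1])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([0.1, 0.2]), np.array([1, 1]))


class TestEvaluateModels:
    def test_separable_data_and_determinism(self, rng):
        X, y = _separable_table(rng, n_per_group=12)
        report = evaluate_models(X, y, seed=5, n_iter=5)
        assert len(report.metrics) == 8
        assert report.metrics["auc"].max() > 0.95
        # every reported metric recomputes from its fold confusion counts
        from neurocoh.classify import confusion_metrics as cm
        for model, folds in report.fold_details.items():
            for metric in ("accuracy", "f1", "ppv", "npv",
                           "sensitivity", "specificity"):
                recomputed = np.mean([
                    getattr(cm(f.tp, f.fp, f.tn, f.fn), metric) for f in folds])
                assert report.metrics.loc[model, metric] == pytest.approx(
                    recomputed, abs=1e-12)
        again = evaluate_models(X, y, seed=5, n_iter=5)
        pd.testing.assert_frame_equal(report.metrics, again.metrics)

    def test_class_too_small_rejected(self, rng):
        X, y = _separable_table(rng, n_per_group=4)
        with pytest.raises(ValueError, match="per class"):
            evaluate_models(X, y, seed=0)


class TestShapleyAttribution:
    def _fit(self, X, y):
        return LogisticRegression(max_iter=500).fit(np.asarray(X), y)

    def test_planted_feature_ranks_first(self, rng):
        n = 80
        X = pd.DataFrame(rng.standard_normal((n, 22)),
                         columns=[f"f{i:02d}" for i in range(22)])
        y = (X["f07"] + 0.3 * rng.standard_normal(n) > 0).astype(int)
        model = self._fit(X, y)
        attr = rank_features_shap(model, X, n_permutations=20, seed=0)
        assert attr.ranking().iloc[0]["feature"] == "f07"

    def test_additivity(self, rng):
        X = pd.DataFrame(rng.standard_normal((30, 6)),
                         columns=[f"f{i}" for i in range(6)])
        y = (X["f0"] + X["f1"] > 0).astype(int)
        model = self._fit(X, y)
        attr = rank_features_shap(model, X, n_permutations=10, seed=1)
        scores = model.predict_proba(np.asarray(X))[:, 1]
        total = attr.base_value + attr.values.sum(axis=1)
        assert np.allclose(total, scores, atol=1e-3)

    def test_duplicated_feature_pair_outranks_noise(self, rng):
        n = 100
        X = pd.DataFrame(rng.standard_normal((n, 8)),
                         columns=[f"f{i}" for i in range(8)])
        X["dup"] = X["f0"] + 0.01 * rng.standard_normal(n)
        y = (X["f0"] > 0).astype(int)
        model = self._fit(X, y)
        attr = rank_features_shap(model, X, n_permutations=30, seed=2)
        ranking = attr.ranking().set_index("feature")["mean_abs_shap"]
        pair = ranking["f0"] + ranking["dup"]
        noise = ranking.drop(["f0", "dup"]).max()
        assert pair > noise

    def test_model_without_scores_rejected(self):
        with pytest.raises(TypeError):
            rank_features_shap(object(), pd.DataFrame({"a": [1.0, 2.0]}))
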