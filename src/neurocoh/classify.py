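"""Feature assembly, the eight-classifier comparison, and Shapley ranking.

The feature table couples eight clinical variables with the 14 graph
measures that discriminate the groups (degree in delta/alpha/beta/gamma,
strength in delta, global efficiency in delta/alpha, local efficiency,
clustering, transitivity and modularity in delta, assortativity in
alpha/beta/gamma) — 22 features per subject with a binary group label.

Eight traditional model families are tuned by seeded random search with
3-fold cross-validation on a stratified 75% training split, then scored by
stratified 3-fold cross-validation with the tuned hyperparameters; every
reported number (PPV, NPV, sensitivity, specificity, accuracy, F1, AUC) is
computed by this module's own confusion-count and ROC operations, averaged
over the folds. Feature influence for the best model is ranked by
permutation-sampling Shapley attribution (exactly additive per sample).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import loguniform, randint
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import (RandomizedSearchCV, StratifiedKFold,
                                     train_test_split)
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = ["GRAPH_FEATURES", "CLINICAL_FEATURES", "MODEL_FAMILIES",
           "build_feature_table", "ConfusionMetrics", "confusion_metrics",
           "roc_auc", "evaluate_models", "ClassifierReport",
           "ShapleyAttribution", "rank_features_shap"]

#: The 14 (measure, band) pairs used as graph features.
GRAPH_FEATURES: tuple[str, ...] = (
    "average_degree_delta", "average_degree_alpha", "average_degree_beta",
    "average_degree_gamma",
    "strength_delta",
    "global_efficiency_delta", "global_efficiency_alpha",
    "local_efficiency_delta",
    "clustering_coefficient_delta",
    "transitivity_delta",
    "modularity_delta",
    "assortativity_alpha", "assortativity_beta", "assortativity_gamma",
)

#: The eight clinical features.
CLINICAL_FEATURES: tuple[str, ...] = (
    "age", "sex_female", "chronic_liver_disease", "platelet", "magnesium",
    "blood_urea_nitrogen", "creatinine", "aspartate_transaminase",
)


def build_feature_table(
    clinical: pd.DataFrame,
    measures: pd.DataFrame,
    *,
    positive_group: str = "tme_like",
) -> tuple[pd.DataFrame, pd.Series]:
    """Assemble the 22-column feature table and binary label vector.

    ``clinical`` is indexed by subject_id with the eight clinical columns
    plus group_label; ``measures`` is the long-format frame of graph
    measures. The label is 1 for ``positive_group``. Subjects present in
    only one source raise an error listing the offenders. Features are
    returned raw; standardization (train statistics only) happens inside
    the model pipelines.
    """
    clinical = clinical.copy()
    if "subject_id" in clinical.columns:
        clinical = clinical.set_index("subject_id")
    wide = measures.assign(
        column=measures["measure"] + "_" + measures["band"]
    ).pivot_table(index="subject_id", columns="column", values="value")
    missing_cols = [c for c in GRAPH_FEATURES if c not in wide.columns]
    if missing_cols:
        raise ValueError(f"measures frame lacks feature columns: {missing_cols}")
    only_clin = sorted(set(clinical.index) - set(wide.index))
    only_meas = sorted(set(wide.index) - set(clinical.index))
    if only_clin or only_meas:
        raise ValueError(
            "subject ID mismatch between clinical table and measures: "
            f"clinical-only={only_clin}, measures-only={only_meas}"
        )
    wide = wide.loc[clinical.index, list(GRAPH_FEATURES)]
    X = pd.concat([clinical[list(CLINICAL_FEATURES)], wide], axis=1)
    y = (clinical["group_label"] == positive_group).astype(int)
    y.name = "label"
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        raise ValueError(f"missing values in feature columns {bad}")
    return X, y


@dataclass(frozen=True)
class ConfusionMetrics:
    """Confusion counts and the six derived fractions.

    Undefined fractions (zero denominator) are NaN for that metric only.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    ppv: float
    npv: float
    sensitivity: float
    specificity: float
    accuracy: float
    f1: float

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "ppv": self.ppv, "npv": self.npv, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "accuracy": self.accuracy,
            "f1": self.f1,
        }


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> ConfusionMetrics:
    """Evaluate the six confusion-matrix metrics from the four counts.

    PPV = TP/(TP+FP); NPV = TN/(TN+FN); sensitivity = TP/(TP+FN);
    specificity = TN/(TN+FP); accuracy = (TP+TN)/total;
    F1 = 2*PPV*sensitivity/(PPV+sensitivity).
    """
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    total = tp + fp + tn + fn
    if total == 0:
        raise ValueError("confusion counts are all zero")
    ppv = _ratio(tp, tp + fp)
    sens = _ratio(tp, tp + fn)
    f1 = (
        _ratio(2 * ppv * sens, ppv + sens)
        if not (math.isnan(ppv) or math.isnan(sens))
        else math.nan
    )
    return ConfusionMetrics(
        tp=tp, fp=fp, tn=tn, fn=fn,
        ppv=ppv, npv=_ratio(tn, tn + fn), sensitivity=sens,
        specificity=_ratio(tn, tn + fp), accuracy=(tp + tn) / total, f1=f1,
    )


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, float]:
    """Empirical ROC curve and trapezoidal AUC.

    Thresholds sweep the unique score values from high to low; ties are
    handled by grouping, which makes the trapezoidal area equal the
    Mann-Whitney U normalization (ties counted 1/2). Returns
    ``(points, auc)`` with ``points`` an (n, 2) array of (FPR, TPR)
    beginning at (0, 0) and ending at (1, 1).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute a ROC curve")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    # group tied scores
    boundary = np.flatnonzero(np.diff(s)) + 1
    tp_cum = np.cumsum(y)
    fp_cum = np.cumsum(1 - y)
    idx = np.append(boundary - 1, s.size - 1)
    tpr = np.concatenate([[0.0], tp_cum[idx] / n_pos])
    fpr = np.concatenate([[0.0], fp_cum[idx] / n_neg])
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def _model_families(seed: int) -> dict[str, tuple]:
    """The eight (estimator, search-space) pairs, seeded."""
    return {
        "gradient_boosting": (
            GradientBoostingClassifier(random_state=seed),
            {"clf__n_estimators": randint(50, 300),
             "clf__learning_rate": loguniform(0.01, 0.3),
             "clf__max_depth": randint(1, 5)},
        ),
        "logistic_regression": (
            LogisticRegression(max_iter=2000, random_state=seed),
            {"clf__C": loguniform(1e-2, 1e2)},
        ),
        "random_forest": (
            RandomForestClassifier(random_state=seed),
            {"clf__n_estimators": randint(50, 300),
             "clf__max_depth": randint(2, 9),
             "clf__max_features": ["sqrt", "log2", None]},
        ),
        "svm": (
            SVC(random_state=seed),  # ranking via decision_function
            {"clf__C": loguniform(1e-2, 1e2),
             "clf__gamma": loguniform(1e-3, 1e1)},
        ),
        "naive_bayes": (
            GaussianNB(),
            {"clf__var_smoothing": loguniform(1e-11, 1e-5)},
        ),
        "neural_network": (
            MLPClassifier(max_iter=1500, random_state=seed),
            {"clf__hidden_layer_sizes": [(8,), (16,), (32,), (16, 8)],
             "clf__alpha": loguniform(1e-5, 1e-1)},
        ),
        "knn": (
            KNeighborsClassifier(),
            {"clf__n_neighbors": randint(1, 16),
             "clf__weights": ["uniform", "distance"]},
        ),
        "decision_tree": (
            DecisionTreeClassifier(random_state=seed),
            {"clf__max_depth": randint(1, 9),
             "clf__min_samples_leaf": randint(1, 9)},
        ),
    }


MODEL_FAMILIES = tuple(_model_families(0).keys())


@dataclass
class ClassifierReport:
    """Per-model evaluation metrics plus the fitted best model."""

    metrics: pd.DataFrame            # one row per model family
    roc_curves: dict[str, np.ndarray]
    fold_details: dict[str, list[ConfusionMetrics]]
    best_model_name: str
    best_estimator: Pipeline
    seed: int
    feature_names: tuple[str, ...]

    def summary(self) -> str:
        cols = ["auc", "accuracy", "f1", "ppv", "npv", "sensitivity", "specificity"]
        tab = self.metrics[cols].map(lambda v: f"{v:.3f}")
        return (
            f"Classifier comparison (seed={self.seed}); metrics are means "
            "over 3 stratified CV folds\n"
            f"best model: {self.best_model_name}\n\n" + tab.to_string()
        )


def _scores(est, X: np.ndarray) -> np.ndarray:
    if hasattr(est, "predict_proba"):
        return est.predict_proba(X)[:, 1]
    return est.decision_function(X)


def evaluate_models(
    X: pd.DataFrame,
    y: pd.Series,
    seed: int = 0,
    *,
    models: tuple[str, ...] | None = None,
    n_iter: int = 20,
    train_fraction: float = 0.75,
    n_folds: int = 3,
) -> ClassifierReport:
    """Tune and evaluate the eight model families.

    For each family, hyperparameters are tuned by random search
    (``n_iter`` candidates) with ``n_folds``-fold stratified CV on a
    stratified ``train_fraction`` split; the tuned model is then scored by
    ``n_folds``-fold stratified CV over the full table. Reported metrics
    are fold averages computed from this module's own confusion-count and
    ROC operations; ROC curves pool the out-of-fold scores. Deterministic
    given ``seed``.
    """
    y_arr = np.asarray(y).astype(int)
    classes, counts = np.unique(y_arr, return_counts=True)
    if len(classes) != 2:
        raise ValueError("labels must be binary")
    if counts.min() < 2 * n_folds:
        raise ValueError(
            f"need at least {2 * n_folds} subjects per class for stratified "
            f"{n_folds}-fold tuning and evaluation"
        )
    X_arr = np.asarray(X, dtype=float)
    families = _model_families(seed)
    names = models or tuple(families)
    X_tr, _, y_tr, _ = train_test_split(
        X_arr, y_arr, train_size=train_fraction, stratify=y_arr,
        random_state=seed,
    )
    rows, curves, fold_details = [], {}, {}
    fitted: dict[str, Pipeline] = {}
    # smallest training partition seen during tuning bounds the kNN space
    tune_fold_size = int(len(y_tr) * (n_folds - 1) / n_folds)
    for k, name in enumerate(names):
        est, space = families[name]
        if name == "knn":
            space = dict(space)
            space["clf__n_neighbors"] = randint(
                1, max(2, min(16, tune_fold_size + 1)))
        pipe = Pipeline([("scale", StandardScaler()), ("clf", est)])
        search = RandomizedSearchCV(
            pipe, space, n_iter=n_iter, scoring="roc_auc",
            cv=StratifiedKFold(n_folds, shuffle=True, random_state=seed + k),
            random_state=seed + k, n_jobs=1, refit=False,
        )
        search.fit(X_tr, y_tr)
        tuned = pipe.set_params(**search.best_params_)

        cv = StratifiedKFold(n_folds, shuffle=True, random_state=seed + 1000 + k)
        per_fold, aucs = [], []
        oof_scores = np.empty_like(y_arr, dtype=float)
        for tr, te in cv.split(X_arr, y_arr):
            tuned.fit(X_arr[tr], y_arr[tr])
            pred = tuned.predict(X_arr[te])
            sc = _scores(tuned, X_arr[te])
            oof_scores[te] = sc
            tp = int(((pred == 1) & (y_arr[te] == 1)).sum())
            fp = int(((pred == 1) & (y_arr[te] == 0)).sum())
            tn = int(((pred == 0) & (y_arr[te] == 0)).sum())
            fn = int(((pred == 0) & (y_arr[te] == 1)).sum())
            per_fold.append(confusion_metrics(tp, fp, tn, fn))
            aucs.append(roc_auc(sc, y_arr[te])[1])
        fold_details[name] = per_fold
        curves[name], _ = roc_auc(oof_scores, y_arr)
        row = {"model": name, "auc": float(np.mean(aucs))}
        for metric in ("accuracy", "f1", "ppv", "npv", "sensitivity", "specificity"):
            row[metric] = float(np.mean([getattr(m, metric) for m in per_fold]))
        rows.append(row)
        fitted[name] = tuned.fit(X_arr, y_arr)
    metrics = pd.DataFrame(rows).set_index("model")
    best = metrics["auc"].idxmax()
    return ClassifierReport(
        metrics=metrics, roc_curves=curves, fold_details=fold_details,
        best_model_name=best, best_estimator=fitted[best], seed=seed,
        feature_names=tuple(X.columns) if hasattr(X, "columns") else
        tuple(f"x{i}" for i in range(X_arr.shape[1])),
    )


@dataclass
class ShapleyAttribution:
    """Per-sample Shapley attributions for a model's score function.

    ``values[s, j]`` is feature j's contribution to sample s's score
    relative to ``base_value`` (the score of the background point);
    attributions are exactly additive per sample:
    ``base_value + values[s].sum() == score(x_s)``.
    """

    values: np.ndarray
    base_value: float
    feature_names: tuple[str, ...]

    def ranking(self) -> pd.DataFrame:
        """Features ordered by mean |attribution|, with signed direction."""
        mean_abs = np.abs(self.values).mean(axis=0)
        mean_signed = self.values.mean(axis=0)
        # direction: correlation between feature attribution and its sign
        df = pd.DataFrame({
            "feature": self.feature_names,
            "mean_abs_shap": mean_abs,
            "mean_shap": mean_signed,
        }).sort_values("mean_abs_shap", ascending=False, kind="stable")
        df["rank"] = np.arange(1, len(df) + 1)
        return df.reset_index(drop=True)


def rank_features_shap(
    model,
    X: pd.DataFrame,
    *,
    n_permutations: int = 30,
    max_samples: int = 60,
    seed: int = 0,
) -> ShapleyAttribution:
    """Shapley attribution of the model score by permutation sampling.

    The score function is ``predict_proba[:, 1]`` (or the decision
    function). For each sampled feature ordering, features are switched one
    by one from the background value (the feature-wise mean of ``X``) to
    the explained sample's value, and the score increments are credited to
    the switched feature; averaging over orderings estimates the Shapley
    value. Each ordering's credits telescope, so additivity
    (base + sum of attributions = score) holds exactly.
    """
    if not (hasattr(model, "predict_proba") or hasattr(model, "decision_function")):
        raise TypeError("model must expose predict_proba or decision_function")
    X_arr = np.asarray(X, dtype=float)
    names = (tuple(X.columns) if hasattr(X, "columns")
             else tuple(f"x{i}" for i in range(X_arr.shape[1])))
    rng = np.random.default_rng(seed)
    if X_arr.shape[0] > max_samples:
        keep = rng.choice(X_arr.shape[0], size=max_samples, replace=False)
        X_arr = X_arr[keep]
    n_samples, n_features = X_arr.shape
    background = X_arr.mean(axis=0)
    base_value = float(_scores(model, background[None, :])[0])
    phi = np.zeros((n_samples, n_features))
    for _ in range(n_permutations):
        order = rng.permutation(n_features)
        # step grid: row k has the first k features (in this order) switched
        grid = np.tile(background, (n_features + 1, n_samples, 1))
        for k, j in enumerate(order):
            grid[k + 1:, :, j] = X_arr[:, j]
        flat = grid.reshape(-1, n_features)
        scores = _scores(model, flat).reshape(n_features + 1, n_samples)
        increments = np.diff(scores, axis=0)  # (n_features, n_samples)
        phi[:, order] += increments.T
    phi /= n_permutations
    return ShapleyAttribution(values=phi, base_value=base_value,
                              feature_names=names)
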