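"""Grade classification from cluster feature tables.

Supervised path: a two-level stacking ensemble. Four base learners (k-NN,
random forest, gradient boosting, XGBoost) produce out-of-fold class
probabilities on the training set (5 inner stratified folds); the stacked
probability matrix — width 4 x n_classes — trains a logistic-regression meta
learner. Evaluation follows a five-split protocol: the model trains once on a
stratified 80% split and is scored on five disjoint stratified splits of the
held-out 20% (a conventional cross-validation mode is also available).

Unsupervised path: PAM k-medoids (greedy BUILD then best-improvement SWAP)
on the standardized feature table with Euclidean dissimilarity, with an
optimal cluster-to-grade mapping for scoring against known labels.

Features are z-scored first (x - mean) / sigma with the population standard
deviation; scaler parameters are fitted on training data only.

Metrics are percentages: accuracy = trace/total; precision, recall and F1
are computed from TP/TN/FP/FN for binary problems and macro-averaged
one-vs-rest for multiclass.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_predict, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import LabelEncoder
from xgboost import XGBClassifier


class ClassificationError(ValueError):
    pass


# ---------------------------------------------------------------- scaling


@dataclass
class ScalerParams:
    """Per-feature mean and population standard deviation."""

    means: np.ndarray
    stds: np.ndarray


def standardize(feature_table, params: ScalerParams | None = None):
    """Z-score a feature table; returns ``(scaled, params)``.

    With ``params=None`` the mean and population std are fitted on the given
    table; otherwise the given parameters are applied (train-fitted params
    reused on test data). Zero-variance columns map to 0.
    """
    is_frame = isinstance(feature_table, pd.DataFrame)
    x = feature_table.to_numpy(dtype=float) if is_frame else np.asarray(feature_table, dtype=float)
    if x.ndim != 2 or len(x) == 0:
        raise ClassificationError("expected a non-empty 2-D feature table")
    if params is None:
        if len(x) < 2:
            raise ClassificationError("need at least 2 rows to fit a scaler")
        params = ScalerParams(means=x.mean(axis=0), stds=x.std(axis=0))
    safe = np.where(params.stds > 0, params.stds, 1.0)
    scaled = np.where(params.stds > 0, (x - params.means) / safe, 0.0)
    if is_frame:
        scaled = pd.DataFrame(scaled, index=feature_table.index, columns=feature_table.columns)
    return scaled, params


# ---------------------------------------------------------- stacking model


def _base_learners(seed: int, n_neighbors: int = 5) -> list[tuple[str, object]]:
    return [
        ("knn", KNeighborsClassifier(n_neighbors=n_neighbors)),
        ("rf", RandomForestClassifier(n_estimators=300, random_state=seed)),
        ("gbm", GradientBoostingClassifier(random_state=seed)),
        (
            "xgb",
            XGBClassifier(
                n_estimators=200,
                random_state=seed,
                verbosity=0,
                eval_metric="logloss",
            ),
        ),
    ]


@dataclass
class StackedEnsemble:
    """Fitted two-level stacking ensemble.

    ``meta_features_`` holds the out-of-fold probability matrix the meta
    learner was trained on (n_samples x 4*n_classes).
    """

    base_models: list[tuple[str, object]]
    meta_model: LogisticRegression
    label_encoder: LabelEncoder
    meta_features_: np.ndarray = field(repr=False, default=None)

    @property
    def classes_(self) -> np.ndarray:
        return self.label_encoder.classes_

    def _stack(self, x: np.ndarray) -> np.ndarray:
        return np.hstack([model.predict_proba(x) for _, model in self.base_models])

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        encoded = self.meta_model.predict(self._stack(x))
        return self.label_encoder.inverse_transform(encoded)

    def predict_proba(self, x) -> np.ndarray:
        return self.meta_model.predict_proba(self._stack(np.asarray(x, dtype=float)))


def fit_stacked_ensemble(train_table, train_labels, seed: int = 0, n_inner_folds: int = 5) -> StackedEnsemble:
    """Train the stacking ensemble on a (standardized) feature table.

    Meta features are out-of-fold predicted probabilities of the four base
    learners under ``n_inner_folds`` stratified inner folds, so the meta
    learner never sees a base prediction made on the data it was trained on.
    Deterministic for a fixed seed.
    """
    x = np.asarray(train_table, dtype=float)
    encoder = LabelEncoder().fit(np.asarray(train_labels))
    y = encoder.transform(np.asarray(train_labels))
    if len(encoder.classes_) < 2:
        raise ClassificationError("need at least 2 classes to fit a classifier")

    inner = StratifiedKFold(n_splits=n_inner_folds, shuffle=True, random_state=seed)
    bases = _base_learners(seed)
    oof = np.hstack(
        [cross_val_predict(model, x, y, cv=inner, method="predict_proba") for _, model in bases]
    )
    meta = LogisticRegression(max_iter=1000, random_state=seed).fit(oof, y)
    fitted = [(name, model.fit(x, y)) for name, model in bases]
    return StackedEnsemble(base_models=fitted, meta_model=meta, label_encoder=encoder, meta_features_=oof)


# ----------------------------------------------------------------- metrics


@dataclass
class Metrics:
    """Accuracy/precision/recall/F1 in percent.

    ``undefined`` names quantities whose denominator was zero (reported 0).
    """

    accuracy: float
    precision: float
    recall: float
    f1: float
    undefined: list[str] = field(default_factory=list)

    def as_row(self) -> dict[str, float]:
        return {
            "Accuracy": self.accuracy,
            "Precision": self.precision,
            "Recall": self.recall,
            "F1-Score": self.f1,
        }


def confusion_matrix(true_labels, predicted_labels, classes=None) -> pd.DataFrame:
    """Count matrix with rows = true class, columns = predicted class."""
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ClassificationError("label vectors have different lengths")
    if classes is None:
        classes = np.unique(np.concatenate([true_labels, predicted_labels]))
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    index = {c: i for i, c in enumerate(classes)}
    for t, p in zip(true_labels, predicted_labels):
        counts[index[t], index[p]] += 1
    return pd.DataFrame(counts, index=list(classes), columns=list(classes))


def _safe_ratio(num: float, den: float, name: str, undefined: list[str]) -> float:
    if den == 0:
        undefined.append(name)
        return 0.0
    return num / den


def compute_metrics(confusion) -> Metrics:
    """Accuracy, precision, recall and F1 (percent) from a confusion matrix.

    Binary matrices use TP/TN/FP/FN directly with the second class as
    positive; multiclass metrics are macro-averaged one-vs-rest. Quantities
    with a zero denominator are reported as 0 and flagged in ``undefined``.
    """
    cm = confusion.to_numpy() if isinstance(confusion, pd.DataFrame) else np.asarray(confusion)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1] or cm.size == 0:
        raise ClassificationError("confusion matrix must be square and non-empty")
    total = cm.sum()
    if total == 0:
        raise ClassificationError("empty confusion matrix")
    undefined: list[str] = []
    accuracy = 100.0 * np.trace(cm) / total

    precisions, recalls, f1s = [], [], []
    classes = range(cm.shape[0]) if cm.shape[0] > 2 else [1]  # binary: class 1 positive
    for c in classes:
        tp = cm[c, c]
        fp = cm[:, c].sum() - tp
        fn = cm[c, :].sum() - tp
        precision = 100.0 * _safe_ratio(tp, tp + fp, f"precision[{c}]", undefined)
        recall = 100.0 * _safe_ratio(tp, tp + fn, f"recall[{c}]", undefined)
        f1 = 2.0 * _safe_ratio(precision * recall, precision + recall, f"f1[{c}]", undefined)
        precisions.append(precision)
        recalls.append(recall)
        f1s.append(f1)
    return Metrics(
        accuracy=float(accuracy),
        precision=float(np.mean(precisions)),
        recall=float(np.mean(recalls)),
        f1=float(np.mean(f1s)),
        undefined=undefined,
    )


# ----------------------------------------------------------- evaluation


def five_fold_evaluate(
    model_factory,
    feature_table,
    labels,
    n_splits: int = 5,
    seed: int = 0,
    mode: str = "holdout_splits",
    test_size: float = 0.2,
) -> pd.DataFrame:
    """Per-split metrics table plus an "Average Split" row.

    mode="holdout_splits" (default): stratified train/test split
    (1 - test_size : test_size), the model trains once on the train part
    (standardized; scaler fitted on train only) and is scored on ``n_splits``
    disjoint stratified splits of the test part.

    mode="cv": conventional stratified n_splits-fold cross-validation over
    the whole table, refitting per fold.

    ``model_factory(seed)`` must return an object with fit(X, y) and
    predict(X).
    """
    x = feature_table.to_numpy(dtype=float) if isinstance(feature_table, pd.DataFrame) else np.asarray(feature_table, dtype=float)
    y = np.asarray(labels)
    _, class_counts = np.unique(y, return_counts=True)
    if class_counts.min() < n_splits:
        raise ClassificationError("every class needs at least n_splits members")
    if mode not in ("holdout_splits", "cv"):
        raise ClassificationError(f"unknown mode {mode!r}")

    rows = []
    if mode == "holdout_splits":
        x_tr, x_te, y_tr, y_te = train_test_split(
            x, y, test_size=test_size, stratify=y, random_state=seed
        )
        x_tr, params = standardize(x_tr)
        x_te, _ = standardize(x_te, params)
        model = model_factory(seed)
        model.fit(x_tr, y_tr)
        splitter = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        for _, test_idx in splitter.split(x_te, y_te):
            cm = confusion_matrix(y_te[test_idx], model.predict(x_te[test_idx]), np.unique(y))
            rows.append(compute_metrics(cm).as_row())
    else:
        splitter = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        for train_idx, test_idx in splitter.split(x, y):
            x_tr, params = standardize(x[train_idx])
            x_te, _ = standardize(x[test_idx], params)
            model = model_factory(seed)
            model.fit(x_tr, y[train_idx])
            cm = confusion_matrix(y[test_idx], model.predict(x_te), np.unique(y))
            rows.append(compute_metrics(cm).as_row())

    table = pd.DataFrame(rows, index=[f"Split {i + 1}" for i in range(len(rows))])
    table.loc["Average Split"] = table.mean()
    return table


# ----------------------------------------------------------- k-medoids


def kmedoids_classify(table, k: int, seed: int = 0, max_iter: int = 200) -> np.ndarray:
    """PAM k-medoids clustering with Euclidean dissimilarity.

    Greedy BUILD initialization followed by best-improvement SWAP passes
    until no swap lowers the total dissimilarity. Medoids are data rows.
    The procedure is deterministic (the seed parameter is accepted for API
    symmetry; BUILD+SWAP has no random step). Returns cluster indices 0..k-1.
    """
    x = np.asarray(table, dtype=float)
    n = len(x)
    if not 1 <= k <= n:
        raise ClassificationError(f"need 1 <= k <= n rows, got k={k}, n={n}")
    dist = cdist(x, x)

    # BUILD: first medoid minimizes total distance; then greedy additions
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    while len(medoids) < k:
        current = dist[:, medoids].min(axis=1)
        gains = np.maximum(current[None, :] - dist, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))

    def cost(meds: list[int]) -> float:
        return float(dist[:, meds].min(axis=1).sum())

    best_cost = cost(medoids)
    for _ in range(max_iter):
        improved = False
        best_swap = None
        for mi, m in enumerate(medoids):
            for h in range(n):
                if h in medoids:
                    continue
                trial = medoids.copy()
                trial[mi] = h
                c = cost(trial)
                if c < best_cost - 1e-12:
                    best_cost, best_swap = c, (mi, h)
                    improved = True
        if not improved:
            break
        medoids[best_swap[0]] = best_swap[1]
    return np.argmin(dist[:, medoids], axis=1)


def map_clusters_to_labels(assignments, true_labels) -> dict:
    """Optimal one-to-one cluster-to-label mapping (maximizes accuracy).

    Exhaustive over label permutations; intended for k <= ~5 clusters.
    """
    assignments = np.asarray(assignments)
    true_labels = np.asarray(true_labels)
    if len(assignments) != len(true_labels):
        raise ClassificationError("assignments and labels have different lengths")
    clusters = np.unique(assignments)
    label_values = np.unique(true_labels)
    if len(clusters) > len(label_values):
        raise ClassificationError("more clusters than label values")
    best_mapping, best_hits = None, -1
    for perm in itertools.permutations(label_values, len(clusters)):
        mapping = dict(zip(clusters, perm))
        hits = int(np.sum([mapping[a] == t for a, t in zip(assignments, true_labels)]))
        if hits > best_hits:
            best_hits, best_mapping = hits, mapping
    return best_mapping


def kmedoids_evaluate(
    feature_table,
    labels,
    k: int | None = None,
    n_splits: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Five-split unsupervised evaluation shaped like the supervised table.

    The whole table is divided into ``n_splits`` disjoint stratified splits;
    k-medoids clusters each split separately (k defaults to the number of
    label values), clusters are optimally mapped to grades, and the metrics
    of each split are reported with an "Average Split" row.
    """
    x = feature_table.to_numpy(dtype=float) if isinstance(feature_table, pd.DataFrame) else np.asarray(feature_table, dtype=float)
    y = np.asarray(labels)
    k = k if k is not None else len(np.unique(y))
    splitter = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    rows = []
    for _, idx in splitter.split(x, y):
        scaled, _ = standardize(x[idx])
        assign = kmedoids_classify(scaled, k=k, seed=seed)
        mapping = map_clusters_to_labels(assign, y[idx])
        predicted = np.array([mapping[a] for a in assign])
        cm = confusion_matrix(y[idx], predicted, np.unique(y))
        rows.append(compute_metrics(cm).as_row())
    table = pd.DataFrame(rows, index=[f"Split {i + 1}" for i in range(len(rows))])
    table.loc["Average Split"] = table.mean()
    return table
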