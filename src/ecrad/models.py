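"""Response classifiers: wrapper selection, SVM/ANN, CV, McNemar, hold-out.

Two classifier families are supported, each behind the same interface:

* SVM — soft-margin RBF kernel (C = 1, gamma = 1/n_features), scores from
  the decision function.
* ANN — single-hidden-layer perceptron with logistic activation and
  ``ceil((n_features + 2) / 2)`` hidden units, seeded initialization and a
  bounded LBFGS iteration budget; scores are class-1 probabilities.

Features are z-scored with training-set statistics inside each fit (a
scaler is part of every model pipeline), so cross-validation folds and the
hold-out set never leak test statistics into training.

Feature selection is greedy backward elimination scored by stratified
10-fold CV accuracy of the target classifier: starting from all candidate
features, the feature whose removal yields the best CV accuracy is dropped
(ties drop the later-manifest feature), and the best subset seen anywhere
along the path is returned (ties prefer the smaller subset).  Selection is
run once on the training split, outside the CV loop used to report
metrics — the same sequence as the analysis it mirrors; the optimistic
bias this can introduce is a property of that design, not corrected here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

from .univariate import delong_variance


@dataclass
class ModelConfig:
    algorithm: str = "svm"  # "svm" | "ann"
    n_folds: int = 10
    seed: int = 0
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.algorithm not in ("svm", "ann"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


@dataclass
class CvMetrics:
    """Support-weighted classification metrics from one confusion matrix."""

    tp_rate: float
    fp_rate: float
    precision: float
    accuracy: float
    f_measure: float
    mcc: float
    auc: float

    def as_dict(self) -> dict[str, float]:
        return {
            "tp_rate": self.tp_rate, "fp_rate": self.fp_rate,
            "precision": self.precision, "accuracy": self.accuracy,
            "f_measure": self.f_measure, "mcc": self.mcc, "auc": self.auc,
        }


def build_model(config: ModelConfig, n_features: int) -> Pipeline:
    """Fresh (unfitted) scaler + classifier pipeline."""
    hp = config.hyperparameters
    if config.algorithm == "svm":
        clf = SVC(kernel=hp.get("kernel", "rbf"), C=hp.get("C", 1.0),
                  gamma=hp.get("gamma", 1.0 / max(n_features, 1)))
    else:
        hidden = hp.get("hidden_units", math.ceil((n_features + 2) / 2))
        clf = MLPClassifier(hidden_layer_sizes=(hidden,),
                            activation="logistic", solver="lbfgs",
                            max_iter=hp.get("max_iter", 400),
                            random_state=config.seed)
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def train_classifier(table: pd.DataFrame, labels: np.ndarray,
                     config: ModelConfig) -> Pipeline:
    """Fit one classifier on a training table (binary labels, 0/1)."""
    labels = np.asarray(labels).astype(int)
    if min(np.bincount(labels, minlength=2)) < 2:
        raise ValueError("need at least 2 cases per class")
    model = build_model(config, table.shape[1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(table.values, labels)
    return model


def decision_scores(model: Pipeline, X: np.ndarray) -> np.ndarray:
    """Continuous score for class 1, for ROC/AUC computation."""
    clf = model.named_steps["clf"]
    if hasattr(clf, "decision_function"):
        return model.decision_function(X)
    return model.predict_proba(X)[:, 1]


def mcc(tp: int, tn: int, fp: int, fn: int) -> float:
    """Matthews correlation coefficient; any zero denominator factor -> 0."""
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / math.sqrt(denom))


def confusion_metrics(y_true: np.ndarray, y_pred: np.ndarray,
                      scores: np.ndarray | None = None) -> CvMetrics:
    """Support-weighted metrics from pooled predictions.

    Per-class TP-rate (recall), FP-rate, precision and F-measure are
    averaged with class-support weights; accuracy is the pooled fraction
    correct; MCC comes from the pooled 2x2 confusion matrix; AUC from the
    continuous scores (0.5 if scores are degenerate or absent).
    """
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    n = len(y_true)
    support = {1: tp + fn, 0: tn + fp}

    def per_class(cls):
        if cls == 1:
            tpr = tp / support[1] if support[1] else 0.0
            fpr = fp / support[0] if support[0] else 0.0
            prec = tp / (tp + fp) if (tp + fp) else 0.0
        else:
            tpr = tn / support[0] if support[0] else 0.0
            fpr = fn / support[1] if support[1] else 0.0
            prec = tn / (tn + fn) if (tn + fn) else 0.0
        f = 2 * prec * tpr / (prec + tpr) if (prec + tpr) else 0.0
        return tpr, fpr, prec, f

    w = np.array([support[0], support[1]], dtype=float) / n
    rows = [per_class(0), per_class(1)]
    tpr_w, fpr_w, prec_w, f_w = (
        float(w @ np.array([r[i] for r in rows])) for i in range(4))
    if scores is not None and len(np.unique(y_true)) == 2:
        auc, _ = delong_variance(scores, y_true.astype(bool))
    else:
        auc = 0.5
    return CvMetrics(tp_rate=tpr_w, fp_rate=fpr_w, precision=prec_w,
                     accuracy=(tp + tn) / n, f_measure=f_w,
                     mcc=mcc(tp, tn, fp, fn), auc=float(auc))


def cross_validate(table: pd.DataFrame, labels: np.ndarray,
                   config: ModelConfig) -> tuple[CvMetrics, pd.DataFrame]:
    """Stratified k-fold CV; metrics from pooled out-of-fold predictions.

    Returns the metrics plus a per-case frame of out-of-fold predictions
    and scores (used by the McNemar comparison).
    """
    labels = np.asarray(labels).astype(int)
    X = table.values
    skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True,
                          random_state=config.seed)
    preds = np.empty(len(labels), dtype=int)
    scores = np.empty(len(labels), dtype=float)
    folds = np.empty(len(labels), dtype=int)
    for fold, (tr, te) in enumerate(skf.split(X, labels)):
        model = train_classifier(table.iloc[tr], labels[tr], config)
        preds[te] = model.predict(X[te])
        scores[te] = decision_scores(model, X[te])
        folds[te] = fold
    oof = pd.DataFrame({"y_true": labels, "y_pred": preds,
                        "score": scores, "fold": folds}, index=table.index)
    return confusion_metrics(labels, preds, scores), oof


def wrapper_select(table: pd.DataFrame, labels: np.ndarray,
                   config: ModelConfig) -> list[str]:
    """Backward recursive elimination maximizing 10-fold CV accuracy.

    Returns the selected feature names in the input column order.
    """
    labels = np.asarray(labels).astype(int)
    features = list(table.columns)

    def cv_accuracy(cols: list[str]) -> float:
        metrics, _ = cross_validate(table[cols], labels, config)
        return metrics.accuracy

    current = list(features)
    best_subset = list(current)
    best_acc = cv_accuracy(current)
    while len(current) > 1:
        # score removal of each remaining feature; ties drop the later one
        accs = [cv_accuracy([f for f in current if f != cand])
                for cand in current]
        drop_idx = int(np.argmax([
            a + 1e-12 * i for i, a in enumerate(accs)]))  # later wins ties
        step_acc = accs[drop_idx]
        current.pop(drop_idx)
        # smaller subset preferred on ties
        if step_acc >= best_acc - 1e-12:
            if step_acc > best_acc + 1e-12 or len(current) < len(best_subset):
                best_subset = list(current)
            best_acc = max(best_acc, step_acc)
    return [f for f in features if f in best_subset]


def mcnemar_test(preds_a: np.ndarray, preds_b: np.ndarray,
                 labels: np.ndarray) -> tuple[int, int, float]:
    """McNemar comparison of two prediction vectors on the same cases.

    Returns (b, c, p): b = cases A got right and B wrong, c = the reverse.
    Exact binomial p for b + c < 25, chi-square with continuity correction
    otherwise; b = c = 0 gives p = 1.
    """
    preds_a = np.asarray(preds_a)
    preds_b = np.asarray(preds_b)
    labels = np.asarray(labels)
    if not (preds_a.shape == preds_b.shape == labels.shape):
        raise ValueError("prediction vectors and labels must share one case set")
    a_ok = preds_a == labels
    b_ok = preds_b == labels
    b = int((a_ok & ~b_ok).sum())
    c = int((~a_ok & b_ok).sum())
    if b + c == 0:
        return b, c, 1.0
    table = [[int((a_ok & b_ok).sum()), b], [c, int((~a_ok & ~b_ok).sum())]]
    exact = (b + c) < 25
    res = sm_mcnemar(table, exact=exact, correction=True)
    return b, c, float(res.pvalue)


def evaluate_holdout(model: Pipeline, test_table: pd.DataFrame,
                     labels: np.ndarray) -> tuple[CvMetrics, np.ndarray]:
    """Metrics and 2x2 confusion matrix on an untouched test split."""
    if test_table.isna().any().any():
        raise ValueError("test table contains missing feature values")
    labels = np.asarray(labels).astype(int)
    preds = model.predict(test_table.values)
    scores = decision_scores(model, test_table.values)
    metrics = confusion_metrics(labels, preds, scores)
    cm = np.array([
        [int(((labels == 0) & (preds == 0)).sum()),
         int(((labels == 0) & (preds == 1)).sum())],
        [int(((labels == 1) & (preds == 0)).sum()),
         int(((labels == 1) & (preds == 1)).sum())],
    ])
    return metrics, cm


def stratified_split(labels: pd.Series, n_test: int, seed: int,
                     n_test_positive: int | None = None
                     ) -> tuple[list[str], list[str]]:
    """Random stratified train/test split by case id.

    ``n_test_positive`` pins the number of positive-class (nonresponder)
    cases in the test split; otherwise the class ratio is preserved.
    """
    rng = np.random.default_rng(seed)
    pos_ids = list(labels.index[labels])
    neg_ids = list(labels.index[~labels])
    if n_test_positive is None:
        n_test_positive = round(n_test * len(pos_ids) / len(labels))
    n_test_positive = min(max(n_test_positive, 1), n_test - 1)
    test = (list(rng.choice(pos_ids, n_test_positive, replace=False))
            + list(rng.choice(neg_ids, n_test - n_test_positive, replace=False)))
    train = [i for i in labels.index if i not in set(test)]
    test = [i for i in labels.index if i in set(test)]
    if not (set(train) | set(test)) == set(labels.index):
        raise RuntimeError("split does not cover the cohort")
    return train, test
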