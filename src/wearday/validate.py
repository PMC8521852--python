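"""Validating user clusters with a supervised classifier ensemble.

If the user groups are real, a classifier should recover them from an
independent representation of the same users.  Each user is summarized by
their *average day* (matrix D: mean minutes/hour over retained days) and
three classifiers — multinomial logistic regression (L2, newton-cg),
gradient-boosted trees, and a fully connected 18-128-64-32-4 ReLU network —
predict the four-class group label (A/B/C/noise) on a stratified 80/20
split.  The ensemble takes the label at least two classifiers agree on,
falling back to the best individual classifier when all three disagree.
Quality is reported as accuracy, per-class / micro / macro one-vs-rest
ROC-AUC, and the tree model's gain-based feature importances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler, label_binarize
from xgboost import XGBClassifier

from .preprocess import DayUseMatrix
from .simulate import HOURS

CLASSIFIERS = ("multinomial_regression", "gradient_boosted_trees", "feedforward_network")


@dataclass
class AverageDayMatrix:
    """Matrix D: one row per user, the mean hourly use over retained days."""

    values: np.ndarray  # (n_users, 18), minutes in [0, 60]
    user_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(HOURS):
            raise ValueError(f"D must have {len(HOURS)} columns")


def build_average_day(
    A: DayUseMatrix, keep_mask: np.ndarray | None = None
) -> AverageDayMatrix:
    """Per-user column means of A over the retained (non-trimmed) days."""
    mask = np.ones(A.n_days, dtype=bool) if keep_mask is None else np.asarray(keep_mask, bool)
    df = pd.DataFrame(A.values[mask])
    df.insert(0, "user_id", A.user_ids[mask])
    means = df.groupby("user_id").mean().sort_index()
    return AverageDayMatrix(means.to_numpy(), means.index.to_numpy())


def split_train_test(
    D: AverageDayMatrix | np.ndarray,
    labels: np.ndarray,
    train_frac: float = 0.8,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stratified train/test split; disjoint and exhaustive."""
    X = D.values if isinstance(D, AverageDayMatrix) else np.asarray(D, dtype=float)
    y = np.asarray(labels)
    return train_test_split(
        X, y, train_size=train_frac, stratify=y, random_state=seed
    )  # X_train, X_test, y_train, y_test


class _XGBWrapper:
    """XGBClassifier with string-label encoding and sklearn-like surface."""

    def __init__(self, seed: int):
        self.model = XGBClassifier(
            n_estimators=100,
            max_depth=5,
            gamma=0,
            reg_alpha=0.1,
            importance_type="gain",
            random_state=seed,
            n_jobs=1,
        )
        self.classes_: np.ndarray | None = None

    def fit(self, X, y):
        self.classes_ = np.unique(y)
        codes = np.searchsorted(self.classes_, y)
        self.model.fit(X, codes)
        return self

    def predict(self, X):
        return self.classes_[self.model.predict(X)]

    def predict_proba(self, X):
        return self.model.predict_proba(X)

    @property
    def feature_importances_(self):
        return self.model.feature_importances_


def train_classifier(kind: str, X_train: np.ndarray, y_train: np.ndarray, seed: int = 0):
    """Fit one of the three ensemble members with the fixed hyperparameters.

    Inputs to the regression and the network are standardized (fit on the
    training split); the trees see raw minutes.
    """
    if len(np.unique(y_train)) < 2:
        raise ValueError("training labels contain a single class")
    if kind == "multinomial_regression":
        return make_pipeline(
            StandardScaler(),
            # L2 penalty is the default regularizer
            LogisticRegression(solver="newton-cg", max_iter=1000),
        ).fit(X_train, y_train)
    if kind == "gradient_boosted_trees":
        return _XGBWrapper(seed).fit(X_train, y_train)
    if kind == "feedforward_network":
        net = make_pipeline(
            StandardScaler(),
            MLPClassifier(
                hidden_layer_sizes=(128, 64, 32),
                activation="relu",
                solver="adam",
                max_iter=25,
                random_state=seed,
            ),
        )
        with warnings.catch_warnings():
            # 25 epochs is the training budget, not a convergence criterion
            warnings.simplefilter("ignore")
            return net.fit(X_train, y_train)
    raise ValueError(f"unknown classifier kind {kind!r}")


def ensemble_predict(predictions: dict[str, np.ndarray], best_kind: str) -> np.ndarray:
    """Majority vote over three aligned prediction vectors.

    A label two or more classifiers agree on wins; if all three disagree,
    the best-performing individual classifier decides.
    """
    kinds = list(predictions)
    if len(kinds) != 3:
        raise ValueError("ensemble_predict expects exactly 3 prediction vectors")
    P = np.vstack([np.asarray(predictions[k]) for k in kinds])
    best_row = kinds.index(best_kind)
    out = []
    for j in range(P.shape[1]):
        votes = P[:, j]
        labs, counts = np.unique(votes, return_counts=True)
        out.append(labs[np.argmax(counts)] if counts.max() >= 2 else votes[best_row])
    return np.asarray(out)


@dataclass
class ClassifierEval:
    accuracy: float  # percent
    auc_micro: float
    auc_macro: float
    auc_per_class: dict


def evaluate_classification(
    y_true: np.ndarray, y_pred: np.ndarray, scores: np.ndarray, classes: np.ndarray
) -> ClassifierEval:
    """Accuracy (%) plus one-vs-rest ROC-AUCs from class-probability scores.

    Per-class AUCs binarize each class against the rest; micro pools the
    binarized decisions, macro is their unweighted mean.
    """
    y_true = np.asarray(y_true)
    acc = float((y_true == np.asarray(y_pred)).mean() * 100.0)
    Y = label_binarize(y_true, classes=classes)
    if Y.shape[1] == 1:  # two classes: binarize gives one column
        Y = np.column_stack([1 - Y, Y])
    per_class = {}
    for j, c in enumerate(classes):
        per_class[c] = float(roc_auc_score(Y[:, j], scores[:, j]))
    micro = float(roc_auc_score(Y.ravel(), scores.ravel()))
    macro = float(np.mean(list(per_class.values())))
    return ClassifierEval(acc, micro, macro, per_class)


def report_importance(tree_model: _XGBWrapper) -> np.ndarray:
    """Normalized gain-based importances of the 18 hourly features."""
    imp = np.asarray(tree_model.feature_importances_, dtype=float)
    total = imp.sum()
    return imp / total if total > 0 else imp


@dataclass
class EnsembleReport:
    """Per-classifier and ensemble performance on the held-out test split."""

    classes: np.ndarray
    per_classifier: dict[str, ClassifierEval]
    best_kind: str
    ensemble: ClassifierEval
    importances: np.ndarray
    n_train: int = 0
    n_test: int = 0
    extras: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            "Cluster validation: 3-classifier majority-vote ensemble",
            "-" * 58,
            f"train/test: {self.n_train}/{self.n_test} users, "
            f"classes: {', '.join(map(str, self.classes))}",
            f"{'classifier':28s} {'acc %':>7s} {'AUC(micro)':>11s}",
        ]
        for k, ev in self.per_classifier.items():
            star = " (best)" if k == self.best_kind else ""
            lines.append(f"{k:28s} {ev.accuracy:7.2f} {ev.auc_micro:11.3f}{star}")
        lines.append(
            f"{'ensemble':28s} {self.ensemble.accuracy:7.2f} {self.ensemble.auc_micro:11.3f}"
        )
        lines.append(f"ensemble macro AUC: {self.ensemble.auc_macro:.3f}")
        top = np.argsort(self.importances)[::-1][:2]
        lines.append(
            "top tree importances: "
            + ", ".join(f"h{HOURS[i]}={self.importances[i]:.3f}" for i in top)
        )
        return "\n".join(lines)

    def as_dict(self) -> dict:
        return {
            "classes": [str(c) for c in self.classes],
            "per_classifier": {
                k: {
                    "accuracy": ev.accuracy,
                    "auc_micro": ev.auc_micro,
                    "auc_macro": ev.auc_macro,
                    "auc_per_class": {str(c): v for c, v in ev.auc_per_class.items()},
                }
                for k, ev in self.per_classifier.items()
            },
            "best_classifier": self.best_kind,
            "ensemble": {
                "accuracy": self.ensemble.accuracy,
                "auc_micro": self.ensemble.auc_micro,
                "auc_macro": self.ensemble.auc_macro,
                "auc_per_class": {str(c): v for c, v in self.ensemble.auc_per_class.items()},
            },
            "feature_importances": {f"h{h}": float(v) for h, v in zip(HOURS, self.importances)},
            "n_train": self.n_train,
            "n_test": self.n_test,
        }


class ClusterValidator:
    """Ensemble validation model: predicts user-group labels from D."""

    def __init__(
        self,
        D: AverageDayMatrix,
        labels: np.ndarray,
        train_frac: float = 0.8,
        seed: int = 0,
    ):
        if len(labels) != D.values.shape[0]:
            raise ValueError("labels must align with rows of D")
        self.D = D
        self.labels = np.asarray(labels)
        self.train_frac = train_frac
        self.seed = seed

    def fit(self) -> EnsembleReport:
        X_train, X_test, y_train, y_test = split_train_test(
            self.D, self.labels, self.train_frac, self.seed
        )
        classes = np.unique(self.labels)
        models, preds, probs, evals = {}, {}, {}, {}
        for kind in CLASSIFIERS:
            models[kind] = train_classifier(kind, X_train, y_train, seed=self.seed)
            preds[kind] = models[kind].predict(X_test)
            # align probability columns to the global class order
            p = models[kind].predict_proba(X_test)
            order = np.searchsorted(classes, models[kind].classes_)
            aligned = np.zeros((len(X_test), len(classes)))
            aligned[:, order] = p
            probs[kind] = aligned
            evals[kind] = evaluate_classification(y_test, preds[kind], aligned, classes)

        best = max(CLASSIFIERS, key=lambda k: evals[k].accuracy)
        ens_pred = ensemble_predict(preds, best)
        ens_scores = np.mean([probs[k] for k in CLASSIFIERS], axis=0)
        ens_eval = evaluate_classification(y_test, ens_pred, ens_scores, classes)
        importances = report_importance(models["gradient_boosted_trees"])
        return EnsembleReport(
            classes=classes,
            per_classifier=evals,
            best_kind=best,
            ensemble=ens_eval,
            importances=importances,
            n_train=len(X_train),
            n_test=len(X_test),
        )
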