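"""Classifier training, evaluation metrics, and image-level cross-validation.

Five classifier families are compared: random forest, support-vector machine,
LogitBoost-style additive logistic regression on depth-1 stumps, an
entropy-based pruned decision tree (C4.5 analogue), and naive Bayes with
Gaussian conditionals (the minimal Bayesian network). They are analogues of
the classical Weka implementations, not bit-compatible replicas; each is
deterministic given its seed.

Metrics follow the one-vs-rest convention for multiclass problems:

    PPV = TP / (TP + FP)        (precision, Eq.-style per class)
    TPR = TP / (TP + FN)        (recall)
    F1  = 2·PPV·TPR / (PPV + TPR) = 2TP / (2TP + FP + FN)
    ACC = correct / N           (multiclass hit rate)

with a 0 convention for empty denominators. Cross-validation is grouped at
the image level: every fold holds out all superpixels of exactly one image,
so with 10 images each model trains on 9 — superpixels of one image never
appear on both sides of a split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .dataio import CLASS_COLUMN, KEY_COLUMNS

CLASSIFIER_FAMILIES = ("random_forest", "svm", "logit_boost", "c45_tree", "bayes_net")

#: fixed tie-break order of enhancements when grid rows are otherwise equal
ENHANCEMENT_ORDER = ("equalize", "match", "normalize", "none")


@dataclass(frozen=True)
class ClassifierSpec:
    family: str = "random_forest"
    seed: int = 0
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.family not in CLASSIFIER_FAMILIES:
            raise ValueError(
                f"unknown classifier family {self.family!r}; choose from {CLASSIFIER_FAMILIES}"
            )


def _build_estimator(spec: ClassifierSpec):
    hp = spec.hyperparameters
    if spec.family == "random_forest":
        return RandomForestClassifier(
            n_estimators=hp.get("n_estimators", 100),
            max_features=hp.get("max_features", "sqrt"),
            random_state=spec.seed, n_jobs=1,
        )
    if spec.family == "svm":
        # feature standardization is fitted inside the pipeline, hence on the
        # training fold only
        return Pipeline([
            ("scale", StandardScaler()),
            ("svc", SVC(kernel=hp.get("kernel", "rbf"), C=hp.get("C", 1.0),
                        gamma=hp.get("gamma", "scale"), random_state=spec.seed)),
        ])
    if spec.family == "logit_boost":
        return GradientBoostingClassifier(
            n_estimators=hp.get("n_estimators", 100), max_depth=1,
            learning_rate=hp.get("learning_rate", 0.1), random_state=spec.seed,
        )
    if spec.family == "c45_tree":
        return DecisionTreeClassifier(
            criterion="entropy", ccp_alpha=hp.get("ccp_alpha", 1e-3),
            random_state=spec.seed,
        )
    if spec.family == "bayes_net":
        return GaussianNB()
    raise ValueError(spec.family)  # pragma: no cover


@dataclass
class Model:
    """A fitted classifier plus the feature columns it was trained on."""

    estimator: object
    feature_columns: list[str]
    classes: np.ndarray
    spec: ClassifierSpec

    def predict(self, features) -> np.ndarray:
        x = np.atleast_2d(np.asarray(features, dtype=float))
        return self.estimator.predict(x)

    def predict_table(self, table: pd.DataFrame) -> np.ndarray:
        return self.estimator.predict(table[self.feature_columns].to_numpy(dtype=float))


def _split_xy(table: pd.DataFrame):
    feature_cols = [c for c in table.columns if c not in KEY_COLUMNS + [CLASS_COLUMN]]
    x = table[feature_cols].to_numpy(dtype=float)
    return x, feature_cols


def train(table: pd.DataFrame, spec: ClassifierSpec) -> Model:
    """Fit a classifier on a labeled feature table.

    Identifier and position columns (image_id, superpixel_id, row, col) are
    excluded from the predictors — they locate superpixels for
    reconstruction but carry no texture information.
    """
    if CLASS_COLUMN not in table.columns:
        raise ValueError("training table has no class column")
    x, feature_cols = _split_xy(table)
    if np.isnan(x).any():
        raise ValueError("feature table contains NaN values")
    y = table[CLASS_COLUMN].to_numpy()
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError(f"training requires at least 2 classes, got {classes.tolist()}")
    est = _build_estimator(spec)
    est.fit(x, y)
    return Model(estimator=est, feature_columns=feature_cols, classes=classes, spec=spec)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    """One-vs-rest TP/FP/FN/TN per class."""

    classes: list
    tp: dict
    fp: dict
    fn: dict
    tn: dict
    n: int


@dataclass
class MetricsReport:
    classes: list
    ppv: dict
    tpr: dict
    f1: dict
    support: dict
    accuracy: float
    macro_f1: float
    weighted_f1: float

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_f1": self.macro_f1,
            "weighted_f1": self.weighted_f1,
            "per_class": {
                str(c): {"ppv": self.ppv[c], "tpr": self.tpr[c],
                         "f1": self.f1[c], "support": self.support[c]}
                for c in self.classes
            },
        }


def _safe_div(num: float, den: float) -> float:
    return num / den if den else 0.0


def compute_metrics(true, predicted) -> tuple[ConfusionMatrix, MetricsReport]:
    """Per-class one-vs-rest confusion counts and the derived metrics."""
    true = np.asarray(true)
    predicted = np.asarray(predicted)
    if true.shape != predicted.shape or true.ndim != 1:
        raise ValueError("true and predicted must be 1-D vectors of equal length")
    if true.size == 0:
        raise ValueError("empty label vectors")
    classes = sorted(set(true.tolist()) | set(predicted.tolist()))
    n = true.size
    tp, fp, fn, tn, ppv, tpr, f1, support = {}, {}, {}, {}, {}, {}, {}, {}
    for c in classes:
        t = true == c
        p = predicted == c
        tp[c] = int(np.sum(t & p))
        fp[c] = int(np.sum(~t & p))
        fn[c] = int(np.sum(t & ~p))
        tn[c] = int(np.sum(~t & ~p))
        ppv[c] = _safe_div(tp[c], tp[c] + fp[c])
        tpr[c] = _safe_div(tp[c], tp[c] + fn[c])
        f1[c] = _safe_div(2 * tp[c], 2 * tp[c] + fp[c] + fn[c])
        support[c] = int(t.sum())
    accuracy = float(np.mean(true == predicted))
    macro_f1 = float(np.mean([f1[c] for c in classes]))
    weighted_f1 = float(sum(f1[c] * support[c] for c in classes) / n)
    cm = ConfusionMatrix(classes=classes, tp=tp, fp=fp, fn=fn, tn=tn, n=n)
    report = MetricsReport(classes=classes, ppv=ppv, tpr=tpr, f1=f1,
                           support=support, accuracy=accuracy,
                           macro_f1=macro_f1, weighted_f1=weighted_f1)
    return cm, report


# ---------------------------------------------------------------------------
# Image-level cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CvReport:
    image_ids: list       # held-out image per fold
    train_ids: list       # training-image ids per fold (fold assignments)
    accuracies: list
    macro_f1s: list
    mean_accuracy: float
    mean_macro_f1: float

    def to_dict(self) -> dict:
        return {
            "folds": [
                {"image_id": i, "train_ids": t, "accuracy": a, "macro_f1": f}
                for i, t, a, f in zip(self.image_ids, self.train_ids,
                                      self.accuracies, self.macro_f1s)
            ],
            "mean_accuracy": self.mean_accuracy,
            "mean_macro_f1": self.mean_macro_f1,
        }


def cross_validate(tables: list[pd.DataFrame], spec: ClassifierSpec) -> CvReport:
    """Leave-one-image-out cross-validation over per-image feature tables."""
    if len(tables) < 2:
        raise ValueError("cross-validation requires at least 2 images")
    def ident(j, t):
        v = t["image_id"].iloc[0] if "image_id" in t else j
        return v.item() if hasattr(v, "item") else v  # JSON-safe scalar

    image_ids, train_ids, accs, f1s = [], [], [], []
    for i, held_out in enumerate(tables):
        training = pd.concat([t for j, t in enumerate(tables) if j != i],
                             ignore_index=True)
        model = train(training, spec)
        predicted = model.predict_table(held_out)
        _, report = compute_metrics(held_out[CLASS_COLUMN].to_numpy(), predicted)
        image_ids.append(ident(i, held_out))
        train_ids.append([ident(j, t) for j, t in enumerate(tables) if j != i])
        accs.append(report.accuracy)
        f1s.append(report.macro_f1)
    return CvReport(
        image_ids=image_ids, train_ids=train_ids, accuracies=accs, macro_f1s=f1s,
        mean_accuracy=float(np.mean(accs)), mean_macro_f1=float(np.mean(f1s)),
    )


def compare_grid(image_sets: dict[str, list[pd.DataFrame]],
                 specs: list[ClassifierSpec]) -> pd.DataFrame:
    """Cross-validate every enhancement × classifier pair.

    Returns one row per pair with mean accuracy and mean macro-F1, sorted so
    the best pair (highest accuracy, ties by macro-F1 then by the fixed
    enhancement order) comes first.
    """
    if not image_sets or not specs:
        raise ValueError("compare_grid needs at least one enhancement set and one classifier")
    rows = []
    for enhancement, tables in image_sets.items():
        for spec in specs:
            report = cross_validate(tables, spec)
            rows.append({
                "enhancement": enhancement,
                "classifier": spec.family,
                "mean_accuracy": report.mean_accuracy,
                "mean_macro_f1": report.mean_macro_f1,
            })
    grid = pd.DataFrame(rows)
    order = {e: i for i, e in enumerate(ENHANCEMENT_ORDER)}
    grid["_order"] = grid["enhancement"].map(lambda e: order.get(e, len(order)))
    grid = grid.sort_values(
        by=["mean_accuracy", "mean_macro_f1", "_order"],
        ascending=[False, False, True], kind="mergesort",
    ).drop(columns="_order").reset_index(drop=True)
    return grid


def select_best(grid: pd.DataFrame) -> tuple[str, str]:
    """Best (enhancement, classifier) pair of a comparison grid."""
    if grid is None or len(grid) == 0:
        raise ValueError("empty comparison grid")
    top = grid.iloc[0]
    return str(top["enhancement"]), str(top["classifier"])
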