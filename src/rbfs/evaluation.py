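"""Classification metrics and the stratified k-fold evaluation protocol.

Precision = TP/(TP+FP), Recall = TP/(TP+FN), Accuracy = (TP+TN)/total and
F1 = 2*Precision*Recall/(Precision+Recall), with class 1 = interaction.
Ratios with a zero denominator are reported as 0 and flagged rather than
returned as NaN.  AUROC is the area under the ROC curve (equivalently the
probability a random positive outscores a random negative, ties
half-credited); AUPR is estimated as average precision, without linear
interpolation.  Cross-validation is stratified k-fold (default k = 5) with
fold assignment derived from the run seed; label predictions threshold the
positive-class probability at 0.5.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from ._seeds import derive_seed

__all__ = [
    "ConfusionCounts",
    "ClassificationMetrics",
    "MetricsReport",
    "confusion",
    "classification_metrics",
    "auroc",
    "aupr",
    "crossvalidate",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Confusion counts with class 1 the positive (interacting) class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true / y_pred length mismatch")
    if not (np.isin(y_true, (0, 1)).all() and np.isin(y_pred, (0, 1)).all()):
        raise ValueError("labels must be binary (0/1)")
    return ConfusionCounts(
        TP=int(((y_true == 1) & (y_pred == 1)).sum()),
        FP=int(((y_true == 0) & (y_pred == 1)).sum()),
        TN=int(((y_true == 0) & (y_pred == 0)).sum()),
        FN=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


@dataclass(frozen=True)
class ClassificationMetrics:
    precision: float
    recall: float
    accuracy: float
    f1: float
    undefined: tuple[str, ...] = ()


def classification_metrics(c: ConfusionCounts) -> ClassificationMetrics:
    """Precision / recall / accuracy / F1 from confusion counts.

    Zero-denominator ratios are reported as 0.0 and named in ``undefined``.
    """
    if c.total == 0:
        raise ValueError("empty confusion counts")
    undefined: list[str] = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    precision = ratio(c.TP, c.TP + c.FP, "precision")
    recall = ratio(c.TP, c.TP + c.FN, "recall")
    accuracy = (c.TP + c.TN) / c.total
    if precision + recall == 0:
        if "precision" not in undefined and "recall" not in undefined:
            undefined.append("f1")
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return ClassificationMetrics(precision, recall, accuracy, f1, tuple(undefined))


def auroc(y_true, scores) -> float:
    """Area under the ROC curve; both classes must be present."""
    y_true = np.asarray(y_true)
    if len(np.unique(y_true)) < 2:
        raise ValueError("AUROC needs both classes present")
    return float(roc_auc_score(y_true, np.asarray(scores, dtype=float)))


def aupr(y_true, scores) -> float:
    """Area under the precision-recall curve (average precision)."""
    y_true = np.asarray(y_true)
    if (y_true == 1).sum() == 0:
        raise ValueError("AUPR needs at least one positive")
    return float(average_precision_score(y_true, np.asarray(scores, dtype=float)))


@dataclass
class MetricsReport:
    """Per-fold and aggregate metrics of one cross-validation run."""

    folds: list[dict] = field(default_factory=list)
    mean: dict = field(default_factory=dict)
    sd: dict = field(default_factory=dict)
    k: int = 5
    seed: int = 0
    selected: list[int] | None = None

    METRICS = ("precision", "recall", "accuracy", "f1", "auroc", "aupr")

    def aggregate(self) -> None:
        for m in self.METRICS:
            vals = np.array([f[m] for f in self.folds])
            self.mean[m] = float(vals.mean())
            self.sd[m] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0

    def to_json(self, **extra) -> str:
        return json.dumps(
            {
                "k": self.k,
                "seed": self.seed,
                "selected": self.selected,
                "folds": self.folds,
                "mean": self.mean,
                "sd": self.sd,
                **extra,
            },
            indent=2,
        )

    def to_text_table(self) -> str:
        """Aligned plain-text table: one row per fold plus mean +/- sd."""
        cols = ["fold"] + [m.capitalize() if m not in ("auroc", "aupr") else m.upper() for m in self.METRICS]
        lines = ["  ".join(f"{c:>10}" for c in cols)]
        for i, f in enumerate(self.folds, 1):
            lines.append(
                "  ".join([f"{i:>10}"] + [f"{f[m]:>10.4f}" for m in self.METRICS])
            )
        lines.append(
            "  ".join(
                [f"{'mean':>10}"] + [f"{self.mean[m]:>10.4f}" for m in self.METRICS]
            )
        )
        lines.append(
            "  ".join([f"{'sd':>10}"] + [f"{self.sd[m]:>10.4f}" for m in self.METRICS])
        )
        return "\n".join(lines)


def crossvalidate(
    X,
    y,
    selected,
    k: int = 5,
    seed: int = 0,
    model_factory=None,
    threshold: float = 0.5,
) -> MetricsReport:
    """Stratified k-fold evaluation of a classifier on the selected columns.

    ``model_factory(fold_seed)`` must return an unfitted classifier with
    ``fit`` / ``predict_proba``; it defaults to the package's
    gradient-boosted tree ensemble.  Deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=np.int64)
    if len(y) < k:
        raise ValueError(f"n={len(y)} smaller than fold count k={k}")
    selected = list(selected)
    if not selected:
        raise ValueError("empty feature selection")
    if model_factory is None:
        from .core import EnsembleConfig, make_classifier

        cfg = EnsembleConfig()
        model_factory = lambda s: make_classifier(cfg, s)  # noqa: E731

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=derive_seed(seed, 7))
    report = MetricsReport(k=k, seed=seed, selected=selected)
    Xs = X[:, selected]
    for fold, (tr, te) in enumerate(skf.split(Xs, y)):
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
            raise ValueError(
                f"fold {fold} is missing a class; check stratification / class balance"
            )
        model = model_factory(derive_seed(seed, 7, fold))
        model.fit(Xs[tr], y[tr])
        prob = model.predict_proba(Xs[te])[:, 1]
        pred = (prob >= threshold).astype(np.int64)
        cm = classification_metrics(confusion(y[te], pred))
        report.folds.append(
            {
                "precision": cm.precision,
                "recall": cm.recall,
                "accuracy": cm.accuracy,
                "f1": cm.f1,
                "auroc": auroc(y[te], prob),
                "aupr": aupr(y[te], prob),
            }
        )
    report.aggregate()
    return report
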