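"""Confusion-matrix metrics, 10-fold cross-validation, method comparison.

Metrics follow the standard binary-classification definitions with class
1 ("sensitizer") as positive:

    AG% = (TP + TN) / (TP + FP + TN + FN) * 100
    SE  = TP / (TP + FN)
    SP  = TN / (TN + FP)
    FP rate = FP / (FP + TN),  FN rate = FN / (FN + TP)

A metric with a zero denominator is reported as ``None`` (undefined),
never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from haptenml.featurize import impute_median
from haptenml.models import (
    predict_committee,
    predict_nb,
    train_committee,
    train_nb,
)

__all__ = [
    "ConfusionMatrix",
    "MetricReport",
    "CVResult",
    "confusion",
    "metrics",
    "cross_validate",
    "compare_methods",
    "make_model_spec",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            tp=self.tp + other.tp,
            tn=self.tn + other.tn,
            fp=self.fp + other.fp,
            fn=self.fn + other.fn,
        )

    def to_dict(self) -> Dict[str, int]:
        return {"tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn}


@dataclass(frozen=True)
class MetricReport:
    """Derived metrics; ``None`` marks an undefined (0/0) metric."""

    accuracy_pct: Optional[float]
    sensitivity: Optional[float]
    specificity: Optional[float]
    fp_rate: Optional[float]
    fn_rate: Optional[float]

    def as_text(self) -> str:
        def fmt(v, pct=False):
            if v is None:
                return "undefined"
            return f"{v:.0f}%" if pct else f"{v:.2f}"

        return (
            f"accuracy {fmt(self.accuracy_pct, pct=True)}  "
            f"SE {fmt(self.sensitivity)}  SP {fmt(self.specificity)}  "
            f"FP-rate {fmt(self.fp_rate)}  FN-rate {fmt(self.fn_rate)}"
        )


def confusion(real: Sequence[int], predicted: Sequence[int]) -> ConfusionMatrix:
    """Count TP/TN/FP/FN with class 1 as positive."""
    real = np.asarray(real, dtype=int)
    predicted = np.asarray(predicted, dtype=int)
    if real.shape != predicted.shape:
        raise ValueError(
            f"length mismatch: {real.shape[0]} real vs {predicted.shape[0]} predicted"
        )
    for arr, name in ((real, "real"), (predicted, "predicted")):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} labels must be binary 0/1")
    return ConfusionMatrix(
        tp=int(((real == 1) & (predicted == 1)).sum()),
        tn=int(((real == 0) & (predicted == 0)).sum()),
        fp=int(((real == 0) & (predicted == 1)).sum()),
        fn=int(((real == 1) & (predicted == 0)).sum()),
    )


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def metrics(cm: ConfusionMatrix) -> MetricReport:
    """Accuracy (%), sensitivity, specificity, FP/FN rates from counts."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return MetricReport(
        accuracy_pct=(cm.tp + cm.tn) / cm.total * 100.0,
        sensitivity=_ratio(cm.tp, cm.tp + cm.fn),
        specificity=_ratio(cm.tn, cm.tn + cm.fp),
        fp_rate=_ratio(cm.fp, cm.fp + cm.tn),
        fn_rate=_ratio(cm.fn, cm.fn + cm.tp),
    )


#: A model spec is (fit, predict): fit(X, y) -> model state,
#: predict(state, X) -> labels.  Imputation/selection that must be refit
#: per fold belongs inside fit.
ModelSpec = Tuple[Callable, Callable]


def make_model_spec(name: str, **kwargs) -> ModelSpec:
    """Model specs for the two pipeline classifiers.

    ``naive_bayes`` — Gaussian NB; ``random_committee`` — averaged
    randomized trees (``n_members``, ``seed`` forwarded).
    """
    if name == "naive_bayes":

        def fit(X, y):
            Xi, _ = impute_median(X)
            return train_nb((Xi, y))

        def predict(model, X):
            return np.array([predict_nb(model, row).label for row in np.asarray(X, dtype=float)])

        return fit, predict
    if name == "random_committee":
        n_members = kwargs.get("n_members", 10)
        seed = kwargs.get("seed", 0)

        def fit(X, y):
            Xi, _ = impute_median(X)
            return train_committee((Xi, y), n_members=n_members, seed=seed)

        def predict(model, X):
            return np.array(
                [predict_committee(model, row).label for row in np.asarray(X, dtype=float)]
            )

        return fit, predict
    raise ValueError(f"unknown model spec {name!r}")


@dataclass
class CVResult:
    """Per-fold reports plus the pooled confusion matrix."""

    fold_matrices: List[ConfusionMatrix]
    fold_reports: List[Optional[MetricReport]]
    pooled: ConfusionMatrix
    pooled_report: MetricReport
    degenerate_folds: List[int] = field(default_factory=list)


def cross_validate(
    training_set,
    model_spec,
    k: int = 10,
    seed: int = 0,
    stratified: bool = False,
) -> CVResult:
    """k-fold cross-validation with a single up-front permutation.

    Records are shuffled once with ``seed`` and split into ``k``
    near-equal folds; for each fold the model is refit on the remainder
    (including any imputation inside the spec's ``fit``) and tested on
    the held-out fold.  The pooled matrix is the elementwise sum, so its
    total equals n.  A training fold missing a class is recorded in
    ``degenerate_folds`` (its test records are still counted, predicted
    by the majority class of the training remainder).

    Folds are plain random by default; ``stratified=True`` balances
    class counts across folds.
    """
    if hasattr(training_set, "X"):
        X = np.asarray(training_set.X, dtype=float)
        y = np.asarray(training_set.y, dtype=int)
    else:
        X, y = training_set
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
    n = len(y)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n // 2:
        raise ValueError("k too large: folds need >= 2 records on average")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present overall")
    if isinstance(model_spec, str):
        model_spec = make_model_spec(model_spec, seed=seed)
    fit, predict = model_spec

    rng = np.random.default_rng(seed)
    if stratified:
        folds: List[np.ndarray] = [np.array([], dtype=int)] * k
        parts: List[List[int]] = [[] for _ in range(k)]
        for c in np.unique(y):
            idx = rng.permutation(np.where(y == c)[0])
            for i, chunk in enumerate(np.array_split(idx, k)):
                parts[i].extend(chunk.tolist())
        folds = [np.array(sorted(p), dtype=int) for p in parts]
    else:
        perm = rng.permutation(n)
        folds = [np.asarray(f) for f in np.array_split(perm, k)]

    fold_matrices: List[ConfusionMatrix] = []
    fold_reports: List[Optional[MetricReport]] = []
    degenerate: List[int] = []
    for i, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        y_tr = y[train_idx]
        # a fold whose training remainder lacks a class (or has too few
        # rows of one to fit class parameters) degrades to majority vote
        if min((y_tr == 0).sum(), (y_tr == 1).sum()) < 2:
            degenerate.append(i)
            majority = int(round(y_tr.mean())) if len(y_tr) else 0
            pred = np.full(len(test_idx), majority, dtype=int)
        else:
            model = fit(X[train_idx], y_tr)
            pred = np.asarray(predict(model, X[test_idx]), dtype=int)
        cm = confusion(y[test_idx], pred)
        fold_matrices.append(cm)
        fold_reports.append(metrics(cm) if cm.total else None)

    pooled = fold_matrices[0]
    for cm in fold_matrices[1:]:
        pooled = pooled + cm
    return CVResult(
        fold_matrices=fold_matrices,
        fold_reports=fold_reports,
        pooled=pooled,
        pooled_report=metrics(pooled),
        degenerate_folds=degenerate,
    )


def compare_methods(
    real: Sequence[Optional[int]],
    calls: Dict[str, Sequence[Optional[int]]],
) -> Dict[str, dict]:
    """Per-method metrics on a shared hapten panel.

    ``real`` and every method's call list are aligned index-by-index on
    the same haptens; ``None`` marks a missing call and is dropped
    pairwise (per method).  Each entry of the result carries the metric
    report, the confusion matrix, and the number of haptens used/dropped.
    """
    n = len(real)
    out: Dict[str, dict] = {}
    for name, method_calls in calls.items():
        if len(method_calls) != n:
            raise ValueError(f"method {name!r}: length mismatch")
        keep = [
            i for i in range(n) if real[i] is not None and method_calls[i] is not None
        ]
        if not keep:
            raise ValueError(f"method {name!r}: no haptens with both calls")
        cm = confusion([real[i] for i in keep], [method_calls[i] for i in keep])
        out[name] = {
            "report": metrics(cm),
            "matrix": cm,
            "n_used": len(keep),
            "n_dropped": n - len(keep),
        }
    return out
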