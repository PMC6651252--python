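"""Confusion matrices, recall rate / overall accuracy, repeated CV.

The grading study reports, per (descriptor, classifier) combination, a
confusion matrix over the four maturity stages together with the
per-class recall rate RR_i = 100 * n_i / N_i (correct / total in class
i) and the overall accuracy OA = 100 * sum(n_i) / sum(N_i), plus a
20x-repeated stratified 10-fold cross-validation summary (mean +- std
of the macro-averaged recall across the 20 repeats).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with rows = true class, columns = predicted class."""

    counts: np.ndarray  # (c, c) int
    class_labels: tuple

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (counts < 0).any():
            raise ValueError("confusion counts must be non-negative")
        if counts.shape[0] != len(self.class_labels):
            raise ValueError("class_labels length must match matrix order")

    @property
    def total(self) -> int:
        return int(np.asarray(self.counts).sum())


@dataclass(frozen=True)
class EvalReport:
    confusion: ConfusionMatrix
    rr: np.ndarray  # per-class recall, percent
    oa: float  # overall accuracy, percent
    cv_mean: float | None = None
    cv_std: float | None = None


def round_half_up(x: float, decimals: int = 1) -> float:
    """Table-style rounding: halves away from zero (96.55 -> 96.6)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def confusion(y_true, y_pred, class_labels=None) -> ConfusionMatrix:
    """Tabulate counts[i, j] = #(true class i, predicted class j)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if class_labels is None:
        class_labels = tuple(np.unique(np.concatenate([y_true, y_pred])).tolist())
    index = {lab: k for k, lab in enumerate(class_labels)}
    counts = np.zeros((len(class_labels), len(class_labels)), dtype=int)
    for t, p in zip(y_true.tolist(), y_pred.tolist()):
        if t not in index or p not in index:
            raise ValueError(f"label outside the class set: true={t!r}, pred={p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, class_labels=tuple(class_labels))


def recall_rates(cm: ConfusionMatrix, decimals: int | None = 1) -> np.ndarray:
    """Per-class recall in percent (100 * diagonal / row sum)."""
    counts = np.asarray(cm.counts, dtype=float)
    row_sums = counts.sum(axis=1)
    if (row_sums == 0).any():
        raise ValueError("empty true class: recall undefined")
    rr = 100.0 * np.diag(counts) / row_sums
    if decimals is not None:
        rr = np.array([round_half_up(v, decimals) for v in rr])
    return rr


def overall_accuracy(cm: ConfusionMatrix, decimals: int | None = 1) -> float:
    """Overall accuracy in percent (100 * trace / total)."""
    counts = np.asarray(cm.counts, dtype=float)
    total = counts.sum()
    if total == 0:
        raise ValueError("empty confusion matrix: accuracy undefined")
    oa = 100.0 * np.trace(counts) / total
    return round_half_up(oa, decimals) if decimals is not None else float(oa)


def macro_recall(cm: ConfusionMatrix) -> float:
    """Unweighted mean of the per-class recalls, as a fraction in [0, 1]."""
    return float(np.mean(recall_rates(cm, decimals=None))) / 100.0


def evaluate(y_true, y_pred, class_labels=None) -> EvalReport:
    cm = confusion(y_true, y_pred, class_labels=class_labels)
    return EvalReport(
        confusion=cm,
        rr=recall_rates(cm),
        oa=overall_accuracy(cm),
    )


def stratified_folds(y, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Random stratified partition into k disjoint folds covering all samples."""
    y = np.asarray(y)
    folds: list[list[int]] = [[] for _ in range(k)]
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        if idx.size < k:
            raise ValueError(f"class {c!r} has {idx.size} samples, fewer than k={k}")
        idx = rng.permutation(idx)
        for f, chunk in enumerate(np.array_split(idx, k)):
            folds[f].extend(chunk.tolist())
    return [np.sort(np.asarray(f, dtype=int)) for f in folds]


def repeated_cv(
    X: np.ndarray,
    y: np.ndarray,
    fit_predict,
    k: int = 10,
    repeats: int = 20,
    seed: int = 0,
) -> tuple[float, float]:
    """Repeated stratified k-fold CV of a fit/predict callable.

    ``fit_predict(X_train, y_train, X_test) -> y_pred``.  Each repeat
    re-partitions the data (seeded), pools the k folds' predictions into
    one confusion matrix and records the macro-averaged recall; returns
    the mean and sample standard deviation over repeats.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    labels = tuple(np.unique(y).tolist())
    stats = []
    for rep in range(repeats):
        rng = np.random.default_rng(seed + rep)
        folds = stratified_folds(y, k, rng)
        y_pred = np.empty_like(y)
        for f in range(k):
            test_idx = folds[f]
            train_idx = np.sort(np.concatenate([folds[g] for g in range(k) if g != f]))
            y_pred[test_idx] = fit_predict(X[train_idx], y[train_idx], X[test_idx])
        stats.append(macro_recall(confusion(y, y_pred, class_labels=labels)))
    stats = np.asarray(stats)
    std = float(stats.std(ddof=1)) if repeats > 1 else 0.0
    return float(stats.mean()), std


def format_confusion(report: EvalReport) -> str:
    """Human-readable table mirroring the study's confusion-matrix layout."""
    cm = report.confusion
    labels = [str(lab) for lab in cm.class_labels]
    header = "\t".join(["", *labels, "RR (%)", "OA (%)"])
    lines = [header]
    for i, lab in enumerate(labels):
        row = [lab, *(str(int(v)) for v in np.asarray(cm.counts)[i])]
        row.append(f"{report.rr[i]:.1f}")
        row.append(f"{report.oa:.1f}" if i == 0 else "")
        lines.append("\t".join(row))
    return "\n".join(lines)
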