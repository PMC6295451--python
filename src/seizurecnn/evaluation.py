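"""Stratified 6-fold cross-validation and segment-based performance metrics.

Three classification tasks are supported, each over labeled 1-s epochs:

* ``interictal-vs-preictal`` (binary, positive class = preictal)
* ``interictal-vs-ictal``   (binary, positive class = ictal)
* ``three-class``           (interictal vs preictal vs ictal)

For binary tasks the seizure-related state is the positive class, and

    sen = TP / (TP + FN)        specificity = TN / (FP + TN)
    acc = (TP + TN) / (P + N)

with P the number of positive (preictal/ictal) test epochs and N the
number of interictal test epochs. For the three-class task only
accuracy is reported. Metrics with a zero denominator raise rather
than silently returning 0, so degenerate folds are visible.

Folds are stratified random splits at the epoch level: every epoch is
tested exactly once, fold sizes per class differ by at most one, and
the shuffle is seeded. Fold metrics are averaged arithmetically; a
pooled mode (metrics over the concatenated test predictions) is also
available.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from . import cnn
from .exceptions import ConfigurationError, UndefinedMetricError
from .segmentation import CLASS_ORDER

__all__ = [
    "TASKS",
    "ConfusionCounts",
    "FoldResult",
    "MetricsReport",
    "make_folds",
    "confusion",
    "sensitivity",
    "specificity",
    "accuracy",
    "accuracy_multiclass",
    "cross_validate",
]

# task name -> class labels in index order (index 0 = negative/interictal)
TASKS: dict[str, tuple[str, ...]] = {
    "interictal-vs-preictal": ("interictal", "preictal"),
    "interictal-vs-ictal": ("interictal", "ictal"),
    "three-class": CLASS_ORDER,
}


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary 2x2 table; positive class is the seizure-related state."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ConfigurationError("confusion counts must be non-negative")

    @property
    def p(self) -> int:
        return self.tp + self.fn

    @property
    def n(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.p + self.n


@dataclass
class FoldResult:
    """Metrics for one held-out fold."""

    acc: float
    sen: float | None = None
    spe: float | None = None
    counts: ConfusionCounts | None = None
    n_test: int = 0


@dataclass
class MetricsReport:
    """Per-fold and averaged metrics for one task in one signal domain."""

    task: str
    domain: str
    folds: list[FoldResult] = field(default_factory=list)
    pooled: FoldResult | None = None

    @property
    def mean_acc(self) -> float:
        return float(np.mean([f.acc for f in self.folds]))

    @property
    def mean_sen(self) -> float | None:
        vals = [f.sen for f in self.folds]
        return None if any(v is None for v in vals) else float(np.mean(vals))

    @property
    def mean_spe(self) -> float | None:
        vals = [f.spe for f in self.folds]
        return None if any(v is None for v in vals) else float(np.mean(vals))

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "domain": self.domain,
            "folds": [
                {"acc": f.acc, "sen": f.sen, "spe": f.spe, "n_test": f.n_test}
                for f in self.folds
            ],
            "mean": {"acc": self.mean_acc, "sen": self.mean_sen, "spe": self.mean_spe},
        }


def make_folds(
    n: int, k: int, labels: Sequence, seed: int = 0
) -> list[np.ndarray]:
    """Stratified k-fold test-index sets: disjoint, exhaustive, seeded.

    Each class's indices are shuffled and dealt round-robin across the
    folds, with the dealing position carried over between classes, so
    per-class (and overall) fold sizes differ by at most one. Classes
    with fewer than ``k`` members are allowed (some folds simply go
    without them), so ``n == k`` yields ``k`` singletons.
    """
    labels = np.asarray(labels)
    if len(labels) != n:
        raise ConfigurationError(f"{len(labels)} labels for n={n}")
    if n < k:
        raise ConfigurationError(f"cannot make {k} folds from {n} examples")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    offset = 0
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        for i, ix in enumerate(idx):
            folds[(offset + i) % k].append(int(ix))
        offset = (offset + len(idx)) % k
    return [np.sort(np.array(f, dtype=np.int64)) for f in folds]


def confusion(
    preds: Sequence[int], truths: Sequence[int], positive_class: int = 1
) -> ConfusionCounts:
    """2x2 counts for a binary task (labels are class indices)."""
    preds = np.asarray(preds)
    truths = np.asarray(truths)
    if preds.shape != truths.shape:
        raise ConfigurationError("prediction/truth length mismatch")
    pos = truths == positive_class
    ppos = preds == positive_class
    return ConfusionCounts(
        tp=int(np.sum(pos & ppos)),
        fn=int(np.sum(pos & ~ppos)),
        tn=int(np.sum(~pos & ~ppos)),
        fp=int(np.sum(~pos & ppos)),
    )


def sensitivity(c: ConfusionCounts) -> float:
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("sensitivity undefined: no positive examples")
    return c.tp / (c.tp + c.fn)


def specificity(c: ConfusionCounts) -> float:
    if c.fp + c.tn == 0:
        raise UndefinedMetricError("specificity undefined: no negative examples")
    return c.tn / (c.fp + c.tn)


def accuracy(c: ConfusionCounts) -> float:
    if c.total == 0:
        raise UndefinedMetricError("accuracy undefined: empty test set")
    return (c.tp + c.tn) / c.total


def accuracy_multiclass(preds: Sequence[int], truths: Sequence[int]) -> float:
    preds = np.asarray(preds)
    truths = np.asarray(truths)
    if preds.shape != truths.shape:
        raise ConfigurationError("prediction/truth length mismatch")
    if preds.size == 0:
        raise UndefinedMetricError("accuracy undefined: empty test set")
    return float(np.mean(preds == truths))


ClassifierFactory = Callable[[np.ndarray, np.ndarray], Callable[[np.ndarray], np.ndarray]]


def _cnn_factory(config: cnn.CNNConfig) -> ClassifierFactory:
    def factory(x_train: np.ndarray, y_train: np.ndarray):
        cfg = replace(config, input_shape=x_train.shape[1:], n_classes=len(np.unique(y_train)))
        model, _ = cnn.train(x_train, y_train, cfg)
        return lambda x_test: cnn.predict_batch(model, x_test)

    return factory


def task_arrays(epochs: Sequence, task: str) -> tuple[np.ndarray, np.ndarray]:
    """Stack the epochs relevant to ``task`` into (X, y) index arrays."""
    if task not in TASKS:
        raise ConfigurationError(f"unknown task {task!r}; expected one of {sorted(TASKS)}")
    classes = TASKS[task]
    kept = [e for e in epochs if e.label in classes]
    if not kept:
        raise ConfigurationError(f"no epochs with labels {classes}")
    x = np.stack([e.data for e in kept])
    y = np.array([classes.index(e.label) for e in kept], dtype=np.int64)
    return x, y


def cross_validate(
    epochs: Sequence,
    task: str,
    domain: str,
    cnn_config: cnn.CNNConfig | None = None,
    k: int = 6,
    seed: int = 0,
    folds: list[np.ndarray] | None = None,
    classifier_factory: ClassifierFactory | None = None,
    pooled: bool = False,
) -> MetricsReport:
    """k-fold cross-validation of one task on one signal domain.

    Each fold is held out once; the classifier (by default the CNN,
    including its normalization statistics) is fitted on the remaining
    k-1 folds only. Per-fold metrics are averaged arithmetically; with
    ``pooled=True`` metrics over the concatenated predictions are also
    reported. Fold seeds are derived deterministically from ``seed``.
    """
    x, y = task_arrays(epochs, task)
    n_classes = len(TASKS[task])
    if len(np.unique(y)) < n_classes:
        raise ConfigurationError(f"task {task!r} needs all of {TASKS[task]} present")
    if folds is None:
        folds = make_folds(len(y), k, y, seed)
    if classifier_factory is None:
        if cnn_config is None:
            cnn_config = cnn.CNNConfig(input_shape=x.shape[1:], n_classes=n_classes, seed=seed)
        classifier_factory = _cnn_factory(cnn_config)

    report = MetricsReport(task=task, domain=domain)
    all_preds = np.full(len(y), -1, dtype=np.int64)
    for test_idx in folds:
        mask = np.zeros(len(y), dtype=bool)
        mask[test_idx] = True
        y_train = y[~mask]
        if len(np.unique(y_train)) < n_classes:
            raise ConfigurationError("a training split lost one of the task's classes")
        predict_fn = classifier_factory(x[~mask], y_train)
        preds = np.asarray(predict_fn(x[mask]))
        all_preds[test_idx] = preds
        report.folds.append(_fold_metrics(preds, y[mask], n_classes))
    if pooled:
        report.pooled = _fold_metrics(all_preds, y, n_classes)
    return report


def _fold_metrics(preds: np.ndarray, truths: np.ndarray, n_classes: int) -> FoldResult:
    if n_classes == 2:
        c = confusion(preds, truths, positive_class=1)
        return FoldResult(
            acc=accuracy(c), sen=sensitivity(c), spe=specificity(c), counts=c, n_test=c.total
        )
    return FoldResult(acc=accuracy_multiclass(preds, truths), n_test=len(truths))
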