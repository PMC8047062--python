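"""Confusion metrics, the burden index, ROC curves, and the trial harness.

Besides sensitivity and specificity, performance is summarised by the
*burden index* B = 100 * (TP + FP) / N: the percentage of images the
classifier flags as Food, i.e. the share of the corpus a human reviewer
must still inspect.  B = 0% means fully automatic triage, B = 100% means
fully manual review.

``run_trial`` executes the full experiment pipeline once (split ->
balance the training set -> vocabulary -> conditionals -> featurize ->
train -> score the untouched test set), and ``repeat_trials`` summarises
several independent trials as mean +/- sd per metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

from .annotations import LabeledDataset, balance_downsample, split_dataset
from .classifiers import ModelKind, decision_scores, predict_labels, train_sln
from .interface import estimate_conditionals, featurize_dataset
from .vocabulary import build_histogram, select_by_coverage

__all__ = [
    "ConfusionCounts",
    "ROCCurve",
    "TrialSummary",
    "ExperimentConfig",
    "sensitivity",
    "specificity",
    "burden_index",
    "confusion_from_predictions",
    "roc_curve",
    "run_trial",
    "run_trial_scores",
    "repeat_trials",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion-matrix counts (positive class = Food)."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def sensitivity(c: ConfusionCounts) -> float:
    """TP / (TP + FN)."""
    if c.tp + c.fn == 0:
        raise ZeroDivisionError("sensitivity undefined: no positive ground truth")
    return c.tp / (c.tp + c.fn)


def specificity(c: ConfusionCounts) -> float:
    """TN / (TN + FP)."""
    if c.tn + c.fp == 0:
        raise ZeroDivisionError("specificity undefined: no negative ground truth")
    return c.tn / (c.tn + c.fp)


def burden_index(c: ConfusionCounts) -> float:
    """100 * (TP + FP) / (TP + TN + FN + FP), in percent."""
    if c.total == 0:
        raise ZeroDivisionError("burden index undefined on empty counts")
    return 100.0 * (c.tp + c.fp) / c.total


def confusion_from_predictions(
    predicted: Sequence[int], labels: Sequence[int]
) -> ConfusionCounts:
    pred = np.asarray(predicted, dtype=int)
    lab = np.asarray(labels, dtype=int)
    if pred.shape != lab.shape:
        raise ValueError("predictions and labels differ in length")
    return ConfusionCounts(
        tp=int(((pred == 1) & (lab == 1)).sum()),
        fp=int(((pred == 1) & (lab == 0)).sum()),
        tn=int(((pred == 0) & (lab == 0)).sum()),
        fn=int(((pred == 0) & (lab == 1)).sum()),
    )


@dataclass(frozen=True)
class ROCCurve:
    """Sensitivity vs. (1 - specificity) swept over decision thresholds."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.fpr.tolist(), self.tpr.tolist()))

    def area(self) -> float:
        """Area under the curve by trapezoidal integration."""
        return float(np.trapezoid(self.tpr, self.fpr))


def roc_curve(scores: Sequence[float], labels: Sequence[int]) -> ROCCurve:
    """Standard threshold sweep; tied scores cross the threshold together.

    The returned curve includes the (0, 0) and (1, 1) endpoints and has
    monotonically non-decreasing fpr and tpr.  Raises on single-class
    labels.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    if np.unique(labels).size < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thr = _sk_roc_curve(labels, scores, drop_intermediate=False)
    if fpr[-1] != 1.0 or tpr[-1] != 1.0:  # pragma: no cover - sklearn guarantees
        fpr = np.append(fpr, 1.0)
        tpr = np.append(tpr, 1.0)
        thr = np.append(thr, -np.inf)
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thr)


@dataclass(frozen=True)
class ExperimentConfig:
    """Parameters of one full train/evaluate experiment."""

    train_fraction: float = 0.75
    coverage: float = 0.5
    alpha: float = 1.0
    classifier: ModelKind = "svm_poly"
    hyperparams: dict = field(default_factory=dict)
    balance_training: bool = True


def _run_pipeline(data: LabeledDataset, config: ExperimentConfig, seed: int):
    """Split, balance, featurize and fit; return test labels, scores, preds."""
    train, test = split_dataset(data, config.train_fraction, seed)
    if config.balance_training:
        train = balance_downsample(train, seed)
    hist = build_histogram(train)
    vocab = select_by_coverage(hist, config.coverage)
    table = estimate_conditionals(train, vocab, config.alpha)
    train_df = featurize_dataset(train, table, vocab)
    test_df = featurize_dataset(test, table, vocab)
    X_tr = train_df.drop(columns="label").to_numpy()
    y_tr = train_df["label"].to_numpy()
    X_te = test_df.drop(columns="label").to_numpy()
    y_te = test_df["label"].to_numpy()
    model = train_sln(X_tr, y_tr, kind=config.classifier,
                      hyperparams=config.hyperparams, vocab=vocab, seed=seed)
    scores = decision_scores(model, X_te)
    preds = (scores > 0).astype(int)
    return y_te, scores, preds


def run_trial(data: LabeledDataset, config: ExperimentConfig, seed: int) -> ConfusionCounts:
    """One end-to-end experiment, fully reproducible per seed.

    The training set is class-balanced by downsampling; the test set
    keeps its natural class imbalance.
    """
    y_te, _, preds = _run_pipeline(data, config, seed)
    return confusion_from_predictions(preds, y_te)


def run_trial_scores(
    data: LabeledDataset, config: ExperimentConfig, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Like ``run_trial`` but returning ``(test_labels, decision_scores)``."""
    y_te, scores, _ = _run_pipeline(data, config, seed)
    return y_te, scores


@dataclass(frozen=True)
class TrialSummary:
    """Mean and sample standard deviation of each metric over trials."""

    n_trials: int
    mean: dict[str, float]
    sd: dict[str, float]
    per_trial: list[dict[str, float]]

    def __str__(self) -> str:
        lines = [f"{'metric':<14}{'mean':>10}{'sd':>10}   (n={self.n_trials})"]
        for m in self.mean:
            lines.append(f"{m:<14}{self.mean[m]:>10.4f}{self.sd[m]:>10.4f}")
        return "\n".join(lines)


def repeat_trials(
    data: LabeledDataset,
    config: ExperimentConfig,
    seeds: Sequence[int],
) -> TrialSummary:
    """Repeat the full experiment once per seed and summarise the metrics.

    Each trial retrains from scratch (its own split, balancing,
    vocabulary, conditionals and classifier).  Standard deviations use
    the sample (n-1) denominator; a single trial reports sd = 0.
    """
    if len(seeds) == 0:
        raise ValueError("at least one seed is required")
    rows: list[dict[str, float]] = []
    for s in seeds:
        c = run_trial(data, config, s)
        rows.append({
            "sensitivity": sensitivity(c),
            "specificity": specificity(c),
            "burden": burden_index(c),
        })
    metrics = list(rows[0])
    mean = {m: float(np.mean([r[m] for r in rows])) for m in metrics}
    if len(rows) > 1:
        sd = {m: float(np.std([r[m] for r in rows], ddof=1)) for m in metrics}
    else:
        sd = {m: 0.0 for m in metrics}
    return TrialSummary(n_trials=len(rows), mean=mean, sd=sd, per_trial=rows)
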