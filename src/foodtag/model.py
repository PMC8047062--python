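"""Model/Results surface tying the pipeline together.

``FoodTagModel`` holds a labeled annotation corpus plus the experiment
configuration; ``fit`` runs the full pipeline once (split, balance the
training set, build the vocabulary, estimate the conditional table,
featurize, train the shallow learner) and returns a
``FoodTagResults`` carrying the fitted state, test-set metrics and a
``summary()`` table, in the spirit of statsmodels' Model/Results pair.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .annotations import (
    LabeledDataset,
    balance_downsample,
    load_annotations,
    split_dataset,
)
from .classifiers import TrainedSLN, decision_scores, train_sln, vocabulary_ref
from .evaluation import (
    ConfusionCounts,
    ExperimentConfig,
    ROCCurve,
    TrialSummary,
    burden_index,
    confusion_from_predictions,
    repeat_trials,
    roc_curve,
    sensitivity,
    specificity,
)
from .interface import ConditionalTable, estimate_conditionals, featurize_dataset
from .vocabulary import TagVocabulary, build_histogram, select_by_coverage

__all__ = ["FoodTagModel", "FoodTagResults"]


class FoodTagModel:
    """Food/non-food classifier over tag annotations.

    Parameters
    ----------
    data : LabeledDataset
        Labeled tag annotations (1 = Food, 0 = Non-food).
    config : ExperimentConfig, optional
        Train fraction, vocabulary coverage, smoothing alpha, classifier
        kind and hyperparameters.

    Examples
    --------
    >>> from foodtag import FoodTagModel, synthetic
    >>> data = synthetic.generate(synthetic.informative_config(seed=7))
    >>> res = FoodTagModel(data).fit(seed=7)
    >>> print(res.summary())                         # doctest: +SKIP
    """

    def __init__(self, data: LabeledDataset, config: ExperimentConfig | None = None):
        if len(data) == 0:
            raise ValueError("dataset is empty")
        self.data = data
        self.config = config or ExperimentConfig()

    @classmethod
    def from_jsonl(cls, path: str | Path, config: ExperimentConfig | None = None,
                   max_tags: int = 200) -> "FoodTagModel":
        """Build a model from a JSON Lines annotation file."""
        return cls(load_annotations(path, max_tags=max_tags), config=config)

    def fit(self, seed: int = 0) -> "FoodTagResults":
        """Run the pipeline once and return fitted results.

        The split, balancing and classifier are all driven by ``seed``,
        so the fit is fully reproducible.
        """
        cfg = self.config
        train, test = split_dataset(self.data, cfg.train_fraction, seed)
        if cfg.balance_training:
            train = balance_downsample(train, seed)
        vocab = select_by_coverage(build_histogram(train), cfg.coverage)
        table = estimate_conditionals(train, vocab, cfg.alpha)
        train_df = featurize_dataset(train, table, vocab)
        test_df = featurize_dataset(test, table, vocab)
        sln = train_sln(
            train_df.drop(columns="label").to_numpy(),
            train_df["label"].to_numpy(),
            kind=cfg.classifier,
            hyperparams=cfg.hyperparams,
            vocab=vocab,
            seed=seed,
        )
        test_scores = decision_scores(sln, test_df.drop(columns="label").to_numpy())
        return FoodTagResults(
            model=self,
            seed=seed,
            vocabulary=vocab,
            conditionals=table,
            sln=sln,
            train_set=train,
            test_set=test,
            test_scores=test_scores,
        )

    def repeat(self, seeds: Sequence[int]) -> TrialSummary:
        """Retrain from scratch once per seed; mean +/- sd per metric."""
        return repeat_trials(self.data, self.config, seeds)


@dataclass
class FoodTagResults:
    """Fitted pipeline state and held-out evaluation."""

    model: FoodTagModel
    seed: int
    vocabulary: TagVocabulary
    conditionals: ConditionalTable
    sln: TrainedSLN
    train_set: LabeledDataset
    test_set: LabeledDataset
    test_scores: np.ndarray

    # -- predictions ---------------------------------------------------
    def scores(self, data: LabeledDataset | None = None) -> np.ndarray:
        """Decision scores (larger = more Food-like); default: test set."""
        if data is None:
            return self.test_scores
        df = featurize_dataset(data, self.conditionals, self.vocabulary)
        return decision_scores(self.sln, df.drop(columns="label").to_numpy(),
                               vocab_ref=vocabulary_ref(self.vocabulary))

    def predict(self, data: LabeledDataset | None = None) -> np.ndarray:
        """Binary Food predictions at the default decision boundary."""
        return (self.scores(data) > 0).astype(int)

    # -- evaluation ----------------------------------------------------
    def confusion(self, data: LabeledDataset | None = None) -> ConfusionCounts:
        labels = (self.test_set if data is None else data).labels
        return confusion_from_predictions(self.predict(data), labels)

    def roc(self, data: LabeledDataset | None = None) -> ROCCurve:
        labels = (self.test_set if data is None else data).labels
        return roc_curve(self.scores(data), labels)

    def metrics(self) -> dict[str, float]:
        c = self.confusion()
        return {
            "sensitivity": sensitivity(c),
            "specificity": specificity(c),
            "burden": burden_index(c),
            "auc": self.roc().area(),
        }

    def plot_roc(self, ax=None):
        """Plot the test-set ROC curve (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        curve = self.roc()
        ax.plot(curve.fpr, curve.tpr, label=f"{self.sln.model_kind} "
                f"(AUC = {curve.area():.3f})")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend()
        return ax

    def summary(self) -> str:
        """Human-readable fit report."""
        c = self.confusion()
        m = self.metrics()
        cfg = self.model.config
        n_pos, n_neg = self.model.data.class_counts()
        lines = [
            "Food/Non-food tag classification results",
            "=" * 46,
            f"classifier:       {self.sln.model_kind}",
            f"images:           {len(self.model.data)} "
            f"({n_pos} food / {n_neg} non-food)",
            f"train fraction:   {cfg.train_fraction} (balanced: "
            f"{len(self.train_set)} images)",
            f"vocabulary:       {len(self.vocabulary)} tags "
            f"at {cfg.coverage:.0%} coverage",
            f"smoothing alpha:  {cfg.alpha}",
            f"seed:             {self.seed}",
            "-" * 46,
            f"test confusion:   TP={c.tp}  FN={c.fn}  TN={c.tn}  FP={c.fp}",
            f"sensitivity:      {m['sensitivity']:.2f}",
            f"specificity:      {m['specificity']:.2f}",
            f"burden index:     {m['burden']:.1f}%",
            f"ROC area:         {m['auc']:.3f}",
            "=" * 46,
        ]
        return "\n".join(lines)
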