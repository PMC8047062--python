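"""Shallow learners over food-prediction-power features, plus two baselines.

The classification head is deliberately shallow: an SVM with a
polynomial kernel (default) or linear discriminant analysis, both
fitted on the M-dimensional feature vectors produced by the
probabilistic interface.  Two reference baselines operate directly on
the raw annotations:

* the annotator-only rule -- classify Food iff the explicit ``"food"``
  tag is reported with likelihood strictly above a threshold; and
* the evidence-value rule -- count how many of the image's tags belong
  to a configured food-related list and classify Food iff that count
  strictly exceeds an integer k.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .annotations import TagAnnotation
from .interface import FeatureVector
from .vocabulary import TagVocabulary

ModelKind = Literal["svm_poly", "lda"]

# Editable default list of food-related tags for the evidence baseline.
DEFAULT_FOOD_RELATED_TAGS = frozenset({
    "food", "dish", "meal", "vegetable", "fruit", "cooking",
    "dinner", "lunch", "breakfast", "kitchen", "plate", "bowl",
})

__all__ = [
    "TrainedSLN",
    "BaselineConfig",
    "vocabulary_ref",
    "train_sln",
    "decision_scores",
    "predict_labels",
    "dnn_threshold_baseline",
    "evidence_value_baseline",
    "DEFAULT_FOOD_RELATED_TAGS",
]


def vocabulary_ref(vocab: TagVocabulary) -> str:
    """Stable identifier binding a model to the vocabulary it was trained on."""
    h = hashlib.sha256("\x00".join(vocab.tags).encode("utf-8"))
    return h.hexdigest()[:16]


@dataclass
class TrainedSLN:
    """A fitted shallow learner bound to its training vocabulary."""

    model_kind: ModelKind
    estimator: object
    vocabulary_ref: str
    scaler: StandardScaler | None = None
    hyperparams: dict = field(default_factory=dict)

    def _check(self, vocab_ref: str | None) -> None:
        if vocab_ref is not None and vocab_ref != self.vocabulary_ref:
            raise ValueError(
                f"vocabulary mismatch: model was trained with {self.vocabulary_ref}, "
                f"scoring requested with {vocab_ref}"
            )


def _stack(features: Sequence[FeatureVector] | np.ndarray) -> np.ndarray:
    if isinstance(features, np.ndarray):
        return np.atleast_2d(features)
    return np.vstack([fv.values for fv in features]) if len(features) else np.empty((0, 0))


def train_sln(
    features: Sequence[FeatureVector] | np.ndarray,
    labels: Sequence[int],
    kind: ModelKind = "svm_poly",
    hyperparams: dict | None = None,
    vocab: TagVocabulary | None = None,
    seed: int = 0,
    standardize: bool = False,
) -> TrainedSLN:
    """Fit an SVM (polynomial kernel) or LDA on feature vectors.

    Hyperparameters default to degree-3 polynomial kernel, C = 1 and
    variance-scaled gamma for the SVM; features are used unscaled by
    default since food-prediction powers are already commensurate in
    [0, 1] (set ``standardize=True`` to z-score them).  Raises on
    single-class labels or inconsistent feature dimensions.
    """
    X = _stack(features)
    y = np.asarray(labels, dtype=int)
    if X.shape[0] != y.shape[0]:
        raise ValueError(f"{X.shape[0]} feature rows but {y.shape[0]} labels")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training labels contain a single class")
    hp = dict(hyperparams or {})
    scaler = None
    if standardize:
        scaler = StandardScaler().fit(X)
        X = scaler.transform(X)
    if kind == "svm_poly":
        # max_iter bounds libsvm's SMO loop, which can cycle endlessly on
        # degenerate (near-constant) feature matrices; converged fits are
        # unaffected at this cap.
        est = SVC(
            kernel="poly",
            degree=hp.get("degree", 3),
            C=hp.get("C", 1.0),
            gamma=hp.get("gamma", "scale"),
            coef0=hp.get("coef0", 1.0),
            max_iter=hp.get("max_iter", 200_000),
            random_state=seed,
        )
    elif kind == "lda":
        est = LinearDiscriminantAnalysis()
    else:
        raise ValueError(f"unknown model kind {kind!r}")
    est.fit(X, y)
    ref = vocabulary_ref(vocab) if vocab is not None else ""
    return TrainedSLN(model_kind=kind, estimator=est, vocabulary_ref=ref,
                      scaler=scaler, hyperparams=hp)


def decision_scores(
    model: TrainedSLN,
    features: Sequence[FeatureVector] | np.ndarray,
    vocab_ref: str | None = None,
) -> np.ndarray:
    """Continuous decision scores; larger means more Food-like.

    Thresholding the scores at 0 reproduces the model's own label
    predictions, and sweeping the threshold traces the ROC curve.
    """
    model._check(vocab_ref)
    X = _stack(features)
    if X.size == 0:
        return np.empty(0)
    if model.scaler is not None:
        X = model.scaler.transform(X)
    return np.asarray(model.estimator.decision_function(X), dtype=float)


def predict_labels(
    model: TrainedSLN,
    features: Sequence[FeatureVector] | np.ndarray,
    vocab_ref: str | None = None,
) -> np.ndarray:
    """Binary predictions at the model's default decision boundary."""
    return (decision_scores(model, features, vocab_ref) > 0).astype(int)


@dataclass(frozen=True)
class BaselineConfig:
    """Parameters of the two annotation-level baselines."""

    food_tag: str = "food"
    likelihood_threshold: float = 0.7
    food_related_tags: frozenset[str] = DEFAULT_FOOD_RELATED_TAGS
    evidence_k: int = 2

    def __post_init__(self) -> None:
        if not 0.0 <= self.likelihood_threshold <= 1.0:
            raise ValueError("likelihood_threshold must lie in [0, 1]")
        if self.evidence_k < 0:
            raise ValueError("evidence_k must be non-negative")


def dnn_threshold_baseline(ann: TagAnnotation, cfg: BaselineConfig) -> int:
    """Annotator-only rule: Food iff ``food_tag`` likelihood > threshold.

    The inequality is strict; an absent food tag (likelihood 0) is
    Non-food for any threshold.
    """
    return int(ann.likelihood(cfg.food_tag) > cfg.likelihood_threshold)


def evidence_value_baseline(ann: TagAnnotation, cfg: BaselineConfig) -> int:
    """Evidence-value rule: Food iff the count of food-related tags > k."""
    if not cfg.food_related_tags:
        raise ValueError("food_related_tags must be non-empty")
    evidence = len(ann.tag_set & cfg.food_related_tags)
    return int(evidence > cfg.evidence_k)
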