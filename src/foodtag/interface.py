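"""Probabilistic network interface: conditional food probabilities and features.

This layer converts an image's tag annotations into a fixed-length
feature vector of *food-prediction powers*.  For each vocabulary tag i,
two conditional probabilities are estimated from labeled training data:

* ``p_pos = P(Food | T_i = 1)`` -- probability the image contains food
  given that tag i correctly describes it, and
* ``p_neg = P(Food | T_i = 0)`` -- the same given the tag does not apply,

each approximated by a count ratio over training images (optionally with
a symmetric pseudo-count ``alpha``).  The annotator's likelihood
``v = P(T_i = 1)`` then combines them by total probability into the
food-prediction power

    P_i = p_pos * v + p_neg * (1 - v),

the probability that the image contains food considering tag i alone.
The vector ``(P_1, ..., P_M)`` over the vocabulary is the classifier's
input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .annotations import LabeledDataset, TagAnnotation
from .vocabulary import TagVocabulary

__all__ = [
    "TagConditional",
    "ConditionalTable",
    "FeatureVector",
    "estimate_conditionals",
    "food_prediction_power",
    "featurize",
    "featurize_dataset",
]


@dataclass(frozen=True)
class TagConditional:
    """Estimated conditionals and supporting counts for one tag."""

    p_pos: float  # P(Food | tag present)
    p_neg: float  # P(Food | tag absent)
    n_with: int
    n_without: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_pos <= 1.0 and 0.0 <= self.p_neg <= 1.0):
            raise ValueError("conditional probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class ConditionalTable:
    """Per-tag conditional food probabilities over a vocabulary."""

    entries: dict[str, TagConditional]
    smoothing: float

    def __getitem__(self, tag: str) -> TagConditional:
        return self.entries[tag]

    def __len__(self) -> int:
        return len(self.entries)

    def arrays(self, vocab: TagVocabulary) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(p_pos, p_neg)`` arrays aligned to the vocabulary order."""
        p_pos = np.array([self.entries[t].p_pos for t in vocab.tags])
        p_neg = np.array([self.entries[t].p_neg for t in vocab.tags])
        return p_pos, p_neg

    def save(self, path: str | Path) -> None:
        obj = {
            "smoothing": self.smoothing,
            "tags": {
                t: {"p_pos": c.p_pos, "p_neg": c.p_neg,
                    "n_with": c.n_with, "n_without": c.n_without}
                for t, c in self.entries.items()
            },
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(obj, fh)

    @classmethod
    def load(cls, path: str | Path) -> "ConditionalTable":
        with open(path, "r", encoding="utf-8") as fh:
            obj = json.load(fh)
        entries = {
            t: TagConditional(d["p_pos"], d["p_neg"], d["n_with"], d["n_without"])
            for t, d in obj["tags"].items()
        }
        return cls(entries=entries, smoothing=float(obj["smoothing"]))


@dataclass(frozen=True)
class FeatureVector:
    """Food-prediction powers of one image, aligned to a vocabulary."""

    image_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1:
            raise ValueError("feature values must be a 1-D vector")
        if np.any(vals < 0.0) or np.any(vals > 1.0):
            raise ValueError("feature values must lie in [0, 1]")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.values)


def estimate_conditionals(
    train: LabeledDataset, vocab: TagVocabulary, alpha: float = 1.0
) -> ConditionalTable:
    """Estimate ``P(Food | tag present)`` and ``P(Food | tag absent)`` per tag.

    With pseudo-count ``alpha``::

        p_pos = (#Food images with tag  + alpha) / (#images with tag  + 2*alpha)
        p_neg = (#Food images w/o tag   + alpha) / (#images w/o tag   + 2*alpha)

    ``alpha = 0`` gives the pure count ratios; it raises a
    ``ZeroDivisionError`` if any vocabulary tag occurs in none or all of
    the training images, since a denominator is then zero.
    """
    if len(train) == 0:
        raise ValueError("training set is empty")
    if alpha < 0:
        raise ValueError(f"alpha must be non-negative, got {alpha}")
    n = len(train)
    entries: dict[str, TagConditional] = {}
    # presence matrix per vocab tag, food counts
    labels = train.labels
    for tag in vocab.tags:
        present = np.array([tag in ann.tag_set for ann, _ in train])
        n_with = int(present.sum())
        n_without = n - n_with
        food_with = int((present & (labels == 1)).sum())
        food_without = int((~present & (labels == 1)).sum())
        if alpha == 0 and (n_with == 0 or n_without == 0):
            raise ZeroDivisionError(
                f"tag {tag!r} occurs in {n_with}/{n} training images; the "
                "unsmoothed count ratio is undefined -- use a positive alpha"
            )
        p_pos = (food_with + alpha) / (n_with + 2 * alpha)
        p_neg = (food_without + alpha) / (n_without + 2 * alpha)
        entries[tag] = TagConditional(p_pos=p_pos, p_neg=p_neg,
                                      n_with=n_with, n_without=n_without)
    return ConditionalTable(entries=entries, smoothing=alpha)


def food_prediction_power(v: float, p_pos: float, p_neg: float) -> float:
    """Total-probability combination ``p_pos * v + p_neg * (1 - v)``.

    Affine in the likelihood ``v``: equals ``p_neg`` at ``v = 0`` and
    ``p_pos`` at ``v = 1``.  All arguments must lie in [0, 1].
    """
    for name, x in (("v", v), ("p_pos", p_pos), ("p_neg", p_neg)):
        if not 0.0 <= x <= 1.0:
            raise ValueError(f"{name}={x} outside [0, 1]")
    return p_pos * v + p_neg * (1.0 - v)


def featurize(
    ann: TagAnnotation, table: ConditionalTable, vocab: TagVocabulary
) -> FeatureVector:
    """Map one annotation to its vector of food-prediction powers.

    For each vocabulary tag the likelihood ``v`` is the annotation's
    reported value if the tag is present and 0 otherwise (an unreported
    tag carries no positive evidence), so absent tags contribute their
    ``p_neg``.  Annotation tags outside the vocabulary are ignored.
    """
    p_pos, p_neg = table.arrays(vocab)
    v = np.zeros(len(vocab))
    lik = dict(ann.tags)
    for i, tag in enumerate(vocab.tags):
        if tag in lik:
            v[i] = lik[tag]
    values = p_pos * v + p_neg * (1.0 - v)
    return FeatureVector(image_id=ann.image_id, values=values)


def featurize_dataset(
    data: LabeledDataset, table: ConditionalTable, vocab: TagVocabulary
) -> pd.DataFrame:
    """Feature matrix for a dataset: image_id index, one column per vocab tag.

    A ``label`` column is appended with the ground-truth class.
    """
    rows = [featurize(ann, table, vocab).values for ann, _ in data]
    X = np.vstack(rows) if rows else np.empty((0, len(vocab)))
    df = pd.DataFrame(X, columns=list(vocab.tags),
                      index=pd.Index([a.image_id for a, _ in data], name="image_id"))
    df["label"] = data.labels
    return df
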