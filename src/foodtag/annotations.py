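"""Tag-annotation data model and I/O.

A wearable camera produces image streams that an upstream annotation
network describes with textual tags, each carrying a likelihood value
``v`` in [0, 1] -- the annotator's confidence that the tag correctly
describes the image.  This module holds the in-memory containers for
those annotations (with binary Food / Non-food ground truth), reads and
writes them as JSON Lines, and provides the dataset plumbing every
experiment needs: random train/test splitting and majority-class
downsampling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

DEFAULT_MAX_TAGS = 200

__all__ = [
    "TagAnnotation",
    "LabeledDataset",
    "AnnotationParseError",
    "load_annotations",
    "save_annotations",
    "split_dataset",
    "balance_downsample",
    "DEFAULT_MAX_TAGS",
]


class AnnotationParseError(ValueError):
    """Raised when an annotation file contains a malformed record."""


@dataclass(frozen=True)
class TagAnnotation:
    """One image's ordered list of ``(tag, likelihood)`` pairs.

    Parameters
    ----------
    image_id : str
        Unique identifier of the image.
    tags : tuple of (str, float)
        Ordered annotation tags with likelihood values in [0, 1].
    """

    image_id: str
    tags: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "tags", tuple((str(t), float(v)) for t, v in self.tags))
        seen: set[str] = set()
        for tag, v in self.tags:
            if not 0.0 <= v <= 1.0:
                raise ValueError(
                    f"image {self.image_id!r}: likelihood {v} for tag {tag!r} "
                    "outside [0, 1]"
                )
            if tag in seen:
                raise ValueError(f"image {self.image_id!r}: duplicate tag {tag!r}")
            seen.add(tag)

    @property
    def tag_set(self) -> frozenset[str]:
        return frozenset(t for t, _ in self.tags)

    def likelihood(self, tag: str) -> float:
        """Likelihood of ``tag``, or 0.0 if the tag was not reported."""
        for t, v in self.tags:
            if t == tag:
                return v
        return 0.0

    def __len__(self) -> int:
        return len(self.tags)


@dataclass(frozen=True)
class LabeledDataset:
    """Annotations paired with binary labels (1 = Food, 0 = Non-food)."""

    items: tuple[tuple[TagAnnotation, int], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(self.items))
        seen: set[str] = set()
        for ann, label in self.items:
            if label not in (0, 1):
                raise ValueError(
                    f"image {ann.image_id!r}: label must be 0 or 1, got {label!r}"
                )
            if ann.image_id in seen:
                raise ValueError(f"duplicate image_id {ann.image_id!r}")
            seen.add(ann.image_id)

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self) -> Iterator[tuple[TagAnnotation, int]]:
        return iter(self.items)

    @property
    def annotations(self) -> tuple[TagAnnotation, ...]:
        return tuple(ann for ann, _ in self.items)

    @property
    def labels(self) -> np.ndarray:
        return np.array([lab for _, lab in self.items], dtype=int)

    def class_counts(self) -> tuple[int, int]:
        """Return ``(n_food, n_nonfood)``."""
        labels = self.labels
        return int((labels == 1).sum()), int((labels == 0).sum())

    def subset(self, indices: Sequence[int]) -> "LabeledDataset":
        return LabeledDataset(tuple(self.items[i] for i in indices))


def _parse_record(obj: dict, max_tags: int, lineno: int) -> tuple[TagAnnotation, int]:
    try:
        image_id = obj["image_id"]
        raw_tags = obj.get("tags", [])
        label = obj.get("label")
    except (TypeError, KeyError) as exc:
        raise AnnotationParseError(f"line {lineno}: missing field {exc}") from exc
    if label is None:
        raise AnnotationParseError(f"line {lineno}: record has no label")
    if len(raw_tags) > max_tags:
        raise AnnotationParseError(
            f"line {lineno}: {len(raw_tags)} tags exceeds cap of {max_tags}"
        )
    try:
        tags = tuple((d["tag"], d["likelihood"]) for d in raw_tags)
        ann = TagAnnotation(image_id=str(image_id), tags=tags)
    except (TypeError, KeyError, ValueError) as exc:
        raise AnnotationParseError(f"line {lineno}: {exc}") from exc
    if label not in (0, 1):
        raise AnnotationParseError(f"line {lineno}: label must be 0 or 1, got {label!r}")
    return ann, int(label)


def load_annotations(path: str | Path, max_tags: int = DEFAULT_MAX_TAGS) -> LabeledDataset:
    """Load a labeled dataset from a JSON Lines annotation file.

    Each line is one image:
    ``{"image_id": str, "label": 0|1, "tags": [{"tag": str, "likelihood": float}, ...]}``.
    Tag order in the file is preserved.

    Raises
    ------
    AnnotationParseError
        On malformed JSON, missing fields, out-of-range likelihoods or
        duplicate tags, naming the offending line.
    """
    items: list[tuple[TagAnnotation, int]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise AnnotationParseError(f"line {lineno}: invalid JSON ({exc.msg})") from exc
            items.append(_parse_record(obj, max_tags, lineno))
    return LabeledDataset(tuple(items))


def save_annotations(data: LabeledDataset, path: str | Path) -> None:
    """Write a dataset as JSON Lines, preserving tag order and likelihoods."""
    with open(path, "w", encoding="utf-8") as fh:
        for ann, label in data:
            obj = {
                "image_id": ann.image_id,
                "label": label,
                "tags": [{"tag": t, "likelihood": v} for t, v in ann.tags],
            }
            fh.write(json.dumps(obj) + "\n")


def split_dataset(
    data: LabeledDataset, train_fraction: float, seed: int
) -> tuple[LabeledDataset, LabeledDataset]:
    """Randomly partition a dataset into train and test sets.

    The train size is ``round(train_fraction * N)`` with half-up rounding
    (ties go to the training set).  The partition is exhaustive, disjoint
    and reproducible for a fixed seed.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    if len(data) == 0:
        raise ValueError("cannot split an empty dataset")
    n = len(data)
    n_train = int(np.floor(train_fraction * n + 0.5))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return data.subset(sorted(perm[:n_train])), data.subset(sorted(perm[n_train:]))


def balance_downsample(data: LabeledDataset, seed: int) -> LabeledDataset:
    """Downsample the majority class to the minority-class count.

    Majority-class items are removed at random without replacement;
    minority-class items are untouched.  The returned dataset keeps the
    original item order.  Raises ``ValueError`` if either class is absent.
    """
    labels = data.labels
    n_pos, n_neg = data.class_counts()
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to balance")
    if n_pos == n_neg:
        return data
    majority = 1 if n_pos > n_neg else 0
    n_keep = min(n_pos, n_neg)
    maj_idx = np.flatnonzero(labels == majority)
    rng = np.random.default_rng(seed)
    kept_maj = set(rng.choice(maj_idx, size=n_keep, replace=False).tolist())
    keep = [i for i in range(len(data)) if labels[i] != majority or i in kept_maj]
    return data.subset(keep)
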