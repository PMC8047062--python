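"""Tag-frequency histogram and coverage-based vocabulary selection.

The upstream annotator can emit thousands of distinct tags across a
corpus, far too many to use as a feature dimension when training sets
number only a few thousand images.  The feature vocabulary is therefore
restricted to the most frequent tags: those whose cumulative occurrence
count reaches a configured fraction (default 50%) of all tag
occurrences in the training corpus.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

from .annotations import LabeledDataset

DEFAULT_COVERAGE = 0.5

__all__ = [
    "TagHistogram",
    "TagVocabulary",
    "build_histogram",
    "select_by_coverage",
    "DEFAULT_COVERAGE",
]


@dataclass(frozen=True)
class TagHistogram:
    """Occurrence counts: number of images whose annotation contains each tag."""

    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __len__(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class TagVocabulary:
    """Ordered feature vocabulary; position defines the feature index."""

    tags: tuple[str, ...]
    source_total: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "tags", tuple(self.tags))
        if len(set(self.tags)) != len(self.tags):
            raise ValueError("vocabulary tags must be unique")

    def __len__(self) -> int:
        return len(self.tags)

    def __contains__(self, tag: str) -> bool:
        return tag in set(self.tags)

    def index(self, tag: str) -> int:
        return self.tags.index(tag)

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"tags": list(self.tags), "source_total": self.source_total}, fh)

    @classmethod
    def load(cls, path: str | Path) -> "TagVocabulary":
        with open(path, "r", encoding="utf-8") as fh:
            obj = json.load(fh)
        return cls(tags=tuple(obj["tags"]), source_total=int(obj["source_total"]))


def build_histogram(train: LabeledDataset) -> TagHistogram:
    """Count, for each tag, the number of images containing it.

    Presence counting only: likelihood values do not weight the counts,
    and a tag appears at most once per image.
    """
    counter: Counter[str] = Counter()
    for ann, _ in train:
        counter.update(ann.tag_set)
    return TagHistogram(counts=dict(counter))


def select_by_coverage(hist: TagHistogram, coverage: float = DEFAULT_COVERAGE) -> TagVocabulary:
    """Select the minimal count-descending tag prefix reaching the coverage.

    Tags are sorted by count descending with lexicographic tie-break, and
    the shortest prefix whose cumulative count is at least
    ``coverage * total`` is returned.
    """
    if not 0.0 < coverage <= 1.0:
        raise ValueError(f"coverage must be in (0, 1], got {coverage}")
    if len(hist) == 0:
        raise ValueError("histogram is empty")
    ordered = sorted(hist.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    total = hist.total
    target = coverage * total
    cum = 0
    selected: list[str] = []
    for tag, count in ordered:
        selected.append(tag)
        cum += count
        if cum >= target:
            break
    return TagVocabulary(tags=tuple(selected), source_total=total)
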