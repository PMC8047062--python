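"""Synthetic tag-annotation corpora with known class-conditional statistics.

The upstream annotator is an external black box and field image corpora
are not redistributable, so experiments are driven by a generator that
emulates the annotator's output with fully known ground truth.  Each
image's label is Bernoulli(prevalence); given the label, every tag is
reported independently with its class-conditional presence probability
(``q_food`` when the image is Food, ``q_nonfood`` otherwise), and a
present tag receives a likelihood drawn from a Beta distribution
(default concentrated near 0.9, mirroring an annotator that reports
only confident tags).  Tag presence is independent across tags given
the class, which makes the conditional probabilities analytically
available via Bayes' rule -- ``analytic_conditionals`` is the exact
oracle the estimator is checked against.

Not emulated: tag co-occurrence structure, annotator calibration error,
and any pixel-level content.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotations import DEFAULT_MAX_TAGS, LabeledDataset, TagAnnotation
from .interface import ConditionalTable, TagConditional

__all__ = [
    "TagSpec",
    "SyntheticConfig",
    "generate",
    "analytic_conditionals",
    "informative_config",
    "uninformative_config",
    "recovery_config",
    "realistic_config",
]


@dataclass(frozen=True)
class TagSpec:
    """Class-conditional statistics of one synthetic tag.

    ``likelihood_shape`` are the (a, b) parameters of the Beta
    distribution the likelihood is drawn from when the tag is present.
    """

    name: str
    q_food: float
    q_nonfood: float
    likelihood_shape: tuple[float, float] = (9.0, 1.0)

    def __post_init__(self) -> None:
        for nm, q in (("q_food", self.q_food), ("q_nonfood", self.q_nonfood)):
            if not 0.0 <= q <= 1.0:
                raise ValueError(f"{self.name}: {nm}={q} outside [0, 1]")
        a, b = self.likelihood_shape
        if a <= 0 or b <= 0:
            raise ValueError(f"{self.name}: Beta parameters must be positive")


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters defining a labeled synthetic corpus."""

    n_images: int
    prevalence: float
    tag_specs: tuple[TagSpec, ...]
    max_tags: int = DEFAULT_MAX_TAGS
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "tag_specs", tuple(self.tag_specs))
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")
        names = [s.name for s in self.tag_specs]
        if len(set(names)) != len(names):
            raise ValueError("tag names must be unique")


def generate(cfg: SyntheticConfig) -> LabeledDataset:
    """Draw a labeled corpus from the configured class-conditional model.

    Reproducible for a fixed ``cfg.seed``.  If more than ``max_tags``
    tags are present on one image, the most confident ones are kept.
    Present tags are listed in descending likelihood order, as an
    annotator would rank them.
    """
    rng = np.random.default_rng(cfg.seed)
    n_tags = len(cfg.tag_specs)
    labels = (rng.random(cfg.n_images) < cfg.prevalence).astype(int)
    q_food = np.array([s.q_food for s in cfg.tag_specs])
    q_nonfood = np.array([s.q_nonfood for s in cfg.tag_specs])
    a = np.array([s.likelihood_shape[0] for s in cfg.tag_specs])
    b = np.array([s.likelihood_shape[1] for s in cfg.tag_specs])
    names = [s.name for s in cfg.tag_specs]

    q = np.where(labels[:, None] == 1, q_food[None, :], q_nonfood[None, :])
    present = rng.random((cfg.n_images, n_tags)) < q
    lik = rng.beta(a[None, :], b[None, :], size=(cfg.n_images, n_tags))

    items = []
    width = len(str(cfg.n_images))
    for i in range(cfg.n_images):
        idx = np.flatnonzero(present[i])
        order = idx[np.argsort(-lik[i, idx], kind="stable")]
        order = order[: cfg.max_tags]
        tags = tuple((names[j], float(lik[i, j])) for j in order)
        items.append((TagAnnotation(image_id=f"img{i:0{width}d}", tags=tags),
                      int(labels[i])))
    return LabeledDataset(tuple(items))


def analytic_conditionals(cfg: SyntheticConfig) -> ConditionalTable:
    """Exact conditional food probabilities implied by the generator.

    By Bayes' rule, with prevalence pi and presence probabilities
    ``q_F``, ``q_N``::

        p_pos = pi*q_F / (pi*q_F + (1-pi)*q_N)
        p_neg = pi*(1-q_F) / (pi*(1-q_F) + (1-pi)*(1-q_N))

    Supporting counts are set to 0 (these are population values, not
    sample estimates).  Raises if a tag is present in both classes
    always or never, where a conditional is undefined.
    """
    pi = cfg.prevalence
    entries: dict[str, TagConditional] = {}
    for s in cfg.tag_specs:
        d_pos = pi * s.q_food + (1 - pi) * s.q_nonfood
        d_neg = pi * (1 - s.q_food) + (1 - pi) * (1 - s.q_nonfood)
        if d_pos == 0 or d_neg == 0:
            raise ZeroDivisionError(
                f"tag {s.name!r}: presence probability is degenerate "
                "(tag always or never present); conditional undefined"
            )
        entries[s.name] = TagConditional(
            p_pos=pi * s.q_food / d_pos,
            p_neg=pi * (1 - s.q_food) / d_neg,
            n_with=0, n_without=0,
        )
    return ConditionalTable(entries=entries, smoothing=0.0)


def informative_config(
    n_images: int = 2000,
    prevalence: float = 0.5,
    n_diagnostic: int = 6,
    n_noise: int = 20,
    seed: int = 0,
) -> SyntheticConfig:
    """Corpus with strongly diagnostic tags (q_food >= 0.8, q_nonfood <= 0.2).

    Near-deterministic tag-class coupling: a pipeline trained on it
    should reach sensitivity and specificity well above 0.95.
    """
    specs = [
        TagSpec(name="food", q_food=0.9, q_nonfood=0.1),
    ]
    for i in range(1, n_diagnostic):
        specs.append(TagSpec(name=f"diag{i:02d}", q_food=0.85, q_nonfood=0.15))
    for i in range(n_noise):
        specs.append(TagSpec(name=f"noise{i:02d}", q_food=0.3, q_nonfood=0.3))
    return SyntheticConfig(n_images=n_images, prevalence=prevalence,
                           tag_specs=tuple(specs), seed=seed)


def uninformative_config(
    n_images: int = 5000,
    prevalence: float = 0.5,
    n_tags: int = 20,
    seed: int = 0,
) -> SyntheticConfig:
    """All tags independent of the class: chance-level discrimination."""
    specs = [
        TagSpec(name=f"tag{i:02d}", q_food=0.4, q_nonfood=0.4)
        for i in range(n_tags)
    ]
    return SyntheticConfig(n_images=n_images, prevalence=prevalence,
                           tag_specs=tuple(specs), seed=seed)


def recovery_config(n_images: int = 10000, seed: int = 0) -> SyntheticConfig:
    """Benchmark corpus for conditional-probability recovery.

    Tags span the diagnostic spectrum from strongly food-leaning to
    strongly non-food-leaning, with complementary presence
    probabilities (``q_food + q_nonfood = 1``) at prevalence 0.5 so
    that every tag is present in about half the corpus and both
    conditionals are estimated from comparable sample sizes.
    """
    pairs = [(0.9, 0.1), (0.85, 0.15), (0.8, 0.2), (0.6, 0.4),
             (0.5, 0.5), (0.4, 0.6), (0.2, 0.8), (0.15, 0.85)]
    specs = tuple(
        TagSpec(name=f"tag{i:02d}", q_food=qf, q_nonfood=qn)
        for i, (qf, qn) in enumerate(pairs)
    )
    return SyntheticConfig(n_images=n_images, prevalence=0.5,
                           tag_specs=specs, seed=seed)


def realistic_config(
    n_images: int = 10000,
    prevalence: float = 0.14,
    n_tags: int = 300,
    seed: int = 0,
) -> SyntheticConfig:
    """Power-law tag-frequency corpus emulating field conditions.

    About 300 tags whose base presence probabilities follow a power law
    (so vocabulary selection at 50% coverage keeps only a head subset),
    a Food prevalence around 14% matching a field corpus where eating
    events are a small share of daily images, and a mix of food-leaning,
    non-food-leaning and neutral tags.  The explicit ``"food"`` tag is
    strongly food-leaning so that the annotator-only threshold baseline
    is exercised.
    """
    rng = np.random.default_rng(seed + 987654)
    ranks = np.arange(1, n_tags + 1)
    base = 0.6 * ranks ** -0.7  # head tags common, tail rare
    specs: list[TagSpec] = []
    for i in range(n_tags):
        p = float(base[i])
        r = rng.random()
        if i == 0:
            # the explicit food tag
            specs.append(TagSpec(name="food", q_food=0.85, q_nonfood=0.08))
            continue
        if r < 0.15:  # food-leaning
            boost = rng.uniform(2.0, 5.0)
            q_f = min(1.0, p * boost)
            q_n = p * rng.uniform(0.2, 0.6)
        elif r < 0.30:  # non-food-leaning
            boost = rng.uniform(2.0, 5.0)
            q_f = p * rng.uniform(0.2, 0.6)
            q_n = min(1.0, p * boost)
        else:  # neutral
            q_f = q_n = p
        specs.append(TagSpec(name=f"tag{i:03d}", q_food=q_f, q_nonfood=q_n))
    return SyntheticConfig(n_images=n_images, prevalence=prevalence,
                           tag_specs=tuple(specs), seed=seed)
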