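import pytest

from foodtag.annotations import LabeledDataset, TagAnnotation


def make_dataset(records):
    """records: list of (image_id, label, {tag: likelihood})."""
    items = []
    for image_id, label, tags in records:
        ann = TagAnnotation(image_id=image_id, tags=tuple(tags.items()))
        items.append((ann, label))
    return LabeledDataset(tuple(items))


@pytest.fixture
def small_corpus():
    """Four images, two per class; tag 'x' in 3 of them (2 food, 1 non-food)."""
    return make_dataset([
        ("a", 1, {"x": 0.9, "y": 0.5}),
        ("b", 1, {"x": 0.8}),
        ("c", 0, {"x": 0.7, "z": 0.6}),
        ("d", 0, {"z": 0.4}),
    ])
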