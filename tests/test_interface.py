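import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from foodtag.interface import (
    estimate_conditionals,
    featurize,
    featurize_dataset,
    food_prediction_power,
)
from foodtag.vocabulary import TagVocabulary
from .conftest import make_dataset

unit = st.floats(min_value=0.0, max_value=1.0)


def brute_force_conditionals(data, tag):
    """Independent counting oracle for the unsmoothed conditional estimates."""
    with_tag = [(ann, lab) for ann, lab in data if tag in ann.tag_set]
    without = [(ann, lab) for ann, lab in data if tag not in ann.tag_set]
    p_pos = sum(lab for _, lab in with_tag) / len(with_tag)
    p_neg = sum(lab for _, lab in without) / len(without)
    return p_pos, p_neg


class TestEstimateConditionals:
    def test_hand_counted_ratios(self, small_corpus):
        vocab = TagVocabulary(("x",), source_total=3)
        table = estimate_conditionals(small_corpus, vocab, alpha=0)
        assert table["x"].p_pos == pytest.approx(2 / 3)
        assert table["x"].p_neg == 0.0
        assert table["x"].n_with == 3
        assert table["x"].n_without == 1

    def test_independent_tag_gives_half(self):
        # balanced 4-image corpus, tag 'u' present in one image per class
        data = make_dataset([
            ("a", 1, {"u": 0.9}), ("b", 1, {}),
            ("c", 0, {"u": 0.9}), ("d", 0, {}),
        ])
        table = estimate_conditionals(data, TagVocabulary(("u",), 2), alpha=0)
        assert table["u"].p_pos == 0.5
        assert table["u"].p_neg == 0.5

    def test_ubiquitous_tag(self):
        data = make_dataset([("a", 1, {"t": 0.9}), ("b", 0, {"t": 0.8})])
        vocab = TagVocabulary(("t",), 2)
        with pytest.raises(ZeroDivisionError, match="alpha"):
            estimate_conditionals(data, vocab, alpha=0)
        table = estimate_conditionals(data, vocab, alpha=1)
        assert table["t"].p_neg == 0.5  # (0+1)/(0+2)

    def test_counts_partition_training_set(self, small_corpus):
        vocab = TagVocabulary(("x", "z"), 5)
        table = estimate_conditionals(small_corpus, vocab, alpha=1)
        for tag in vocab.tags:
            assert table[tag].n_with + table[tag].n_without == len(small_corpus)

    def test_matches_brute_force_on_random_corpora(self):
        rng = np.random.default_rng(1234)
        tags = ["a", "b", "c", "d"]
        for _ in range(100):
            n = rng.integers(4, 21)
            recs = []
            for i in range(n):
                present = {t: 0.5 for t in tags if rng.random() < 0.5}
                recs.append((f"i{i}", int(rng.random() < 0.5), present))
            data = make_dataset(recs)
            labels = data.labels
            if labels.min() == labels.max():
                continue
            usable = [t for t in tags
                      if 0 < sum(t in a.tag_set for a, _ in data) < n]
            if not usable:
                continue
            table = estimate_conditionals(data, TagVocabulary(tuple(usable), 1), alpha=0)
            for t in usable:
                p_pos, p_neg = brute_force_conditionals(data, t)
                assert table[t].p_pos == pytest.approx(p_pos)
                assert table[t].p_neg == pytest.approx(p_neg)


class TestFoodPredictionPower:
    def test_endpoints(self):
        assert food_prediction_power(1.0, 0.7, 0.2) == pytest.approx(0.7)
        assert food_prediction_power(0.0, 0.7, 0.2) == pytest.approx(0.2)

    def test_midpoint(self):
        assert food_prediction_power(0.5, 0.8, 0.2) == pytest.approx(0.5)

    @pytest.mark.parametrize("kwargs", [
        {"v": 1.2, "p_pos": 0.5, "p_neg": 0.5},
        {"v": 0.5, "p_pos": -0.1, "p_neg": 0.5},
        {"v": 0.5, "p_pos": 0.5, "p_neg": 2.0},
    ])
    def test_domain_checks(self, kwargs):
        with pytest.raises(ValueError):
            food_prediction_power(**kwargs)

    @settings(max_examples=200, deadline=None)
    @given(v1=unit, v2=unit, lam=unit, p_pos=unit, p_neg=unit)
    def test_affine_in_likelihood(self, v1, v2, lam, p_pos, p_neg):
        v = lam * v1 + (1 - lam) * v2
        lhs = food_prediction_power(v, p_pos, p_neg)
        rhs = (lam * food_prediction_power(v1, p_pos, p_neg)
               + (1 - lam) * food_prediction_power(v2, p_pos, p_neg))
        assert lhs == pytest.approx(rhs, abs=1e-12)

    @settings(max_examples=200, deadline=None)
    @given(v1=unit, v2=unit, p_pos=unit, p_neg=unit)
    def test_monotone_iff_positively_diagnostic(self, v1, v2, p_pos, p_neg):
        lo, hi = sorted([v1, v2])
        d = (food_prediction_power(hi, p_pos, p_neg)
             - food_prediction_power(lo, p_pos, p_neg))
        if p_pos > p_neg:
            assert d >= 0
        elif p_pos == p_neg:
            assert d == pytest.approx(0, abs=1e-12)
        else:
            assert d <= 0

    @settings(max_examples=100, deadline=None)
    @given(v=unit, p_pos=unit, p_neg=unit)
    def test_total_probability_decomposition(self, v, p_pos, p_neg):
        # joint form P(Food, T=1) + P(Food, T=0) equals the conditional form
        joint = p_pos * v + p_neg * (1 - v)
        assert food_prediction_power(v, p_pos, p_neg) == pytest.approx(joint)


class TestFeaturize:
    @pytest.fixture
    def fitted(self, small_corpus):
        vocab = TagVocabulary(("x", "z"), 5)
        table = estimate_conditionals(small_corpus, vocab, alpha=1)
        return vocab, table

    def test_absent_tag_contributes_p_neg(self, fitted, small_corpus):
        vocab, table = fitted
        ann = small_corpus.items[3][0]  # image "d": only tag z
        fv = featurize(ann, table, vocab)
        assert fv.values[0] == pytest.approx(table["x"].p_neg)

    def test_vector_aligned_to_vocabulary(self, fitted, small_corpus):
        vocab, table = fitted
        ann = small_corpus.items[0][0]  # image "a": x=0.9, y=0.5
        fv = featurize(ann, table, vocab)
        assert len(fv) == len(vocab)
        expected_x = table["x"].p_pos * 0.9 + table["x"].p_neg * 0.1
        assert fv.values[0] == pytest.approx(expected_x)

    def test_out_of_vocabulary_tags_ignored(self, fitted):
        vocab, table = fitted
        data = make_dataset([("q", 0, {"unseen1": 0.9, "unseen2": 0.99})])
        fv = featurize(data.items[0][0], table, vocab)
        expected = np.array([table[t].p_neg for t in vocab.tags])
        np.testing.assert_allclose(fv.values, expected)

    def test_dataset_matrix_shape_and_labels(self, fitted, small_corpus):
        vocab, table = fitted
        df = featurize_dataset(small_corpus, table, vocab)
        assert df.shape == (4, 3)  # 2 features + label
        assert list(df.columns[:-1]) == list(vocab.tags)
        assert df["label"].tolist() == [1, 1, 0, 0]
        vals = df.drop(columns="label").to_numpy()
        assert ((vals >= 0) & (vals <= 1)).all()
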