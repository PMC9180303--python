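"""Tests for annotation aggregation: categories, tags, faces, words."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from visrep import (
    CATEGORIES,
    EMOTIONS,
    STOP_WORDS,
    AnnotationBundle,
    category_frequencies,
    face_feature_table,
    face_photo_features,
    implied_male_mean,
    mean_tag_confidence,
    summarize_faces,
    tokenize_and_filter,
    word_frequency_table,
)
from visrep.annotations import FaceRecord


def bundle(pid="p0", category="people", tags=(), faces=(), words=(), likes=0, sentiments=()):
    return AnnotationBundle(
        photo_id=pid,
        category=category,
        tags=list(tags),
        faces=list(faces),
        words=list(words),
        likes=likes,
        comment_sentiments=list(sentiments),
    )


def face(box=(0, 0, 10, 10), age=30.0, is_female=True, happy=0.5):
    emotions = [0.0] * len(EMOTIONS)
    emotions[EMOTIONS.index("happiness")] = happy
    emotions[EMOTIONS.index("neutral")] = 1.0 - happy
    return FaceRecord(box=box, age=age, is_female=is_female, emotions=tuple(emotions))


class TestCategories:
    def test_counts_zero_filled_over_vocabulary(self):
        freq = category_frequencies(
            [bundle("a", "people"), bundle("b", "people"), bundle("c", "text")]
        )
        assert freq["people"] == 2
        assert freq["text"] == 1
        assert freq["others"] == 0
        assert set(freq.index) == set(CATEGORIES)
        assert freq.sum() == 3

    def test_empty_corpus_all_zero(self):
        freq = category_frequencies([])
        assert (freq == 0).all()

    def test_unknown_category_names_the_photo(self):
        with pytest.raises(ValueError, match="weird"):
            category_frequencies([bundle("weird", category="selfie")])


class TestTagConfidence:
    def test_present_only_vs_all_photos_denominators(self):
        bundles = [
            bundle("a", tags=[("person", 0.9)]),
            bundle("b", tags=[("person", 0.7)]),
            bundle("c", tags=[("sky", 0.8)]),
        ]
        present = mean_tag_confidence(bundles, "present_only")
        assert present.set_index("tag").loc["person", "mean_confidence"] == pytest.approx(0.8)
        everyone = mean_tag_confidence(bundles, "all_photos")
        assert everyone.set_index("tag").loc["person", "mean_confidence"] == pytest.approx(
            1.6 / 3
        )

    def test_single_photo_single_tag(self):
        table = mean_tag_confidence([bundle("a", tags=[("mask", 0.42)])])
        assert table.loc[0, "tag"] == "mask"
        assert table.loc[0, "mean_confidence"] == pytest.approx(0.42)

    def test_top_n_truncates_ranked_output(self):
        bundles = [bundle("a", tags=[("x", 0.9), ("y", 0.5), ("z", 0.7)])]
        table = mean_tag_confidence(bundles, top_n=2)
        assert list(table["tag"]) == ["x", "z"]


class TestFaceFeatures:
    def test_closeup_and_face_ratio_hand_computed(self):
        b = bundle(faces=[face(box=(0, 0, 200, 200)), face(box=(300, 300, 100, 100))])
        feats = face_photo_features(b, (1000, 1000))
        assert feats.closeup == pytest.approx(0.04)
        assert feats.face_ratio == pytest.approx(0.05)

    def test_age_mean_and_female_count(self):
        b = bundle(faces=[face(age=20, is_female=True), face(age=40, is_female=False)])
        feats = face_photo_features(b, (100, 100))
        assert feats.age == pytest.approx(30.0)
        assert feats.gender == 1
        assert feats.number_of_faces == 2

    def test_faceless_photo_all_zero(self):
        feats = face_photo_features(bundle(), (100, 100))
        assert feats.number_of_faces == 0
        assert feats.closeup == 0.0 and feats.face_ratio == 0.0
        assert feats.age == 0.0 and feats.gender == 0
        assert all(getattr(feats, e) == 0.0 for e in EMOTIONS)

    def test_box_outside_image_rejected(self):
        b = bundle(faces=[face(box=(90, 90, 20, 20))])
        with pytest.raises(ValueError, match="outside"):
            face_photo_features(b, (100, 100))

    def test_closeup_never_exceeds_face_ratio(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(1, 4))
            faces = [
                face(box=(int(rng.integers(0, 50)), int(rng.integers(0, 50)),
                          int(rng.integers(1, 40)), int(rng.integers(1, 40))))
                for _ in range(n)
            ]
            feats = face_photo_features(bundle(faces=faces), (100, 100))
            assert feats.closeup <= feats.face_ratio + 1e-12
            assert feats.gender <= feats.number_of_faces


class TestFaceSummary:
    def test_male_mean_identity(self):
        assert implied_male_mean(1.441, 0.855) == pytest.approx(0.586, abs=1e-12)

    def test_single_face_photo_summary(self):
        table = face_feature_table([bundle(faces=[face(age=25)])], (100, 100))
        summary = summarize_faces(table, "face_photos_only")
        assert summary.loc["age", "mean"] == pytest.approx(25.0)
        assert summary.loc["age", "sd"] == 0.0
        assert summary.attrs["n_photos"] == 1

    def test_zero_imputation_only_lowers_face_mean(self):
        bundles = [bundle("a", faces=[face(), face()]), bundle("b")]
        table = face_feature_table(bundles, (100, 100))
        only = summarize_faces(table, "face_photos_only")
        everyone = summarize_faces(table, "all_photos")
        assert (
            only.loc["number_of_faces", "mean"]
            >= everyone.loc["number_of_faces", "mean"]
        )

    def test_empty_selection_marked(self):
        table = face_feature_table([bundle("a")], (100, 100))
        summary = summarize_faces(table, "face_photos_only")
        assert summary.attrs["empty"] is True
        assert summary.attrs["n_photos"] == 0


class TestWordPipeline:
    def test_lowercase_and_edge_punctuation(self):
        assert tokenize_and_filter(["The", "Mask,", "the", "MASK!"]) == ["mask", "mask"]

    def test_no_is_not_a_stop_word_and_urls_drop(self):
        assert tokenize_and_filter(["No", "mask", "http://x.co"]) == ["no", "mask"]
        assert tokenize_and_filter(["WWW.example.com", "HTTPS://a.b/c"]) == []

    def test_pure_stop_word_input_empties(self):
        assert tokenize_and_filter(["a", "the", "0", "•"]) == []

    def test_internal_apostrophe_survives(self):
        assert tokenize_and_filter(["Don't!"]) == ["don't"]

    def test_interior_separators_split(self):
        assert tokenize_and_filter(["covid-19", "mask/face"]) == [
            "covid", "19", "mask", "face",
        ]

    def test_exact_stop_list_is_applied_verbatim(self):
        expected = {
            "a", "about", "am", "an", "and", "are", "as", "at", "be", "by",
            "but", "de", "e", "for", "from", "in", "is", "it", "la", "o",
            "of", "on", "or", "so", "that", "the", "this", "to", "up",
            "was", "•", "0", "1", "2",
        }
        assert set(STOP_WORDS) == expected
        assert tokenize_and_filter(sorted(expected)) == []

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.text(alphabet=st.characters(codec="ascii"), max_size=12), max_size=20))
    def test_filter_is_idempotent(self, raw):
        once = tokenize_and_filter(raw)
        assert tokenize_and_filter(once) == once

    def test_frequency_table_and_per_photo_counts(self):
        bundles = [
            bundle("a", words=["mask"]),
            bundle("b", words=["mask", "no"]),
        ]
        table, counts = word_frequency_table(bundles)
        assert table.values.tolist() == [["mask", 2], ["no", 1]]
        assert counts.to_dict() == {"a": 1, "b": 2}

    def test_frequency_ties_break_alphabetically(self):
        table, _ = word_frequency_table([bundle("a", words=["zebra", "apple"])])
        assert list(table["word"]) == ["apple", "zebra"]

    def test_top_n_larger_than_vocabulary_returns_all(self):
        table, _ = word_frequency_table([bundle("a", words=["mask"])], top_n=99)
        assert len(table) == 1

    def test_empty_corpus_empty_table(self):
        table, counts = word_frequency_table([])
        assert len(table) == 0 and len(counts) == 0


class TestBundleValidation:
    def test_confidence_and_sentiment_bounds_enforced(self):
        b = bundle(tags=[("mask", 1.2)])
        with pytest.raises(ValueError, match="confidence"):
            b.validate()
        b = bundle(sentiments=[2.0])
        with pytest.raises(ValueError, match="sentiment"):
            b.validate()

    def test_emotion_simplex_enforced(self):
        bad = FaceRecord(box=(0, 0, 1, 1), age=30, is_female=False,
                         emotions=(0.5,) * 8)
        with pytest.raises(ValueError, match="sum to 1"):
            bad.validate()
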