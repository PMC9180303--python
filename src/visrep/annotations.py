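"""Per-photo annotation types and corpus-level aggregation.

Covers the content, face and in-photo-word summaries of a hashtag photo
corpus: content-category frequencies over a fixed 15-class vocabulary,
mean tag-confidence rankings, per-photo facial features (face count,
closeup, face ratio, age, female count, eight emotion-class means) and
their corpus/cluster summaries, and the word-cleaning / frequency
pipeline (lowercasing, URL and punctuation removal, a fixed stop-word
list).
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORIES",
    "EMOTIONS",
    "STOP_WORDS",
    "AnnotationBundle",
    "FaceRecord",
    "FacePhotoFeatures",
    "FACE_FEATURE_COLUMNS",
    "category_frequencies",
    "mean_tag_confidence",
    "face_photo_features",
    "face_feature_table",
    "summarize_faces",
    "implied_male_mean",
    "tokenize_and_filter",
    "word_frequency_table",
]

#: The fixed 15-class content-category vocabulary.
CATEGORIES = (
    "abstract", "animal", "building", "dark", "drink", "food", "indoor",
    "others", "outdoor", "people", "plant", "object", "sky", "text",
    "transportation",
)

#: The eight emotion classes, in reporting order.
EMOTIONS = (
    "anger", "contempt", "disgust", "fear", "happiness", "sadness",
    "surprise", "neutral",
)

#: Exact stop-word list applied to in-photo words after lowercasing.
STOP_WORDS = frozenset(
    {
        "a", "about", "am", "an", "and", "are", "as", "at", "be", "by",
        "but", "de", "e", "for", "from", "in", "is", "it", "la", "o",
        "of", "on", "or", "so", "that", "the", "this", "to", "up", "was",
        "•", "0", "1", "2",
    }
)

_URL_RE = re.compile(r"^(https?://|www\.)", re.IGNORECASE)
_SPLIT_RE = re.compile(r"[^a-z0-9']+")


@dataclass
class FaceRecord:
    """One detected face: bounding box, demographics, emotion scores."""

    box: tuple[int, int, int, int]  # (x, y, width, height), origin top-left
    age: float
    is_female: bool
    emotions: tuple[float, ...]  # 8 scores in EMOTIONS order, summing to 1

    def validate(self) -> None:
        if len(self.emotions) != len(EMOTIONS):
            raise ValueError("expected 8 emotion scores")
        if any(not 0.0 <= e <= 1.0 for e in self.emotions):
            raise ValueError("emotion scores must lie in [0, 1]")
        if abs(sum(self.emotions) - 1.0) > 1e-6:
            raise ValueError("emotion scores must sum to 1")


@dataclass
class AnnotationBundle:
    """All service-style annotations for one photo."""

    photo_id: str
    category: str
    tags: list[tuple[str, float]]
    faces: list[FaceRecord]
    words: list[str]
    likes: int
    comment_sentiments: list[float]

    def validate(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(
                f"photo {self.photo_id!r}: unknown category {self.category!r}"
            )
        for tag, conf in self.tags:
            if not 0.0 < conf <= 1.0:
                raise ValueError(
                    f"photo {self.photo_id!r}: tag {tag!r} confidence {conf} not in (0, 1]"
                )
        for face in self.faces:
            face.validate()
        if self.likes < 0:
            raise ValueError(f"photo {self.photo_id!r}: negative likes")
        if any(not -1.0 <= s <= 1.0 for s in self.comment_sentiments):
            raise ValueError(f"photo {self.photo_id!r}: sentiment outside [-1, 1]")


@dataclass(frozen=True)
class FacePhotoFeatures:
    """The 13 per-photo facial features.

    ``gender`` is the count of female faces (not a proportion); ``closeup``
    is the area share of the largest face and ``face_ratio`` the summed
    area share of all faces. Photos without faces carry all-zero features.
    """

    number_of_faces: int
    closeup: float
    face_ratio: float
    age: float
    gender: int
    anger: float
    contempt: float
    disgust: float
    fear: float
    happiness: float
    sadness: float
    surprise: float
    neutral: float


FACE_FEATURE_COLUMNS = (
    "number_of_faces", "closeup", "face_ratio", "age", "gender", *EMOTIONS,
)


def category_frequencies(bundles) -> pd.Series:
    """Photo counts per content category, zero-filled over all 15 classes."""
    counts = dict.fromkeys(CATEGORIES, 0)
    for b in bundles:
        if b.category not in counts:
            raise ValueError(
                f"photo {b.photo_id!r}: unknown category {b.category!r}"
            )
        counts[b.category] += 1
    return pd.Series(counts, name="count")


def mean_tag_confidence(
    bundles, denominator: str = "present_only", top_n: int | None = None
) -> pd.DataFrame:
    """Per-tag mean confidence, ranked descending.

    ``present_only`` averages over photos carrying the tag; ``all_photos``
    divides the summed confidence by the corpus size.
    """
    if denominator not in ("present_only", "all_photos"):
        raise ValueError(f"unknown denominator {denominator!r}")
    sums: Counter = Counter()
    hits: Counter = Counter()
    n_photos = 0
    for b in bundles:
        n_photos += 1
        for tag, conf in b.tags:
            sums[tag] += conf
            hits[tag] += 1
    rows = []
    for tag in sums:
        denom = hits[tag] if denominator == "present_only" else n_photos
        rows.append((tag, sums[tag] / denom, hits[tag]))
    table = pd.DataFrame(rows, columns=["tag", "mean_confidence", "n_photos"])
    table = table.sort_values(
        ["mean_confidence", "tag"], ascending=[False, True]
    ).reset_index(drop=True)
    return table.head(top_n) if top_n is not None else table


def face_photo_features(
    bundle: AnnotationBundle, image_size: tuple[int, int]
) -> FacePhotoFeatures:
    """Per-photo facial features; all zeros when the photo has no faces."""
    h, w = image_size
    image_area = float(h * w)
    areas = []
    for f in bundle.faces:
        x, y, bw, bh = f.box
        if x < 0 or y < 0 or x + bw > w or y + bh > h:
            raise ValueError(
                f"photo {bundle.photo_id!r}: face box {f.box} outside {w}x{h} image"
            )
        areas.append(bw * bh / image_area)
    if not bundle.faces:
        return FacePhotoFeatures(0, 0.0, 0.0, 0.0, 0, *([0.0] * len(EMOTIONS)))
    emotion_means = np.mean([f.emotions for f in bundle.faces], axis=0)
    return FacePhotoFeatures(
        number_of_faces=len(bundle.faces),
        closeup=float(max(areas)),
        face_ratio=float(sum(areas)),
        age=float(np.mean([f.age for f in bundle.faces])),
        gender=int(sum(f.is_female for f in bundle.faces)),
        **{emo: float(emotion_means[i]) for i, emo in enumerate(EMOTIONS)},
    )


def face_feature_table(bundles, image_size: tuple[int, int]) -> pd.DataFrame:
    """Per-photo facial feature rows for a whole corpus, indexed by photo_id."""
    rows = {
        b.photo_id: face_photo_features(b, image_size).__dict__ for b in bundles
    }
    table = pd.DataFrame.from_dict(rows, orient="index", columns=FACE_FEATURE_COLUMNS)
    table.index.name = "photo_id"
    return table


def summarize_faces(
    features: pd.DataFrame, scope: str = "face_photos_only"
) -> pd.DataFrame:
    """Mean/SD summary of per-photo facial features.

    ``face_photos_only`` restricts to photos with at least one face (the
    corpus-level reporting convention); ``all_photos`` keeps zero-imputed
    faceless photos (the cluster-comparison convention). The summary also
    reports the implied male-face mean, number_of_faces mean minus the
    female-count (gender) mean. An empty selection yields an empty frame
    with ``attrs['empty'] = True``.
    """
    if scope == "face_photos_only":
        sel = features[features["number_of_faces"] >= 1]
    elif scope == "all_photos":
        sel = features
    else:
        raise ValueError(f"unknown scope {scope!r}")
    if len(sel) == 0:
        empty = pd.DataFrame(columns=["mean", "sd"])
        empty.attrs["empty"] = True
        empty.attrs["n_photos"] = 0
        return empty
    summary = pd.DataFrame(
        {"mean": sel.mean(), "sd": sel.std(ddof=0)},
        index=list(FACE_FEATURE_COLUMNS),
    )
    summary.attrs["empty"] = False
    summary.attrs["n_photos"] = int(len(sel))
    summary.attrs["male_mean"] = implied_male_mean(
        summary.loc["number_of_faces", "mean"], summary.loc["gender", "mean"]
    )
    return summary


def implied_male_mean(faces_mean: float, female_mean: float) -> float:
    """Mean male-face count implied by total and female means."""
    return float(faces_mean) - float(female_mean)


def tokenize_and_filter(raw_words) -> list[str]:
    """Clean raw in-photo words.

    Lowercase; drop URL tokens (http(s)://, www.); split on interior
    separators and strip edge punctuation (internal apostrophes survive,
    so "don't" is kept intact); drop tokens on the fixed stop-word list.
    """
    out: list[str] = []
    for raw in raw_words:
        token = str(raw).lower()
        if _URL_RE.match(token):
            continue
        for part in _SPLIT_RE.split(token):
            part = part.strip("'")
            if part and part not in STOP_WORDS:
                out.append(part)
    return out


def word_frequency_table(
    bundles, top_n: int | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Cleaned-token frequency ranking plus per-photo cleaned word counts.

    Ties in frequency are broken alphabetically. The per-photo count
    series feeds the between-cluster word comparison.
    """
    counter: Counter = Counter()
    per_photo = {}
    for b in bundles:
        tokens = tokenize_and_filter(b.words)
        counter.update(tokens)
        per_photo[b.photo_id] = len(tokens)
    table = pd.DataFrame(
        sorted(counter.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["word", "count"],
    )
    counts = pd.Series(per_photo, name="n_words", dtype=int)
    counts.index.name = "photo_id"
    if top_n is not None:
        table = table.head(top_n)
    return table, counts
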