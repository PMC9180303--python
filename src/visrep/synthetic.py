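"""Seeded synthetic photo corpus with two latent visual classes.

Stands in for a scraped hashtag photo corpus that cannot be
redistributed. Two ground-truth classes are generated:

* **text** — near-white, low-saturation backgrounds carrying dark
  horizontal glyph-like strokes (text-centered screenshots/memes);
* **people** — colorful sky/grass backgrounds with 1–3 skin-tone
  ellipses standing in for faces.

Each photo carries a service-style annotation bundle (content category,
tags with confidences, face records, in-photo words, likes, per-comment
sentiment scores) whose class-conditional distributions are calibrated
to the corpus statistics the downstream analysis is designed to detect:
words per photo 5.519 vs 0.398, mean comment sentiment 0.073 vs 0.198,
mean faces per face-bearing photo near 1.44 with a 0.6 female fraction,
and emotion scores concentrated on happiness/neutral.

Reproducibility: one root seed; each photo draws from a counter-derived
substream, so corpora are byte-identical for identical configs and
independent of generation order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image as PILImage

from .annotations import CATEGORIES, EMOTIONS, AnnotationBundle, FaceRecord

__all__ = [
    "ClassParams",
    "GeneratorConfig",
    "SyntheticPhoto",
    "make_text_image",
    "make_people_image",
    "make_annotations",
    "generate_corpus",
    "save_corpus",
    "load_corpus",
    "TEXT_CLASS_DEFAULTS",
    "PEOPLE_CLASS_DEFAULTS",
]

# Target mean emotion profile (order = EMOTIONS); matches the corpus-level
# face statistics the generator emulates, normalized to the simplex.
_EMOTION_MEANS = np.array(
    [0.014, 0.013, 0.002, 0.002, 0.433, 0.019, 0.017, 0.499], dtype=float
)
_EMOTION_MEANS = _EMOTION_MEANS / _EMOTION_MEANS.sum()

# Fixed word vocabulary with sampling weights. Deliberately includes stop
# words, URLs and bullet glyphs so the cleaning stage is exercised.
_VOCAB = [
    ("you", 8), ("mask", 8), ("masks", 4), ("no", 6), ("not", 5),
    ("face", 4), ("wear", 3), ("wearing", 2), ("covid", 3), ("virus", 2),
    ("health", 2), ("life", 2), ("freedom", 2), ("if", 3), ("because", 2),
    ("don't", 3), ("just", 2), ("see", 2), ("our", 2), ("he", 1),
    ("out", 1), ("people", 2), ("stop", 1), ("2020", 2),
    ("the", 6), ("a", 4), ("and", 3), ("to", 3), ("of", 2), ("in", 2),
    ("is", 2), ("it", 2), ("this", 2), ("for", 1), ("on", 1), ("was", 1),
    ("http://example.com/post", 1), ("https://t.co/nomask", 1),
    ("www.nomask.org", 1), ("•", 1), ("0", 1), ("1", 1), ("2", 1),
]
_VOCAB_WORDS = [w for w, _ in _VOCAB]
_VOCAB_P = np.array([p for _, p in _VOCAB], dtype=float)
_VOCAB_P /= _VOCAB_P.sum()

_TEXT_TAGS = ["text", "screenshot", "design", "font", "typography", "sign"]
_PEOPLE_TAGS = [
    "person", "human face", "clothing", "smile", "woman", "man",
    "girl", "outdoor", "sky", "grass",
]


@dataclass
class ClassParams:
    """Class-conditional distribution parameters for one latent class.

    face_count_probs: probabilities of 0,1,2,... faces per photo.
    word_count_mean: Poisson mean of raw in-photo word count.
    like_log_mean / like_log_sigma: lognormal parameters for likes.
    comment_rate: Poisson mean of comment count per photo.
    sentiment_mean / sentiment_sd: Normal parameters of per-comment
        sentiment, clipped to [-1, 1].
    emotion_concentration: Dirichlet concentration multiplier on the
        target emotion-mean profile.
    category / category_prob: modal content category and its probability;
        the remainder is spread uniformly over the other 14 classes.
    """

    face_count_probs: tuple[float, ...]
    word_count_mean: float
    like_log_mean: float
    like_log_sigma: float
    comment_rate: float
    sentiment_mean: float
    sentiment_sd: float
    emotion_concentration: float
    category: str
    category_prob: float


TEXT_CLASS_DEFAULTS = ClassParams(
    face_count_probs=(1.0,),  # text photos carry no rendered faces
    word_count_mean=5.519,
    like_log_mean=3.6,
    like_log_sigma=1.0,
    comment_rate=3.0,
    sentiment_mean=0.073,
    sentiment_sd=0.4,
    emotion_concentration=1.2,
    category="text",
    category_prob=0.8,
)

PEOPLE_CLASS_DEFAULTS = ClassParams(
    face_count_probs=(0.0, 0.66, 0.24, 0.10),  # mean 1.44 faces
    word_count_mean=0.398,
    like_log_mean=4.2,
    like_log_sigma=1.0,
    comment_rate=4.2,
    sentiment_mean=0.198,
    sentiment_sd=0.4,
    emotion_concentration=1.2,
    category="people",
    category_prob=0.7,
)


@dataclass
class GeneratorConfig:
    """Configuration of a synthetic corpus draw."""

    n_photos: int = 400
    mix: float = 0.5  # fraction of text-class photos
    image_size: tuple[int, int] = (64, 64)  # (height, width)
    seed: int = 0
    text_params: ClassParams = field(default_factory=lambda: TEXT_CLASS_DEFAULTS)
    people_params: ClassParams = field(default_factory=lambda: PEOPLE_CLASS_DEFAULTS)

    def validate(self) -> None:
        if self.n_photos < 2:
            raise ValueError("n_photos must be at least 2")
        if not 0.0 <= self.mix <= 1.0:
            raise ValueError("mix must lie in [0, 1]")
        h, w = self.image_size
        if h < 16 or w < 16:
            raise ValueError("image_size must be at least 16 x 16")
        if self.seed < 0:
            raise ValueError("seed must be a nonnegative integer")

    def params_for(self, true_class: str) -> ClassParams:
        if true_class == "text":
            return self.text_params
        if true_class == "people":
            return self.people_params
        raise ValueError(f"unknown class {true_class!r}")


@dataclass
class SyntheticPhoto:
    photo_id: str
    image: np.ndarray  # H x W x 3 uint8
    true_class: str  # "text" | "people"
    annotations: AnnotationBundle


def _hsv_to_rgb255(h_deg, s, v):
    """Vectorized HSV -> uint8 RGB helper (h in degrees)."""
    h = (np.asarray(h_deg, dtype=float) % 360.0) / 60.0
    s = np.asarray(s, dtype=float)
    v = np.asarray(v, dtype=float)
    c = v * s
    x = c * (1 - np.abs(h % 2 - 1))
    m = v - c
    zeros = np.zeros_like(c)
    idx = np.floor(h).astype(int) % 6
    r = np.choose(idx, [c, x, zeros, zeros, x, c])
    g = np.choose(idx, [x, c, c, x, zeros, zeros])
    b = np.choose(idx, [zeros, zeros, x, c, c, x])
    rgb = np.stack([r + m, g + m, b + m], axis=-1)
    return np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)


def make_text_image(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Bright, low-saturation image with dark glyph-like stroke rows."""
    config.validate()
    h, w = config.image_size
    base = rng.uniform(228, 250)
    img = np.full((h, w, 3), base, dtype=np.float64)
    img += rng.normal(0.0, 3.0, size=(h, w, 3))  # paper-grain noise

    # horizontal "text lines" of short dark glyph rectangles
    n_lines = int(rng.integers(3, 7))
    line_h = max(2, h // 14)
    dark = rng.uniform(15, 60)
    for _ in range(n_lines):
        y0 = int(rng.integers(0, max(1, h - line_h)))
        x = int(rng.integers(0, w // 6))
        while x < w - 2:
            glyph_w = int(rng.integers(2, max(3, w // 10)))
            x1 = min(w, x + glyph_w)
            if rng.random() < 0.8:  # glyph vs inter-word gap
                shade = dark + rng.uniform(-10, 10)
                img[y0 : y0 + line_h, x:x1, :] = shade + rng.normal(
                    0.0, 2.0, size=(min(line_h, h - y0), x1 - x, 3)
                )
            x = x1 + int(rng.integers(1, 4))
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def make_people_image(
    config: GeneratorConfig, rng: np.random.Generator
) -> tuple[np.ndarray, list[tuple[int, int, int, int]]]:
    """Colorful sky/grass scene with skin-tone face ellipses.

    Returns the image and the list of face bounding boxes
    (x, y, width, height), origin top-left, fully inside the frame.
    """
    config.validate()
    h, w = config.image_size
    horizon = int(h * rng.uniform(0.35, 0.6))

    sky = _hsv_to_rgb255(
        rng.uniform(195, 240), rng.uniform(0.35, 0.65), rng.uniform(0.6, 0.9)
    ).astype(np.float64)
    grass = _hsv_to_rgb255(
        rng.uniform(95, 135), rng.uniform(0.45, 0.8), rng.uniform(0.3, 0.6)
    ).astype(np.float64)
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:horizon] = sky
    img[horizon:] = grass
    img += rng.normal(0.0, 8.0, size=(h, w, 3))

    probs = np.asarray(config.people_params.face_count_probs, dtype=float)
    n_faces = int(rng.choice(len(probs), p=probs / probs.sum()))
    boxes: list[tuple[int, int, int, int]] = []
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(n_faces):
        ry = int(max(2, h * rng.uniform(0.08, 0.18)))
        rx = int(max(2, ry * rng.uniform(0.7, 0.9)))
        cy = int(rng.integers(ry, h - ry))
        cx = int(rng.integers(rx, w - rx))
        skin = _hsv_to_rgb255(
            rng.uniform(20, 40), rng.uniform(0.3, 0.55), rng.uniform(0.65, 0.9)
        ).astype(np.float64)
        mask = ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0
        img[mask] = skin + rng.normal(0.0, 5.0, size=(int(mask.sum()), 3))
        boxes.append((cx - rx, cy - ry, 2 * rx, 2 * ry))
    return np.clip(np.round(img), 0, 255).astype(np.uint8), boxes


def make_annotations(
    true_class: str,
    face_boxes: list[tuple[int, int, int, int]],
    config: GeneratorConfig,
    rng: np.random.Generator,
    photo_id: str = "photo",
) -> AnnotationBundle:
    """Draw a service-style annotation bundle for one photo."""
    params = config.params_for(true_class)

    # content category: modal class with configured probability, the rest
    # spread uniformly over the remaining 14 classes
    others = [c for c in CATEGORIES if c != params.category]
    if rng.random() < params.category_prob:
        category = params.category
    else:
        category = str(rng.choice(others))

    tag_pool = _TEXT_TAGS if true_class == "text" else _PEOPLE_TAGS
    n_tags = int(rng.integers(3, len(tag_pool) + 1))
    chosen = rng.choice(len(tag_pool), size=n_tags, replace=False)
    tags = [
        (tag_pool[i], float(np.clip(rng.uniform(0.5, 1.0), 1e-9, 1.0)))
        for i in sorted(chosen)
    ]

    faces = []
    alpha = params.emotion_concentration * _EMOTION_MEANS
    for box in face_boxes:
        emotions = rng.dirichlet(alpha)
        faces.append(
            FaceRecord(
                box=tuple(int(v) for v in box),
                age=float(np.clip(rng.normal(31.0, 11.0), 1.0, 90.0)),
                is_female=bool(rng.random() < 0.6),
                emotions=tuple(float(e) for e in emotions),
            )
        )

    n_words = int(rng.poisson(params.word_count_mean))
    words = [str(w) for w in rng.choice(_VOCAB_WORDS, size=n_words, p=_VOCAB_P)]

    likes = int(np.floor(rng.lognormal(params.like_log_mean, params.like_log_sigma)))
    n_comments = int(rng.poisson(params.comment_rate))
    sentiments = [
        float(np.clip(rng.normal(params.sentiment_mean, params.sentiment_sd), -1.0, 1.0))
        for _ in range(n_comments)
    ]
    return AnnotationBundle(
        photo_id=photo_id,
        category=category,
        tags=tags,
        faces=faces,
        words=words,
        likes=likes,
        comment_sentiments=sentiments,
    )


def _photo_rng(config: GeneratorConfig, index: int) -> np.random.Generator:
    # counter-derived substream: order-independent, byte-reproducible
    return np.random.default_rng(np.random.SeedSequence([config.seed, index]))


def generate_corpus(config: GeneratorConfig) -> list[SyntheticPhoto]:
    """Generate the full corpus: exactly round(mix * n_photos) text photos."""
    config.validate()
    n_text = round(config.mix * config.n_photos)
    photos: list[SyntheticPhoto] = []
    for i in range(config.n_photos):
        rng = _photo_rng(config, i)
        true_class = "text" if i < n_text else "people"
        photo_id = f"photo_{i:05d}"
        if true_class == "text":
            image = make_text_image(config, rng)
            boxes: list[tuple[int, int, int, int]] = []
        else:
            image, boxes = make_people_image(config, rng)
        bundle = make_annotations(true_class, boxes, config, rng, photo_id=photo_id)
        photos.append(SyntheticPhoto(photo_id, image, true_class, bundle))
    return photos


def labels_frame(photos: list[SyntheticPhoto]) -> pd.DataFrame:
    return pd.DataFrame(
        {"photo_id": [p.photo_id for p in photos], "true_class": [p.true_class for p in photos]}
    )


def save_corpus(photos: list[SyntheticPhoto], out_dir: str | Path) -> Path:
    """Write images as PNG plus annotation JSON, flat CSVs and labels.csv."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    ann = []
    photo_rows, face_rows, tag_rows, word_rows, comment_rows = [], [], [], [], []
    for p in photos:
        PILImage.fromarray(p.image).save(out / "images" / f"{p.photo_id}.png")
        b = p.annotations
        ann.append(
            {
                "photo_id": b.photo_id,
                "category": b.category,
                "tags": [[t, c] for t, c in b.tags],
                "faces": [
                    {
                        "box": list(f.box),
                        "age": f.age,
                        "is_female": f.is_female,
                        "emotions": list(f.emotions),
                    }
                    for f in b.faces
                ],
                "words": b.words,
                "likes": b.likes,
                "comment_sentiments": b.comment_sentiments,
            }
        )
        photo_rows.append(
            {
                "photo_id": b.photo_id,
                "category": b.category,
                "likes": b.likes,
                "n_faces": len(b.faces),
                "n_words": len(b.words),
                "n_comments": len(b.comment_sentiments),
            }
        )
        for j, f in enumerate(b.faces):
            face_rows.append(
                {
                    "photo_id": b.photo_id,
                    "face_index": j,
                    "x": f.box[0],
                    "y": f.box[1],
                    "width": f.box[2],
                    "height": f.box[3],
                    "age": f.age,
                    "is_female": f.is_female,
                    **{emo: f.emotions[k] for k, emo in enumerate(EMOTIONS)},
                }
            )
        tag_rows.extend(
            {"photo_id": b.photo_id, "tag": t, "confidence": c} for t, c in b.tags
        )
        word_rows.extend({"photo_id": b.photo_id, "word": w} for w in b.words)
        comment_rows.extend(
            {"photo_id": b.photo_id, "sentiment": s} for s in b.comment_sentiments
        )
    with open(out / "annotations.json", "w") as fh:
        json.dump(ann, fh, indent=1)
    pd.DataFrame(photo_rows).to_csv(out / "photos.csv", index=False)
    cols = ["photo_id", "face_index", "x", "y", "width", "height", "age", "is_female", *EMOTIONS]
    pd.DataFrame(face_rows, columns=cols).to_csv(out / "faces.csv", index=False)
    pd.DataFrame(tag_rows, columns=["photo_id", "tag", "confidence"]).to_csv(
        out / "tags.csv", index=False
    )
    pd.DataFrame(word_rows, columns=["photo_id", "word"]).to_csv(out / "words.csv", index=False)
    pd.DataFrame(comment_rows, columns=["photo_id", "sentiment"]).to_csv(
        out / "comments.csv", index=False
    )
    labels_frame(photos).to_csv(out / "labels.csv", index=False)
    return out


def load_corpus(corpus_dir: str | Path) -> list[SyntheticPhoto]:
    """Read back a corpus written by :func:`save_corpus`."""
    out = Path(corpus_dir)
    with open(out / "annotations.json") as fh:
        ann = json.load(fh)
    labels = pd.read_csv(out / "labels.csv").set_index("photo_id")["true_class"]
    photos = []
    for rec in ann:
        pid = rec["photo_id"]
        image = np.asarray(PILImage.open(out / "images" / f"{pid}.png").convert("RGB"))
        bundle = AnnotationBundle(
            photo_id=pid,
            category=rec["category"],
            tags=[(t, float(c)) for t, c in rec["tags"]],
            faces=[
                FaceRecord(
                    box=tuple(f["box"]),
                    age=float(f["age"]),
                    is_female=bool(f["is_female"]),
                    emotions=tuple(float(e) for e in f["emotions"]),
                )
                for f in rec["faces"]
            ],
            words=list(rec["words"]),
            likes=int(rec["likes"]),
            comment_sentiments=[float(s) for s in rec["comment_sentiments"]],
        )
        photos.append(SyntheticPhoto(pid, image, str(labels.get(pid, "")), bundle))
    return photos
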