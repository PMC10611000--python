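"""Selection of highly emotive stimulus images from an affective ratings table.

An image-norms table (per-image mean valence and arousal on [1, 9], discrete
basic-emotion labels, and per-emotion intensity ratings on [1, 7]) is reduced
to seven balanced emotion-specific image pools:

1. a global pre-screen drops images rated too disgusting (disgust
   intensity > 4) to protect participants' sensitivity;
2. k-means (k = 3) on the (valence, arousal) plane yields three clusters,
   labelled *negative* / *neutral* / *positive* by the valence band that the
   majority of their members fall in;
3. for each basic emotion, candidates are the images in the clusters that the
   emotion maps to (surprise searches all three, reflecting its dual
   positive/negative nature) that also carry the emotion's discrete label;
   the ten with the highest intensity for that emotion are kept;
4. neutral images come from the neutral cluster, restricted to images that
   carry all six basic-emotion labels, taking the ten with the lowest arousal.

The resulting 7 x 10 = 70 images feed randomized per-participant sessions of
35 images, five per emotion, with no two consecutive images from the same
emotion group.
"""

from __future__ import annotations

import json
import logging
import math
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .emotions import BASIC_EMOTIONS, EMOTIONS, validate_emotions

logger = logging.getLogger(__name__)

#: Fixed order in which the seven emotion groups are filled. Earlier groups
#: remove their picks from later candidate pools so the 70 ids are disjoint.
PROCESSING_ORDER: tuple[str, ...] = (
    "neutral",
    "happy",
    "anger",
    "fear",
    "sad",
    "disgust",
    "surprise",
)

MACRO_LABELS: tuple[str, ...] = ("negative", "neutral", "positive")

IMAGE_CATEGORIES: tuple[str, ...] = (
    "people",
    "faces",
    "animals",
    "objects",
    "landscapes",
)

RATINGS_COLUMNS: tuple[str, ...] = (
    "image_id",
    "category",
    "valence_mean",
    "arousal_mean",
    "labels",
) + tuple(f"int_{e}" for e in BASIC_EMOTIONS)


class RatingsTable:
    """Validated per-image affective norms.

    Wraps a :class:`pandas.DataFrame` with one row per image and columns
    ``image_id, category, valence_mean, arousal_mean, labels,
    int_anger ... int_surprise``. ``labels`` holds frozensets of basic-emotion
    names in memory and semicolon-joined strings on disk.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in RATINGS_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"ratings table missing column(s): {', '.join(missing)}")
        df = df.loc[:, list(RATINGS_COLUMNS)].reset_index(drop=True).copy()
        df["labels"] = df["labels"].map(_as_label_set)
        if df["image_id"].duplicated().any():
            dupes = df.loc[df["image_id"].duplicated(), "image_id"].tolist()
            raise ValueError(f"duplicate image_id(s): {dupes}")
        numeric = ["valence_mean", "arousal_mean"] + [f"int_{e}" for e in BASIC_EMOTIONS]
        vals = df[numeric].to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValueError("ratings table contains NaN ratings")
        va = df[["valence_mean", "arousal_mean"]].to_numpy(dtype=float)
        if ((va < 1) | (va > 9)).any():
            raise ValueError("valence/arousal ratings must lie in [1, 9]")
        inten = df[[f"int_{e}" for e in BASIC_EMOTIONS]].to_numpy(dtype=float)
        if ((inten < 1) | (inten > 7)).any():
            raise ValueError("intensity ratings must lie in [1, 7]")
        for labels in df["labels"]:
            validate_emotions(labels, allow_neutral=False)
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def image_ids(self) -> list[str]:
        return self.df["image_id"].tolist()

    def valence_arousal(self) -> np.ndarray:
        """(n, 2) array of (valence_mean, arousal_mean) rows."""
        return self.df[["valence_mean", "arousal_mean"]].to_numpy(dtype=float)

    def subset(self, image_ids: Iterable[str]) -> "RatingsTable":
        keep = set(image_ids)
        return RatingsTable(self.df[self.df["image_id"].isin(keep)])

    @classmethod
    def from_csv(cls, path: str | Path) -> "RatingsTable":
        df = pd.read_csv(path, dtype={"image_id": str}, keep_default_na=False)
        return cls(df)

    def to_csv(self, path: str | Path) -> None:
        out = self.df.copy()
        out["labels"] = out["labels"].map(lambda s: ";".join(sorted(s)))
        out.to_csv(path, index=False)


def _as_label_set(value) -> frozenset:
    if isinstance(value, frozenset):
        return value
    if isinstance(value, (set, list, tuple)):
        return frozenset(value)
    if isinstance(value, float) and math.isnan(value):
        return frozenset()
    text = str(value).strip()
    if not text:
        return frozenset()
    return frozenset(part.strip() for part in text.split(";") if part.strip())


@dataclass
class ClusterModel:
    """k-means partition of the (valence, arousal) plane.

    ``labels`` maps each cluster index to a macro affect label
    (negative / neutral / positive); it is empty until
    :func:`label_clusters` runs.
    """

    k: int
    assignment: dict[str, int]
    centroids: np.ndarray
    labels: dict[int, str] = field(default_factory=dict)

    def clusters_with_label(self, macro: str) -> list[int]:
        return [c for c, lab in self.labels.items() if lab == macro]

    def members(self, cluster: int) -> list[str]:
        return [img for img, c in self.assignment.items() if c == cluster]


@dataclass
class EmotionClusterMap:
    """Which macro-affect clusters to search for each emotion.

    Defaults follow the discrete-to-dimensional remapping: the four
    high-arousal negative emotions search the negative cluster, happiness the
    positive one, neutrality the neutral one, and surprise — which carries
    both positive and negative components — searches all three.
    """

    targets: dict[str, frozenset] = field(default_factory=lambda: {
        "anger": frozenset({"negative"}),
        "disgust": frozenset({"negative"}),
        "fear": frozenset({"negative"}),
        "sad": frozenset({"negative"}),
        "happy": frozenset({"positive"}),
        "neutral": frozenset({"neutral"}),
        "surprise": frozenset(MACRO_LABELS),
    })

    def __post_init__(self) -> None:
        validate_emotions(self.targets.keys())
        for emotion in EMOTIONS:
            if not self.targets.get(emotion):
                raise ValueError(f"emotion '{emotion}' has no target cluster label")

    def __getitem__(self, emotion: str) -> frozenset:
        return self.targets[emotion]


@dataclass
class StimulusSet:
    """Seven emotion-keyed groups of selected image ids."""

    groups: dict[str, list[str]]
    group_size: int = 10

    def __post_init__(self) -> None:
        if set(self.groups) != set(EMOTIONS):
            raise ValueError("stimulus set must have exactly the seven emotion groups")
        for emotion, ids in self.groups.items():
            if len(ids) != self.group_size:
                raise ValueError(
                    f"group '{emotion}' has {len(ids)} ids, expected {self.group_size}"
                )
        all_ids = [i for ids in self.groups.values() for i in ids]
        if len(set(all_ids)) != len(all_ids):
            raise ValueError("image ids must be unique across the stimulus set")

    @property
    def all_ids(self) -> list[str]:
        return [i for e in EMOTIONS for i in self.groups[e]]

    def to_json(self, path: str | Path) -> None:
        doc = {"group_size": self.group_size, "groups": {e: list(v) for e, v in self.groups.items()}}
        Path(path).write_text(json.dumps(doc, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "StimulusSet":
        doc = json.loads(Path(path).read_text())
        return cls(groups={e: list(v) for e, v in doc["groups"].items()},
                   group_size=int(doc["group_size"]))


@dataclass
class Session:
    """One participant's randomized presentation order.

    ``items`` is an ordered list of (image_id, emotion-group) pairs with
    ``per_emotion`` images from each of the seven groups and no two
    consecutive items from the same group.
    """

    items: list[tuple[str, str]]
    per_emotion: int = 5

    def __post_init__(self) -> None:
        if len(self.items) != 7 * self.per_emotion:
            raise ValueError("session length must be 7 x per_emotion")
        counts: dict[str, int] = {}
        for _, group in self.items:
            counts[group] = counts.get(group, 0) + 1
        if any(counts.get(e, 0) != self.per_emotion for e in EMOTIONS):
            raise ValueError("each emotion group must appear exactly per_emotion times")
        for (_, a), (_, b) in zip(self.items, self.items[1:]):
            if a == b:
                raise ValueError("two consecutive items share an emotion group")

    def to_json(self, path: str | Path) -> None:
        doc = {"per_emotion": self.per_emotion,
               "items": [{"image_id": i, "emotion": e} for i, e in self.items]}
        Path(path).write_text(json.dumps(doc, indent=2))


def cluster_images(table: RatingsTable, k: int = 3, seed: int = 0) -> ClusterModel:
    """Partition the images into ``k`` clusters in the (valence, arousal) plane.

    Runs Lloyd iterations from k-means++ seeds with 10 restarts, which
    reliably recovers well-separated affect groups regardless of the seed.
    Both axes already share the [1, 9] scale, so no standardization is
    applied.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(table) == 0:
        raise ValueError("insufficient data: ratings table is empty")
    if len(table) < k:
        raise ValueError(f"insufficient data: {len(table)} images for k={k}")
    points = table.valence_arousal()
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, max_iter=300,
                algorithm="lloyd", random_state=seed)
    idx = km.fit_predict(points)
    assignment = dict(zip(table.image_ids, (int(i) for i in idx)))
    return ClusterModel(k=k, assignment=assignment, centroids=km.cluster_centers_.copy())


def valence_band(valence: float) -> str:
    """Macro affect band of a valence value: [1,4) negative, [4,6) neutral, [6,9] positive."""
    if valence < 4:
        return "negative"
    if valence < 6:
        return "neutral"
    return "positive"


def label_clusters(model: ClusterModel, table: RatingsTable) -> ClusterModel:
    """Attach negative/neutral/positive labels to each cluster.

    A cluster gets the band holding the majority of its members' valence
    values; ties are broken by the band containing the cluster's mean
    valence, then by the fixed band order negative < neutral < positive.
    """
    valence = dict(zip(table.image_ids, table.df["valence_mean"].astype(float)))
    labels: dict[int, str] = {}
    for cluster in range(model.k):
        members = model.members(cluster)
        if not members:
            raise ValueError(f"cluster {cluster} is empty")
        counts = {band: 0 for band in MACRO_LABELS}
        for img in members:
            counts[valence_band(valence[img])] += 1
        best = max(counts.values())
        tied = [band for band in MACRO_LABELS if counts[band] == best]
        if len(tied) == 1:
            labels[cluster] = tied[0]
        else:
            mean_band = valence_band(float(np.mean([valence[m] for m in members])))
            labels[cluster] = mean_band if mean_band in tied else tied[0]
    model.labels = labels
    return model


def prescreen(table: RatingsTable, threshold: float = 4.0) -> RatingsTable:
    """Drop images whose disgust intensity exceeds ``threshold``.

    Applied once, globally, before any per-emotion search, so that overly
    shocking images are never shown. The comparison is strict: an intensity
    exactly at the threshold is kept.
    """
    keep = table.df["int_disgust"].astype(float) <= threshold
    return RatingsTable(table.df[keep])


def select_for_emotion(
    table: RatingsTable,
    emotion: str,
    model: ClusterModel,
    cluster_map: EmotionClusterMap | None = None,
    n: int = 10,
    exclude: Iterable[str] = (),
) -> list[str]:
    """Pick the ``n`` most intense images for one basic emotion.

    Candidates are images in the clusters the emotion maps to that also carry
    the emotion's discrete label. They are ranked by that emotion's intensity,
    descending, with ties broken by image id for reproducibility.
    """
    if emotion not in BASIC_EMOTIONS:
        raise ValueError(f"'{emotion}' is not a basic emotion")
    cluster_map = cluster_map or EmotionClusterMap()
    allowed = {c for macro in cluster_map[emotion] for c in model.clusters_with_label(macro)}
    excluded = set(exclude)
    rows = table.df
    candidates = []
    for img, labels, intensity in zip(rows["image_id"], rows["labels"], rows[f"int_{emotion}"]):
        if img in excluded or model.assignment.get(img) not in allowed:
            continue
        if emotion in labels:
            candidates.append((-float(intensity), img))
    if len(candidates) < n:
        raise ValueError(
            f"insufficient candidates for emotion '{emotion}': "
            f"{len(candidates)} available, {n} required"
        )
    candidates.sort()
    return [img for _, img in candidates[:n]]


def select_neutral(
    table: RatingsTable,
    model: ClusterModel,
    n: int = 10,
    exclude: Iterable[str] = (),
) -> list[str]:
    """Pick the ``n`` calmest neutral images.

    The norms table provides no neutral intensity, so neutrality is inferred:
    candidates are images in neutral-labelled clusters that the raters tagged
    with *all six* basic-emotion labels (no single emotion dominates), ranked
    by arousal ascending.
    """
    allowed = set(model.clusters_with_label("neutral"))
    excluded = set(exclude)
    required = set(BASIC_EMOTIONS)
    rows = table.df
    candidates = []
    for img, labels, arousal in zip(rows["image_id"], rows["labels"], rows["arousal_mean"]):
        if img in excluded or model.assignment.get(img) not in allowed:
            continue
        if required <= set(labels):
            candidates.append((float(arousal), img))
    if len(candidates) < n:
        raise ValueError(
            f"insufficient candidates for emotion 'neutral': "
            f"{len(candidates)} available, {n} required"
        )
    candidates.sort()
    return [img for _, img in candidates[:n]]


def build_stimulus_set(
    table: RatingsTable,
    seed: int = 0,
    n_per_group: int = 10,
    cluster_map: EmotionClusterMap | None = None,
) -> StimulusSet:
    """Run the full selection procedure: pre-screen, cluster, label, pick.

    Groups are filled in a fixed order (neutral, happy, anger, fear, sad,
    disgust, surprise) and ids already selected by an earlier group are
    removed from later candidate pools, so the seven groups are disjoint.
    """
    cluster_map = cluster_map or EmotionClusterMap()
    screened = prescreen(table)
    model = label_clusters(cluster_images(screened, k=3, seed=seed), screened)
    groups: dict[str, list[str]] = {}
    taken: set[str] = set()
    for emotion in PROCESSING_ORDER:
        if emotion == "neutral":
            picked = select_neutral(screened, model, n=n_per_group, exclude=taken)
        else:
            picked = select_for_emotion(
                screened, emotion, model, cluster_map, n=n_per_group, exclude=taken
            )
        groups[emotion] = picked
        taken.update(picked)
    return StimulusSet(groups=groups, group_size=n_per_group)


def sample_session(
    stimulus_set: StimulusSet | Mapping[str, Sequence[str]],
    per_emotion: int = 5,
    seed: int = 0,
) -> Session:
    """Draw a randomized session: ``per_emotion`` images per group, no two
    consecutive items from the same emotion group.

    Uses seeded uniform sampling within each group followed by randomized
    placement with backtracking; the arrangement always succeeds when no
    group holds more than half the slots (rounded up), which holds for the
    standard 5-of-7 session.
    """
    groups = stimulus_set.groups if isinstance(stimulus_set, StimulusSet) else dict(stimulus_set)
    rng = random.Random(seed)
    chosen: dict[str, list[str]] = {}
    for emotion, pool in groups.items():
        if len(pool) < per_emotion:
            raise ValueError(
                f"group '{emotion}' has only {len(pool)} ids; {per_emotion} required"
            )
        chosen[emotion] = rng.sample(list(pool), per_emotion)
    total = len(groups) * per_emotion
    if per_emotion > math.ceil(total / 2):
        raise ValueError("infeasible arrangement: one group exceeds half the session")
    counts = {e: per_emotion for e in groups}
    order = _arrange(counts, rng)
    if order is None:  # pragma: no cover - guarded by the feasibility check
        raise ValueError("infeasible arrangement: no non-consecutive ordering exists")
    items = []
    offsets = {e: 0 for e in groups}
    for emotion in order:
        items.append((chosen[emotion][offsets[emotion]], emotion))
        offsets[emotion] += 1
    return Session(items=items, per_emotion=per_emotion)


def _arrange(counts: dict[str, int], rng: random.Random) -> list[str] | None:
    """Backtracking search for an ordering with no equal adjacent groups."""
    remaining = sum(counts.values())
    if remaining == 0:
        return []
    return _arrange_from(dict(counts), None, remaining, rng)


def _arrange_from(counts, prev, remaining, rng):
    if remaining == 0:
        return []
    # prune: a group needing more than half the remaining slots cannot avoid
    # adjacency
    if max(counts.values()) > (remaining + 1) // 2:
        return None
    options = [g for g, c in counts.items() if c > 0 and g != prev]
    rng.shuffle(options)
    for group in options:
        counts[group] -= 1
        rest = _arrange_from(counts, group, remaining - 1, rng)
        counts[group] += 1
        if rest is not None:
            return [group] + rest
    return None


def sample_sessions(
    stimulus_set: StimulusSet,
    n_sessions: int,
    per_emotion: int = 5,
    seed: int = 0,
) -> list[Session]:
    """Independent seeded sessions for ``n_sessions`` participants."""
    return [
        sample_session(stimulus_set, per_emotion=per_emotion, seed=seed + i)
        for i in range(n_sessions)
    ]
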