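"""Synthetic affective-norms tables and landmark datasets with a known,
controllable expression signal.

Two generators make every pipeline stage testable without any external
download:

* :func:`generate_ratings` emulates an affective image-norms table: images
  are drawn around three macro-affect centroids in the (valence, arousal)
  plane — negative (2.7, 6.9), neutral (5.0, 3.0), positive (8.0, 6.9) —
  with discrete labels and intensity ratings assigned consistently with the
  generating cluster, so the stimulus-selection procedure always finds
  enough qualifying candidates per emotion. A small fraction of images is
  given disgust intensity above the pre-screen threshold to exercise the
  screen.

* :func:`generate_landmarks` emulates raw 68-point landmark capture: each
  sample is a canonical neutral face template (unit inter-anchor distances)
  plus per-emotion displacement prototypes scaled by ``expression_strength``,
  isotropic Gaussian landmark noise, and translation/axis-scale jitter that
  the anchor normalization must cancel. The prototypes are hand-designed
  caricatures of the facial-action-unit patterns of each emotion (brow raise
  for surprise, mouth-corner raise for happiness, brow lowering for anger,
  lip-corner depression for sadness, nose wrinkling for disgust, eye widening
  with a dropped jaw for fear); the neutral field is zero and all four anchor
  landmarks are undisplaced in every prototype, mirroring the
  expression-stability assumption the normalization relies on.

The generators' role is parameter recovery, not photorealism: real faces
vary in geometry, expressiveness, head pose, and landmark-detector error in
ways these caricatures do not capture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .emotions import BASIC_EMOTIONS, EMOTIONS
from .landmark_processing import N_LANDMARKS, AnchorSet, LandmarkFrame
from .stimulus_selection import IMAGE_CATEGORIES, RatingsTable

#: Macro-affect centroid defaults in the (valence, arousal) plane.
DEFAULT_CENTROIDS: dict[str, tuple[float, float]] = {
    "negative": (2.7, 6.9),
    "neutral": (5.0, 3.0),
    "positive": (8.0, 6.9),
}


@dataclass
class GeneratorConfig:
    """Knobs of both synthetic generators.

    Defaults mirror the emulated study: 31 subjects rating 35 images each,
    a 700-image norms table, tight affect clusters (sd 0.3), a unit
    expression signal over landmark noise of sd 0.2 (in template units,
    where all anchor distances are 1), and a 25% chance that a sample
    carries a second emotion.
    """

    seed: int = 0
    n_images: int = 700
    cluster_centroids: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CENTROIDS))
    cluster_sd: float = 0.3
    n_subjects: int = 31
    images_per_subject: int = 35
    expression_strength: float = 1.0
    noise_sd: float = 0.2
    translation_range: tuple[float, float] = (100.0, 500.0)
    scale_range: tuple[float, float] = (80.0, 120.0)
    multi_label_rate: float = 0.25
    shock_fraction: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.multi_label_rate <= 1.0:
            raise ValueError("multi_label_rate must lie in [0, 1]")
        if not 0.0 <= self.shock_fraction <= 1.0:
            raise ValueError("shock_fraction must lie in [0, 1]")
        if self.cluster_sd < 0 or self.noise_sd < 0 or self.expression_strength < 0:
            raise ValueError("sd and strength parameters must be >= 0")
        if self.scale_range[0] <= 0 or self.scale_range[1] < self.scale_range[0]:
            raise ValueError("scale_range must be positive and ordered")
        if self.translation_range[1] < self.translation_range[0]:
            raise ValueError("translation_range must be ordered")


# ---------------------------------------------------------------------------
# Face template and expression prototypes


def build_template() -> np.ndarray:
    """Canonical neutral 68-point face with unit inter-anchor distances.

    The nasal center (index 27) sits at the origin, lateral anchors (0, 16)
    at x = -1 and +1 on the anchor line, and the subnasal center (33) one
    unit below the nasal center. y grows downward, as in image pixels.
    """
    pts = np.zeros((N_LANDMARKS, 2))
    # jaw line 0-16: half-ellipse from the left temple through the chin
    t = np.arange(17) * np.pi / 16
    pts[0:17, 0] = -np.cos(t)
    pts[0:17, 1] = 1.9 * np.sin(t)
    # brows 17-21 (left) and 22-26 (right): gentle arcs above the eyes
    bx = np.linspace(-0.80, -0.15, 5)
    pts[17:22, 0] = bx
    pts[17:22, 1] = -0.55 - 0.08 * np.sin(np.linspace(0, np.pi, 5))
    pts[22:27, 0] = -bx[::-1]
    pts[22:27, 1] = pts[17:22, 1][::-1]
    # nose bridge 27-30 and base row 31-35
    pts[27:31, 0] = 0.0
    pts[27:31, 1] = np.array([0.0, 0.30, 0.60, 0.88])
    pts[31:36, 0] = np.array([-0.26, -0.13, 0.0, 0.13, 0.26])
    pts[31:36, 1] = np.array([1.06, 1.09, 1.00, 1.09, 1.06])
    # eyes 36-41 (left) and 42-47 (right)
    pts[36:42] = [(-0.75, -0.10), (-0.62, -0.20), (-0.48, -0.20),
                  (-0.35, -0.10), (-0.48, 0.00), (-0.62, 0.00)]
    pts[42:48] = [(0.35, -0.10), (0.48, -0.20), (0.62, -0.20),
                  (0.75, -0.10), (0.62, 0.00), (0.48, 0.00)]
    # mouth: outer lips 48-59, inner lips 60-67
    pts[48:60] = [(-0.50, 1.70), (-0.35, 1.60), (-0.18, 1.55), (0.00, 1.52),
                  (0.18, 1.55), (0.35, 1.60), (0.50, 1.70), (0.35, 1.84),
                  (0.18, 1.90), (0.00, 1.92), (-0.18, 1.90), (-0.35, 1.84)]
    pts[60:68] = [(-0.40, 1.70), (-0.18, 1.66), (0.00, 1.64), (0.18, 1.66),
                  (0.40, 1.70), (0.18, 1.77), (0.00, 1.79), (-0.18, 1.77)]
    return pts


_FIELD_AMPLITUDE = 1.5


def _displacement_fields() -> dict[str, np.ndarray]:
    """Seven 68x2 per-emotion displacement prototypes (template units).

    Each field is a caricature of the action-unit pattern characteristic of
    the emotion; the neutral field is zero and the anchors (0, 16, 27, 33)
    are undisplaced everywhere. y grows downward, so raising a point means a
    negative y displacement.
    """
    fields: dict[str, np.ndarray] = {e: np.zeros((N_LANDMARKS, 2)) for e in EMOTIONS}

    happy = fields["happy"]
    happy[48] = (-0.35, -0.60)   # mouth corners pulled strongly up and out
    happy[54] = (0.35, -0.60)
    happy[49] = (-0.18, -0.35)
    happy[53] = (0.18, -0.35)
    happy[59] = (-0.15, -0.30)
    happy[55] = (0.15, -0.30)
    happy[50, 1] = happy[52, 1] = -0.15
    for i in (40, 41, 46, 47):   # cheek raise narrows the lower lids
        happy[i, 1] = -0.18

    sad = fields["sad"]
    sad[48] = (0.0, 0.55)        # lip corners depressed
    sad[54] = (0.0, 0.55)
    sad[49, 1] = sad[53, 1] = 0.32
    sad[21] = (0.10, -0.50)      # inner brows raised and drawn in
    sad[22] = (-0.10, -0.50)
    sad[20, 1] = sad[23, 1] = -0.30
    for i in (37, 38, 43, 44):   # upper lids droop
        sad[i, 1] = 0.15

    anger = fields["anger"]
    for i in range(17, 27):      # whole brow lowered
        anger[i, 1] = 0.40
    anger[20] += (0.18, 0.25)    # inner brows lower further and knit
    anger[21] += (0.25, 0.25)
    anger[22] += (-0.25, 0.25)
    anger[23] += (-0.18, 0.25)
    anger[51, 1] = 0.12          # lips pressed together
    anger[57, 1] = -0.15
    anger[62, 1] = 0.08
    anger[66, 1] = -0.10

    surprise = fields["surprise"]
    for i in range(17, 27):      # brows shoot up
        surprise[i, 1] = -0.70
    for i in (37, 38, 43, 44):   # eyes widen
        surprise[i, 1] = -0.20
    for i in (40, 41, 46, 47):
        surprise[i, 1] = 0.20
    surprise[48] = (0.15, 0.25)  # mouth rounds: corners pulled inward
    surprise[54] = (-0.15, 0.25)
    for i in (55, 56, 57, 58, 59):   # jaw drops, mouth opens wide
        surprise[i, 1] = 0.95
    for i in (65, 66, 67):
        surprise[i, 1] = 0.80
    for i in (6, 7, 8, 9, 10):   # chin follows the jaw
        surprise[i, 1] = 0.60

    fear = fields["fear"]
    for i in range(17, 27):      # brows raised and pulled together
        fear[i, 1] = -0.35
    fear[20, 0] = 0.15
    fear[21, 0] = 0.30
    fear[22, 0] = -0.30
    fear[23, 0] = -0.15
    for i in (37, 38, 43, 44):   # eyes wide
        fear[i, 1] = -0.18
    for i in (40, 41, 46, 47):
        fear[i, 1] = 0.18
    fear[48] = (-0.40, 0.10)     # mouth stretched strongly sideways
    fear[54] = (0.40, 0.10)
    fear[49, 0] = fear[59, 0] = -0.20
    fear[53, 0] = fear[55, 0] = 0.20
    for i in (56, 57, 58):       # slightly open
        fear[i, 1] = 0.30
    for i in (65, 66, 67):
        fear[i, 1] = 0.22

    disgust = fields["disgust"]
    for i in (31, 32, 34, 35):   # nose wrinkle: wings pulled up
        disgust[i, 1] = -0.35
    disgust[28, 1] = disgust[29, 1] = -0.12
    for i in (49, 50, 51, 52, 53):   # upper lip raised
        disgust[i, 1] = -0.40
    for i in (61, 62, 63):
        disgust[i, 1] = -0.25
    for i in range(17, 27):      # mild brow lowering
        disgust[i, 1] = 0.15
    for i in (40, 41, 46, 47):   # lower lids raised (squint)
        disgust[i, 1] = -0.14

    # neutral stays the zero field
    for e, f in fields.items():
        assert not f[[0, 16, 27, 33]].any(), f"anchor displaced in '{e}'"
        # overall caricature amplitude: a unit expression_strength moves the
        # expressive landmarks by a clearly super-threshold fraction of the
        # (unit) anchor distances, as full-blown posed expressions do
        f *= _FIELD_AMPLITUDE
    return fields


@dataclass
class FaceTemplate:
    """Canonical neutral face plus per-emotion displacement prototypes."""

    points: np.ndarray = field(default_factory=build_template)
    displacements: dict[str, np.ndarray] = field(default_factory=_displacement_fields)

    def expression(self, emotions: Sequence[str], strength: float) -> np.ndarray:
        """Neutral face plus the summed, scaled fields of the given emotions."""
        pts = self.points.copy()
        for emotion in emotions:
            pts += strength * self.displacements[emotion]
        return pts


# ---------------------------------------------------------------------------
# Ratings generator


def generate_ratings(config: GeneratorConfig) -> RatingsTable:
    """Synthesize an affective norms table around the macro centroids.

    Image roles cycle through the seven emotion targets plus occasional
    "shock" images (disgust intensity above the pre-screen threshold).
    Valence/arousal are drawn around the role's cluster centroid, clipped to
    [1, 9]; intensity ratings in [1, 7] are high for the target emotion and
    low otherwise; neutral-eligible images carry all six basic labels with
    uniformly low intensities and reduced arousal.
    """
    rng = np.random.default_rng(config.seed)
    centroids = config.cluster_centroids
    n_shock = int(round(config.shock_fraction * config.n_images))
    roles = []
    role_cycle = ("neutral", "happy", "anger", "fear", "sad", "disgust", "surprise")
    for i in range(config.n_images - n_shock):
        roles.append(role_cycle[i % len(role_cycle)])
    roles.extend(["shock"] * n_shock)

    rows = []
    surprise_cluster_cycle = ("negative", "neutral", "positive")
    n_surprise = 0
    for i, role in enumerate(roles):
        image_id = f"img{i:05d}"
        category = IMAGE_CATEGORIES[i % len(IMAGE_CATEGORIES)]
        intensity = {e: rng.uniform(1.0, 2.2) for e in BASIC_EMOTIONS}
        if role == "neutral":
            macro = "neutral"
            labels = set(BASIC_EMOTIONS)
        elif role == "happy":
            macro = "positive"
            labels = {"happy"}
            intensity["happy"] = rng.uniform(5.0, 7.0)
        elif role in ("anger", "fear", "sad"):
            macro = "negative"
            labels = {role}
            intensity[role] = rng.uniform(5.0, 7.0)
        elif role == "disgust":
            macro = "negative"
            labels = {"disgust"}
            # high but below the pre-screen threshold of 4
            intensity["disgust"] = rng.uniform(3.2, 4.0)
        elif role == "surprise":
            macro = surprise_cluster_cycle[n_surprise % 3]
            n_surprise += 1
            labels = {"surprise"}
            intensity["surprise"] = rng.uniform(5.0, 7.0)
        else:  # shock: screened out by the disgust pre-screen
            macro = "negative"
            labels = {"disgust", "fear"}
            intensity["disgust"] = rng.uniform(4.5, 7.0)
            intensity["fear"] = rng.uniform(4.0, 6.0)
        cx, cy = centroids[macro]
        valence = float(np.clip(rng.normal(cx, config.cluster_sd), 1.0, 9.0))
        arousal = float(np.clip(rng.normal(cy, config.cluster_sd), 1.0, 9.0))
        if role == "neutral":
            # calm images: push arousal toward the bottom of the neutral blob
            arousal = float(np.clip(arousal - rng.uniform(0.2, 0.9), 1.0, 9.0))
        rows.append({
            "image_id": image_id,
            "category": category,
            "valence_mean": valence,
            "arousal_mean": arousal,
            "labels": frozenset(labels),
            **{f"int_{e}": intensity[e] for e in BASIC_EMOTIONS},
        })
    return RatingsTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Landmark generator


@dataclass
class LandmarkDataset:
    """Generated raw frames plus the ground truth that produced them."""

    frames: list[LandmarkFrame]
    sample_ids: list[str]
    subjects: list[str]
    selections: list[frozenset]
    truth: list[tuple[str, ...]]

    def __len__(self) -> int:
        return len(self.frames)


def generate_landmarks(config: GeneratorConfig, template: FaceTemplate | None = None) -> LandmarkDataset:
    """Synthesize raw landmark frames with self-reported emotion selections.

    Per sample: a primary emotion drawn uniformly over the seven states, a
    second distinct emotion with probability ``multi_label_rate``, points =
    template + strength x summed displacement fields + Gaussian landmark
    noise, then per-axis positive scaling and translation jitter. Jitter is
    drawn after the noise from the same stream, so configurations differing
    only in jitter ranges produce identical pre-jitter geometry.
    """
    template = template or FaceTemplate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects * config.images_per_subject
    frames, ids, subjects, selections, truth = [], [], [], [], []
    for i in range(n):
        subject = f"subj{i // config.images_per_subject:03d}"
        primary = EMOTIONS[rng.integers(0, len(EMOTIONS))]
        # draw the multi-label coin and candidate unconditionally so the
        # random stream is identical across multi_label_rate settings;
        # neutrality never co-occurs with an expressed emotion (a face
        # cannot be simultaneously neutral and expressive)
        coin = rng.uniform()
        other = [e for e in BASIC_EMOTIONS if e != primary]
        second = other[int(rng.integers(0, len(other)))]
        if primary != "neutral" and coin < config.multi_label_rate:
            emotions: tuple[str, ...] = (primary, second)
        else:
            emotions = (primary,)
        base = template.expression(emotions, config.expression_strength)
        noise = rng.normal(0.0, config.noise_sd, size=base.shape)
        # anchor landmarks sit on rigid, high-contrast facial structure
        # (jaw corners, nose bridge and base) that detectors localize much
        # more precisely than deformable features; give them a quarter of
        # the landmark noise so the normalization denominators stay stable
        noise[list(_ANCHOR_INDICES)] *= 0.25
        base = base + noise
        _enforce_anchor_geometry(base)
        scale = rng.uniform(config.scale_range[0], config.scale_range[1], size=2)
        translation = rng.uniform(
            config.translation_range[0], config.translation_range[1], size=2)
        pts = base * scale + translation
        frames.append(LandmarkFrame(points=pts, space="raw"))
        ids.append(f"s{i:05d}")
        subjects.append(subject)
        selections.append(frozenset(emotions))
        truth.append(emotions)
    return LandmarkDataset(
        frames=frames, sample_ids=ids, subjects=subjects,
        selections=selections, truth=truth,
    )


_ANCHOR_INDICES = (
    AnchorSet().left_anchor, AnchorSet().right_anchor,
    AnchorSet().nasal_center, AnchorSet().subnasal_center,
)

_MIN_ANCHOR_GAP = 0.1


def _enforce_anchor_geometry(pts: np.ndarray) -> None:
    """Keep anchor distances strictly positive under extreme noise draws.

    Landmark noise can, in rare tails, push an anchor past the nasal center;
    the affected anchor is clamped back to a minimum separation so every
    generated frame is normalizable by construction. In-place, deterministic.
    """
    anchors = AnchorSet()
    nc = anchors.nasal_center
    if pts[nc, 0] - pts[anchors.left_anchor, 0] < _MIN_ANCHOR_GAP:
        pts[anchors.left_anchor, 0] = pts[nc, 0] - _MIN_ANCHOR_GAP
    if pts[anchors.right_anchor, 0] - pts[nc, 0] < _MIN_ANCHOR_GAP:
        pts[anchors.right_anchor, 0] = pts[nc, 0] + _MIN_ANCHOR_GAP
    if abs(pts[anchors.subnasal_center, 1] - pts[nc, 1]) < _MIN_ANCHOR_GAP:
        pts[anchors.subnasal_center, 1] = pts[nc, 1] + _MIN_ANCHOR_GAP


def write_labels_csv(dataset: LandmarkDataset, path) -> None:
    """Write per-sample selections as CSV ``sample_id,subject,labels``."""
    rows = [{
        "sample_id": sid,
        "subject": subj,
        "labels": ";".join(sorted(sel)),
    } for sid, subj, sel in zip(dataset.sample_ids, dataset.subjects, dataset.selections)]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_labels_csv(path) -> tuple[list[str], list[str], list[frozenset]]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in ("sample_id", "labels") if c not in df.columns]
    if missing:
        raise ValueError(f"missing column(s): {', '.join(missing)}")
    ids = df["sample_id"].tolist()
    subjects = df["subject"].tolist() if "subject" in df.columns else [""] * len(df)
    selections = [
        frozenset(p.strip() for p in lab.split(";") if p.strip()) for lab in df["labels"]
    ]
    return ids, subjects, selections
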