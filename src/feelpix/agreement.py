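"""User-versus-algorithm agreement statistics for multi-label emotion
annotations.

Each presentation yields a pair of label sets: the emotions the participant
selected (always at least one) and the emotions an algorithm detected
(possibly none). Two summaries are computed:

* the **success rate** — the fraction of presentations where the two sets
  share at least one emotion, reported per user and averaged;
* **per-emotion agreement** — for each emotion, a binary confusion over
  presentations (truth: the user selected it; prediction: the algorithm
  detected it) scored with precision, F-measure, and G-mean (accuracy is
  computed too but omitted from the default report, which mirrors the
  imbalance-insensitive trio).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .classifier_ensemble import metrics_from_confusion
from .emotions import EMOTIONS, validate_emotions

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnnotationPair:
    """One presentation's user-selected and algorithm-detected emotion sets."""

    image_id: str
    user_labels: frozenset
    algo_labels: frozenset
    user: str | None = None

    def __post_init__(self) -> None:
        if not self.user_labels:
            raise ValueError("user_labels must be non-empty")
        validate_emotions(self.user_labels)
        validate_emotions(self.algo_labels)


def success_rate(pairs: Sequence[AnnotationPair]) -> float:
    """Fraction of pairs whose user and algorithm sets share >= 1 emotion."""
    if not pairs:
        raise ValueError("no annotation pairs given")
    hits = sum(1 for p in pairs if p.user_labels & p.algo_labels)
    return hits / len(pairs)


def per_emotion_agreement(
    pairs: Sequence[AnnotationPair],
    include_accuracy: bool = False,
) -> dict[str, dict[str, float]]:
    """Per-emotion confusion metrics between user selections and detections.

    For each emotion the confusion counts a pair as positive-truth when the
    user selected it and positive-prediction when the algorithm detected it.
    An emotion absent from every user selection gets the zero-denominator
    convention (metrics 0 where undefined) and a warning.
    """
    if not pairs:
        raise ValueError("no annotation pairs given")
    reported = ("accuracy", "precision", "f_score", "g_mean") if include_accuracy \
        else ("precision", "f_score", "g_mean")
    out: dict[str, dict[str, float]] = {}
    for emotion in EMOTIONS:
        tp = fp = tn = fn = 0
        for p in pairs:
            truth = emotion in p.user_labels
            pred = emotion in p.algo_labels
            if truth and pred:
                tp += 1
            elif pred:
                fp += 1
            elif truth:
                fn += 1
            else:
                tn += 1
        if tp + fn == 0:
            logger.warning(
                "emotion '%s' absent from all user selections; "
                "zero-denominator metric convention applies", emotion,
            )
        metrics = metrics_from_confusion(tp, fp, tn, fn)
        out[emotion] = {name: metrics[name] for name in reported}
    return out


@dataclass
class AgreementReport:
    """Per-user success rates plus pooled per-emotion agreement metrics."""

    per_user_success: dict[str, float]
    mean_success: float
    per_emotion: dict[str, dict[str, float]]
    n_images: int
    n_users: int

    def to_dict(self) -> dict:
        return {
            "per_user_success": self.per_user_success,
            "mean_success": self.mean_success,
            "per_emotion": self.per_emotion,
            "n_images": self.n_images,
            "n_users": self.n_users,
        }


def agreement_report(pairs: Sequence[AnnotationPair]) -> AgreementReport:
    """Summarize agreement over a set of pairs, grouped by user.

    Success rates are computed per user and averaged; per-emotion metrics
    are pooled over all pairs (pairs lacking a user id form one anonymous
    group).
    """
    if not pairs:
        raise ValueError("no annotation pairs given")
    by_user: dict[str, list[AnnotationPair]] = {}
    for p in pairs:
        by_user.setdefault(p.user or "anonymous", []).append(p)
    per_user = {u: success_rate(ps) for u, ps in sorted(by_user.items())}
    return AgreementReport(
        per_user_success=per_user,
        mean_success=float(np.mean(list(per_user.values()))),
        per_emotion=per_emotion_agreement(pairs),
        n_images=len(pairs),
        n_users=len(by_user),
    )


# ---------------------------------------------------------------------------
# CSV interface


def read_pairs_csv(path: str | Path) -> list[AnnotationPair]:
    """Read pairs from CSV ``image_id,user_labels,algo_labels[,user]``;
    label sets are semicolon-joined."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in ("image_id", "user_labels", "algo_labels") if c not in df.columns]
    if missing:
        raise ValueError(f"missing column(s): {', '.join(missing)}")
    pairs = []
    for _, row in df.iterrows():
        pairs.append(AnnotationPair(
            image_id=row["image_id"],
            user_labels=_split(row["user_labels"]),
            algo_labels=_split(row["algo_labels"]),
            user=row["user"] if "user" in df.columns and row["user"] else None,
        ))
    return pairs


def write_pairs_csv(pairs: Sequence[AnnotationPair], path: str | Path) -> None:
    has_user = any(p.user is not None for p in pairs)
    rows = []
    for p in pairs:
        row = {
            "image_id": p.image_id,
            "user_labels": ";".join(sorted(p.user_labels)),
            "algo_labels": ";".join(sorted(p.algo_labels)),
        }
        if has_user:
            row["user"] = p.user or ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def _split(text: str) -> frozenset:
    return frozenset(part.strip() for part in str(text).split(";") if part.strip())
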