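"""Construction of labelled landmark samples and balanced per-emotion
binary tasks.

Each sample pairs a 44-value normalized landmark feature vector with a
7-bit emotion label vector (anger, disgust, fear, happy, neutral, sad,
surprise) encoding the participant's self-reported emotions — 1 for each
selected emotion, 0 otherwise. Participants had to select at least one
emotion, so an all-zero label vector is invalid.

For training, the multi-label problem is decomposed into seven binary
tasks, one per emotion (selected = class 1, not selected = class 0). Class
1 is typically the minority; balancing keeps every positive sample and
undersamples the negatives so that the class difference equals half the
minority count — i.e. negatives are capped at ``n_pos + floor(n_pos / 2)``.
Negatives span a wider variety of expressions than positives, which is why
the majority class is not cut all the way down to parity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .emotions import EMOTIONS, EMOTION_INDEX, validate_emotions

logger = logging.getLogger(__name__)

N_FEATURES = 44

METADATA_COLUMNS = ("subject", "sex", "age_band", "glasses")


def encode_labels(selected: Iterable[str]) -> np.ndarray:
    """Encode a set of selected emotion names as a 7-bit vector.

    Bit order is the fixed emotion order (anger, disgust, fear, happy,
    neutral, sad, surprise). At least one emotion must be selected.
    """
    names = set(selected)
    if not names:
        raise ValueError("at least one emotion required")
    validate_emotions(names)
    bits = np.zeros(len(EMOTIONS), dtype=int)
    for name in names:
        bits[EMOTION_INDEX[name]] = 1
    return bits


def decode_labels(bits: Sequence[int]) -> frozenset:
    """Inverse of :func:`encode_labels`: bit vector back to the emotion set."""
    bits = np.asarray(bits, dtype=int)
    if bits.shape != (len(EMOTIONS),):
        raise ValueError(f"label vector must have length {len(EMOTIONS)}")
    if not set(np.unique(bits)) <= {0, 1}:
        raise ValueError("label bits must be 0 or 1")
    if bits.sum() == 0:
        raise ValueError("at least one emotion required")
    return frozenset(e for e, b in zip(EMOTIONS, bits) if b)


@dataclass
class FeelPixSample:
    """One labelled observation: feature vector + emotion bits + metadata."""

    sample_id: str
    features: np.ndarray
    labels: np.ndarray
    subject: str | None = None
    sex: str | None = None
    age_band: str | None = None
    glasses: bool | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.shape != (N_FEATURES,):
            raise ValueError(
                f"feature vector must have length {N_FEATURES}, got {self.features.shape}"
            )
        if not np.isfinite(self.features).all():
            raise ValueError("features must be finite")
        self.labels = np.asarray(self.labels, dtype=int)
        decode_labels(self.labels)  # validates shape, bits, and non-emptiness

    @property
    def selected(self) -> frozenset:
        return decode_labels(self.labels)


@dataclass
class BinaryTask:
    """One emotion's binary classification view of the dataset."""

    emotion: str
    X: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y must have the same number of rows")

    @property
    def n_pos(self) -> int:
        return int(self.y.sum())

    @property
    def n_neg(self) -> int:
        return int((self.y == 0).sum())


def binarize(dataset: Sequence[FeelPixSample], emotion: str) -> BinaryTask:
    """Project the multi-label dataset onto one emotion's binary task."""
    if not dataset:
        raise ValueError("dataset is empty")
    validate_emotions([emotion])
    idx = EMOTION_INDEX[emotion]
    X = np.stack([s.features for s in dataset])
    y = np.array([int(s.labels[idx]) for s in dataset])
    return BinaryTask(emotion=emotion, X=X, y=y)


def undersample(task: BinaryTask, seed: int = 0) -> BinaryTask:
    """Balance a binary task by undersampling the majority (negative) class.

    All positives are kept; negatives are reduced by seeded uniform sampling
    without replacement to ``n_pos + floor(n_pos / 2)``, so the residual
    class difference equals half the minority count. If the negatives
    already fit under that cap — or positives are not the minority — the
    task is returned unchanged.
    """
    n_pos, n_neg = task.n_pos, task.n_neg
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"cannot balance '{task.emotion}': class counts pos={n_pos}, neg={n_neg}"
        )
    if n_pos > n_neg:
        logger.info(
            "undersample('%s'): positives (%d) outnumber negatives (%d); "
            "task returned unchanged", task.emotion, n_pos, n_neg,
        )
        return task
    cap = n_pos + n_pos // 2
    if n_neg <= cap:
        return task
    rng = np.random.default_rng(seed)
    neg_idx = np.flatnonzero(task.y == 0)
    keep_neg = rng.choice(neg_idx, size=cap, replace=False)
    keep = np.sort(np.concatenate([np.flatnonzero(task.y == 1), keep_neg]))
    return BinaryTask(emotion=task.emotion, X=task.X[keep], y=task.y[keep])


def build_samples(
    features: np.ndarray,
    selections: Sequence[Iterable[str]],
    sample_ids: Sequence[str] | None = None,
    subjects: Sequence[str] | None = None,
) -> list[FeelPixSample]:
    """Assemble samples from a feature matrix and per-row emotion selections."""
    features = np.asarray(features, dtype=float)
    n = features.shape[0]
    if len(selections) != n:
        raise ValueError("features and selections must have equal length")
    sample_ids = sample_ids or [f"s{i:05d}" for i in range(n)]
    return [
        FeelPixSample(
            sample_id=str(sample_ids[i]),
            features=features[i],
            labels=encode_labels(selections[i]),
            subject=None if subjects is None else str(subjects[i]),
        )
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# CSV interface

_FEATURE_COLS = tuple(f"f{i}" for i in range(N_FEATURES))
_REQUIRED_COLS = ("sample_id",) + _FEATURE_COLS + EMOTIONS


def write_feelpix(samples: Sequence[FeelPixSample], path: str | Path) -> None:
    """Write samples as CSV: ``sample_id,f0..f43,anger..surprise[,metadata]``."""
    rows = []
    has_meta = any(s.subject is not None for s in samples)
    for s in samples:
        row = {"sample_id": s.sample_id}
        row.update({f"f{i}": v for i, v in enumerate(s.features)})
        row.update({e: int(b) for e, b in zip(EMOTIONS, s.labels)})
        if has_meta:
            row.update({
                "subject": s.subject or "",
                "sex": s.sex or "",
                "age_band": s.age_band or "",
                "glasses": "" if s.glasses is None else int(s.glasses),
            })
        rows.append(row)
    columns = list(_REQUIRED_COLS) + (list(METADATA_COLUMNS) if has_meta else [])
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False, float_format="%.17g")


def read_feelpix(path: str | Path) -> list[FeelPixSample]:
    """Read a FeelPix-style CSV, validating invariants row by row.

    Malformed rows (non-finite features, invalid label bits, all-zero
    labels) are logged and skipped; missing required columns raise.
    """
    df = pd.read_csv(path, dtype={"sample_id": str})
    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"missing column(s): {', '.join(missing)}")
    samples: list[FeelPixSample] = []
    for pos, row in df.iterrows():
        try:
            meta = {}
            if "subject" in df.columns and pd.notna(row.get("subject")):
                meta["subject"] = str(row["subject"])
            if "sex" in df.columns and pd.notna(row.get("sex")):
                meta["sex"] = str(row["sex"])
            if "age_band" in df.columns and pd.notna(row.get("age_band")):
                meta["age_band"] = str(row["age_band"])
            if "glasses" in df.columns and pd.notna(row.get("glasses")):
                meta["glasses"] = bool(int(row["glasses"]))
            samples.append(FeelPixSample(
                sample_id=str(row["sample_id"]),
                features=row[list(_FEATURE_COLS)].to_numpy(dtype=float),
                labels=row[list(EMOTIONS)].to_numpy(dtype=int),
                **meta,
            ))
        except (ValueError, TypeError) as exc:
            logger.warning("skipping malformed row %s (%s): %s",
                           pos, row.get("sample_id", "?"), exc)
    return samples
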