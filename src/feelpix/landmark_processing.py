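"""Anchor-based normalization of 68-point facial landmark frames and
reduction to the 22 expression-informative points.

Raw landmark coordinates depend on where the face sits in the camera's field
of view and on the subject's physiognomy. Four anatomical anchor points whose
position is essentially unaffected by facial expression — the left and right
lateral face points, the nasal center (top of the nose bridge), and the
subnasal center (base of the nose) — define a per-face coordinate frame:

* x coordinates left of the nasal center are divided by the horizontal
  nasal-center-to-left-anchor distance, those to the right by the
  nasal-center-to-right-anchor distance (balancing facial asymmetry);
* all y coordinates are divided by the vertical nasal-to-subnasal distance;
* the nasal center becomes the origin.

The result is invariant to translation and to independent positive scalings
of the two image axes. The feature vector then keeps only the 22 landmarks
lying over the facial muscles that the Facial Action Coding System singles
out as the drivers of expression (brows, eye region, nose wings, mouth),
giving 44 values per face.

Coordinates follow the image-pixel convention: y grows downward; no axis is
flipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

N_LANDMARKS = 68

#: Default 22-point expression subset over the standard 68-point scheme:
#: brows (17, 19, 24, 26), eye corners and lids (36, 37, 39, 42, 44, 45),
#: nose wings (31, 35), and mouth outline plus inner lips
#: (48, 50, 51, 52, 54, 56, 57, 58, 62, 66).
DEFAULT_FEATURE_INDICES: tuple[int, ...] = (
    17, 19, 24, 26,
    36, 37, 39, 42, 44, 45,
    31, 35,
    48, 50, 51, 52, 54, 56, 57, 58, 62, 66,
)


@dataclass
class LandmarkFrame:
    """One face observation: an ordered (N, 2) array of landmark coordinates.

    ``space`` records whether the points are raw pixels or anchor-normalized.
    """

    points: np.ndarray
    space: str = "raw"

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 1:
            raise ValueError("points must be an (N, 2) array with N >= 1")
        if not np.isfinite(pts).all():
            raise ValueError("landmark coordinates must be finite")
        if self.space not in ("raw", "normalized"):
            raise ValueError("space must be 'raw' or 'normalized'")
        self.points = pts

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class AnchorSet:
    """Indices of the four expression-stable anchor landmarks.

    Defaults target the 68-point scheme: the outer jaw/temple points (0, 16)
    as lateral anchors, the top of the nose bridge (27) as the nasal center,
    and the base of the nose (33) as the subnasal center.
    """

    left_anchor: int = 0
    right_anchor: int = 16
    nasal_center: int = 27
    subnasal_center: int = 33

    def __post_init__(self) -> None:
        idx = (self.left_anchor, self.right_anchor, self.nasal_center, self.subnasal_center)
        if len(set(idx)) != 4:
            raise ValueError("anchor indices must be distinct")
        if any(i < 0 for i in idx):
            raise ValueError("anchor indices must be non-negative")

    def validate_for(self, frame: LandmarkFrame) -> None:
        idx = (self.left_anchor, self.right_anchor, self.nasal_center, self.subnasal_center)
        if max(idx) >= frame.n_points:
            raise ValueError(
                f"anchor index {max(idx)} out of range for a {frame.n_points}-point frame"
            )


@dataclass(frozen=True)
class FeatureSubset:
    """Ordered landmark indices retained in the feature vector."""

    indices: tuple[int, ...] = DEFAULT_FEATURE_INDICES

    def __post_init__(self) -> None:
        if len(set(self.indices)) != len(self.indices):
            raise ValueError("feature subset indices must be distinct")
        if any(i < 0 for i in self.indices):
            raise ValueError("feature subset indices must be non-negative")

    def __len__(self) -> int:
        return len(self.indices)


def anchor_distances(frame: LandmarkFrame, anchors: AnchorSet | None = None) -> tuple[float, float, float]:
    """Axis-aligned distances between the anchor pairs of a raw frame.

    Returns ``(d_left, d_right, d_vert)``: nasal-center-to-left-anchor and
    right-anchor-to-nasal-center horizontal deltas, and the absolute vertical
    nasal-to-subnasal delta. All three must be strictly positive for the
    anchors to define a usable face frame.
    """
    anchors = anchors or AnchorSet()
    if frame.space != "raw":
        raise ValueError("anchor distances are defined on raw frames")
    anchors.validate_for(frame)
    pts = frame.points
    d_left = pts[anchors.nasal_center, 0] - pts[anchors.left_anchor, 0]
    d_right = pts[anchors.right_anchor, 0] - pts[anchors.nasal_center, 0]
    d_vert = abs(pts[anchors.subnasal_center, 1] - pts[anchors.nasal_center, 1])
    if d_left <= 0 or d_right <= 0 or d_vert <= 0:
        raise ValueError(
            f"degenerate anchors: d_left={d_left:g}, d_right={d_right:g}, d_vert={d_vert:g}"
        )
    return float(d_left), float(d_right), float(d_vert)


def normalize_frame(frame: LandmarkFrame, anchors: AnchorSet | None = None) -> LandmarkFrame:
    """Normalize a raw frame into the anchor-defined coordinate system.

    With the nasal center as origin, x deltas are divided by the left or
    right horizontal anchor distance according to which side of the nasal
    center the point lies on (points exactly at the nasal x use the right
    distance), and y deltas by the vertical anchor distance, for every point
    regardless of position.
    """
    anchors = anchors or AnchorSet()
    d_left, d_right, d_vert = anchor_distances(frame, anchors)
    pts = frame.points
    origin = pts[anchors.nasal_center]
    dx = pts[:, 0] - origin[0]
    dy = pts[:, 1] - origin[1]
    x_norm = np.where(dx < 0, dx / d_left, dx / d_right)
    y_norm = dy / d_vert
    return LandmarkFrame(points=np.column_stack([x_norm, y_norm]), space="normalized")


def select_features(frame: LandmarkFrame, subset: FeatureSubset | None = None) -> np.ndarray:
    """Flatten the normalized coordinates of the subset landmarks.

    Returns ``(x, y)`` pairs concatenated in subset order — 44 values for the
    default 22-point subset.
    """
    subset = subset or FeatureSubset()
    if frame.space != "normalized":
        raise ValueError("normalize first: feature selection requires a normalized frame")
    if subset.indices and max(subset.indices) >= frame.n_points:
        raise ValueError(
            f"subset index {max(subset.indices)} out of range for a "
            f"{frame.n_points}-point frame"
        )
    return frame.points[list(subset.indices)].reshape(-1).copy()


def extract_features(
    frame: LandmarkFrame,
    anchors: AnchorSet | None = None,
    subset: FeatureSubset | None = None,
) -> np.ndarray:
    """Convenience: normalize a raw frame and select the feature subset."""
    return select_features(normalize_frame(frame, anchors), subset)


# ---------------------------------------------------------------------------
# CSV interfaces


def write_frames_csv(frames: Sequence[LandmarkFrame], sample_ids: Sequence[str], path: str | Path) -> None:
    """Write frames as rows ``sample_id, x0, y0, ..., x{N-1}, y{N-1}``."""
    if len(frames) != len(sample_ids):
        raise ValueError("frames and sample_ids must have equal length")
    n = frames[0].n_points if frames else N_LANDMARKS
    columns = ["sample_id"] + [f"{axis}{i}" for i in range(n) for axis in ("x", "y")]
    rows = []
    for sid, frame in zip(sample_ids, frames):
        if frame.n_points != n:
            raise ValueError("all frames in one file must have the same point count")
        rows.append([sid] + frame.points.reshape(-1).tolist())
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False, float_format="%.17g")


def read_frames_csv(path: str | Path, space: str = "raw") -> tuple[list[LandmarkFrame], list[str]]:
    """Read frames written by :func:`write_frames_csv`; returns (frames, ids)."""
    df = pd.read_csv(path, dtype={"sample_id": str})
    coord_cols = [c for c in df.columns if c != "sample_id"]
    if len(coord_cols) % 2 != 0 or not coord_cols:
        raise ValueError("frame CSV must have an even, positive number of coordinate columns")
    frames, ids = [], []
    for _, row in df.iterrows():
        pts = row[coord_cols].to_numpy(dtype=float).reshape(-1, 2)
        frames.append(LandmarkFrame(points=pts, space=space))
        ids.append(str(row["sample_id"]))
    return frames, ids


def write_features_csv(features: np.ndarray, sample_ids: Sequence[str], path: str | Path) -> None:
    """Write a feature matrix as rows ``sample_id, f0, ..., f{d-1}``."""
    features = np.asarray(features, dtype=float)
    columns = ["sample_id"] + [f"f{i}" for i in range(features.shape[1])]
    df = pd.DataFrame(features, columns=columns[1:])
    df.insert(0, "sample_id", list(sample_ids))
    df.to_csv(path, index=False, float_format="%.17g")


def read_features_csv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, dtype={"sample_id": str})
    cols = [c for c in df.columns if c != "sample_id"]
    return df[cols].to_numpy(dtype=float), df["sample_id"].astype(str).tolist()
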