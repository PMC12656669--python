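"""Occlusion detection from redundant-detection confidence scores, and
occlusion simulation by body-part group.

Detection: top-down pose estimators emit clusters of redundant detections
per person.  For each keypoint *i* the cluster scores are merged with a
score-weight rule,

    merge_score_i = sum_j cluster_scores[j, i] * masked_scores[j, i]
                    / sum_k masked_scores[k, i],

where ``masked_scores`` zeroes detections too far from the reference pose
(upstream pose-NMS behaviour; accepted as given, not recomputed).  A
keypoint is visible iff its merged score strictly exceeds a threshold tau
(default 0.5); occluded joints have depressed confidence, so the weighted
mean drops below tau.  If every mask weight is zero the merged score is
defined as 0 and the keypoint treated as occluded — the conservative
reading of a keypoint no detection supports.

Simulation: keypoints of selected body-part groups are replaced with the
exact (0, 0) sentinel over the last ``k`` frames (suffix mode, the
canonical experiment with k in {10, 20, 30, 40}) or an explicit frame
range.  Suffix removal emulates the realistic case where a tracker only
has past frames to extrapolate from.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sequences import GaitSequence
from .skeleton import N_KEYPOINTS, BodyPart

__all__ = [
    "PoseCluster",
    "OcclusionSpec",
    "merge_score",
    "detect_occluded",
    "apply_detector",
    "simulate_missing",
    "DEFAULT_TAU",
]

DEFAULT_TAU = 0.5


@dataclass
class PoseCluster:
    """Redundant pose detections for one frame of one person.

    ``cluster_scores`` holds the raw per-keypoint confidences of every
    detection in the cluster; ``masked_scores`` is the same matrix with
    rows (or entries) zeroed for detections too far from the reference
    pose.  Both have shape (detections, 17).
    """

    cluster_scores: np.ndarray
    masked_scores: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.cluster_scores = np.atleast_2d(
            np.asarray(self.cluster_scores, dtype=float))
        if self.masked_scores is None:
            self.masked_scores = self.cluster_scores.copy()
        else:
            self.masked_scores = np.atleast_2d(
                np.asarray(self.masked_scores, dtype=float))
        if self.masked_scores.shape != self.cluster_scores.shape:
            raise ValueError(
                f"masked_scores shape {self.masked_scores.shape} != "
                f"cluster_scores shape {self.cluster_scores.shape}"
            )
        if self.cluster_scores.shape[0] == 0:
            raise ValueError("empty cluster: at least one detection required")


def merge_score(cluster: PoseCluster) -> np.ndarray:
    """Score-weight merged confidence per keypoint.

    Keypoints whose mask weights sum to zero merge to 0 (occluded).
    """
    c = cluster.cluster_scores
    m = cluster.masked_scores
    denom = m.sum(axis=0)
    num = (c * m).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        merged = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    return merged


def detect_occluded(merged: np.ndarray, tau: float = DEFAULT_TAU) -> np.ndarray:
    """Boolean occlusion flags: visible iff ``merged > tau`` (strict)."""
    if not (0.0 <= tau <= 1.0):
        raise ValueError(f"tau must lie in [0, 1], got {tau}")
    merged = np.asarray(merged, dtype=float)
    return ~(merged > tau)


def apply_detector(seq: GaitSequence, tau: float = DEFAULT_TAU) -> GaitSequence:
    """Flag keypoints whose stored confidence falls at or below tau.

    Uses the sequence's per-keypoint scores as the (already merged)
    confidence; returns a copy with visibility updated.
    """
    out = seq.copy()
    occluded = ~(out.scores > tau)
    out.visibility &= ~occluded
    return out


@dataclass
class OcclusionSpec:
    """What to remove: which body-part groups, and which frames.

    ``missing_frames`` = k removes the last k frames (suffix mode);
    alternatively ``frame_range`` = (first, last), 1-indexed inclusive,
    removes an explicit interior range.
    """

    groups: tuple[BodyPart, ...]
    missing_frames: int = 0
    frame_range: tuple[int, int] | None = None
    fill: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        groups = []
        for g in self.groups:
            groups.append(BodyPart.from_name(g) if isinstance(g, str) else g)
        self.groups = tuple(groups)
        if self.missing_frames < 0:
            raise ValueError("missing_frames must be >= 0")

    def keypoint_indices(self) -> list[int]:
        idx: set[int] = set()
        for g in self.groups:
            idx.update(g.indices)
        return sorted(idx)

    def frame_indices(self, n_frames: int) -> np.ndarray:
        """0-indexed frames to remove."""
        if self.frame_range is not None:
            first, last = self.frame_range
            if not (1 <= first <= last <= n_frames):
                raise ValueError(
                    f"frame range ({first}, {last}) outside [1, {n_frames}]"
                )
            return np.arange(first - 1, last)
        k = self.missing_frames
        if k > n_frames:
            raise ValueError(
                f"missing_frames {k} exceeds sequence length {n_frames}"
            )
        return np.arange(n_frames - k, n_frames)


def simulate_missing(seq: GaitSequence, spec: OcclusionSpec) -> GaitSequence:
    """Return a copy with the spec's keypoints zero-filled and flagged.

    The number of zeroed coordinate values is exactly
    ``2 * |keypoints| * |frames removed|`` (e.g. head with a 40-frame
    suffix on a 50-frame record zeroes 400 of the 1700 values).  The
    operation is idempotent for a fixed spec and never mutates its input.
    """
    out = seq.copy()
    kps = spec.keypoint_indices()
    frames = spec.frame_indices(seq.n_frames)
    if len(kps) == 0 or len(frames) == 0:
        return out
    fi = frames[:, None]
    out.coords[fi, kps, :] = np.asarray(spec.fill, dtype=float)
    out.visibility[fi, kps] = False
    out.scores[fi, kps] = 0.0
    return out
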