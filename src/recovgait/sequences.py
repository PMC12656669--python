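"""Keypoint-sequence data model and on-disk formats.

A :class:`GaitSequence` is the universal currency of the pipeline: one
subject's fixed-length trajectory of COCO-17 keypoints with per-keypoint
confidence scores and a visibility mask.  A missing (occluded) keypoint is
encoded with the exact coordinate sentinel ``(0, 0)``; the visibility mask
is false exactly where that sentinel appears or where the occlusion
detector has flagged the keypoint.

Two serializations are supported:

* a flat CSV record layout — one row per video: ``subject_id, label``
  followed by ``frames x 17 x 2`` coordinate values, frame-major, keypoint
  ascending, ``(x, y)`` interleaved.  For the default 50 frames that is
  1700 coordinate values per record.  The CSV carries coordinates only.
* pose-estimator JSON — an array of frame entries, each listing detected
  people with 17 ``[x, y, score]`` triplets.  JSON is the score-bearing
  format.

Coordinates are pixels in the standard image convention (origin top-left,
x rightward, y downward).  Frames are 0-indexed internally and 1-indexed
in user-facing messages.
"""

from __future__ import annotations

import csv
import enum
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .skeleton import GROUP_INDICES, N_KEYPOINTS, BodyPart

logger = logging.getLogger(__name__)

DEFAULT_FRAMES = 50

__all__ = [
    "Label",
    "GaitSequence",
    "MalformedRecordError",
    "read_records_csv",
    "write_records_csv",
    "parse_pose_json",
    "flatten_record",
    "unflatten_record",
]


class Label(str, enum.Enum):
    PD = "PD"
    HEALTHY = "HEALTHY"
    UNKNOWN = "UNKNOWN"


class MalformedRecordError(ValueError):
    """A CSV row or JSON entry does not match the expected record layout."""


@dataclass
class GaitSequence:
    """One subject's keypoint trajectory.

    Attributes
    ----------
    subject_id : str
        Subject identifier.  Augmented variants keep the base id with a
        ``#variant`` suffix so leakage-safe splitting can group them.
    label : Label
        PD / HEALTHY / UNKNOWN class label.
    coords : ndarray, shape (frames, 17, 2)
        Pixel coordinates; the exact value ``(0, 0)`` marks a missing
        keypoint.
    scores : ndarray, shape (frames, 17)
        Detection confidence in [0, 1]; 1.0 for visible and 0.0 for
        sentinel keypoints when no score source is available.
    visibility : ndarray of bool, shape (frames, 17)
        False where the keypoint is missing or flagged occluded.
    imputed : ndarray of bool, shape (frames, 17)
        True where a recovery method wrote the coordinate.
    """

    subject_id: str
    label: Label
    coords: np.ndarray
    scores: np.ndarray = None  # type: ignore[assignment]
    visibility: np.ndarray = None  # type: ignore[assignment]
    imputed: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (N_KEYPOINTS, 2):
            raise ValueError(
                f"coords must have shape (frames, {N_KEYPOINTS}, 2), "
                f"got {self.coords.shape}"
            )
        sentinel = self.sentinel_mask()
        if self.visibility is None:
            self.visibility = ~sentinel
        else:
            self.visibility = np.asarray(self.visibility, dtype=bool)
            # the sentinel always implies invisibility
            self.visibility = self.visibility & ~sentinel
        if self.scores is None:
            self.scores = self.visibility.astype(float)
        else:
            self.scores = np.asarray(self.scores, dtype=float)
        if self.imputed is None:
            self.imputed = np.zeros(self.visibility.shape, dtype=bool)
        else:
            self.imputed = np.asarray(self.imputed, dtype=bool)
        shape = (self.n_frames, N_KEYPOINTS)
        for name in ("scores", "visibility", "imputed"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} must have shape {shape}, got {arr.shape}")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def sentinel_mask(self) -> np.ndarray:
        """Boolean (frames, 17) mask of exact-(0, 0) missing keypoints."""
        return np.all(self.coords == 0.0, axis=2)

    @property
    def base_id(self) -> str:
        """Subject id with any augmentation suffix stripped."""
        return self.subject_id.split("#", 1)[0]

    def copy(self) -> "GaitSequence":
        return GaitSequence(
            subject_id=self.subject_id,
            label=self.label,
            coords=self.coords.copy(),
            scores=self.scores.copy(),
            visibility=self.visibility.copy(),
            imputed=self.imputed.copy(),
        )

    def allclose(self, other: "GaitSequence", **kw) -> bool:
        return (
            self.subject_id == other.subject_id
            and self.label == other.label
            and self.coords.shape == other.coords.shape
            and np.allclose(self.coords, other.coords, **kw)
        )


def flatten_record(seq: GaitSequence) -> np.ndarray:
    """Flatten to the record layout: frame-major, keypoint-ascending, (x, y).

    A 50-frame sequence flattens to 1700 values (50 frames x 34 values).
    """
    return seq.coords.reshape(-1).copy()


def unflatten_record(values: np.ndarray, subject_id: str = "",
                     label: Label = Label.UNKNOWN) -> GaitSequence:
    """Inverse of :func:`flatten_record`; frame count inferred from length."""
    values = np.asarray(values, dtype=float)
    if values.size % (2 * N_KEYPOINTS) != 0:
        raise MalformedRecordError(
            f"flat record length {values.size} is not a multiple of "
            f"{2 * N_KEYPOINTS}"
        )
    coords = values.reshape(-1, N_KEYPOINTS, 2)
    return GaitSequence(subject_id=subject_id, label=label, coords=coords)


def _csv_header(frames: int) -> list[str]:
    cols = ["subject_id", "label"]
    for f in range(1, frames + 1):  # 1-indexed in the file, like user messages
        for k in range(N_KEYPOINTS):
            cols.append(f"f{f}_k{k}_x")
            cols.append(f"f{f}_k{k}_y")
    return cols


def write_records_csv(seqs: list[GaitSequence], path: str | Path,
                      frames: int | None = None) -> None:
    """Write sequences in the flat record layout, one row per video."""
    path = Path(path)
    if seqs:
        counts = {s.n_frames for s in seqs}
        if len(counts) > 1:
            offenders = sorted({s.subject_id for s in seqs}
                               )[:10]
            raise ValueError(
                f"sequences have heterogeneous frame counts {sorted(counts)}; "
                f"offending ids include {offenders}"
            )
        frames = seqs[0].n_frames
    elif frames is None:
        frames = DEFAULT_FRAMES
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_csv_header(frames))
        for seq in seqs:
            row = [seq.subject_id, seq.label.value]
            row.extend(repr(float(v)) for v in flatten_record(seq))
            writer.writerow(row)


def read_records_csv(path: str | Path) -> list[GaitSequence]:
    """Read the flat CSV record layout.

    Visibility is inferred from (0, 0) sentinels; scores are set to 1.0
    for visible and 0.0 for sentinel keypoints (the CSV carries no scores).
    """
    path = Path(path)
    seqs: list[GaitSequence] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise MalformedRecordError(f"{path}: empty file, header row required")
        n_values = len(header) - 2
        if n_values <= 0 or n_values % (2 * N_KEYPOINTS) != 0:
            raise MalformedRecordError(
                f"{path}: header implies {n_values} coordinate columns, "
                f"not a positive multiple of {2 * N_KEYPOINTS}"
            )
        for row_idx, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != n_values + 2:
                raise MalformedRecordError(
                    f"{path} row {row_idx}: expected {n_values + 2} cells "
                    f"(id, label, {n_values} values), got {len(row)}"
                )
            subject_id, label_str = row[0], row[1]
            try:
                label = Label(label_str.upper())
            except ValueError:
                raise MalformedRecordError(
                    f"{path} row {row_idx}: unknown label {label_str!r}"
                ) from None
            try:
                values = np.array(row[2:], dtype=float)
            except ValueError:
                for col, cell in enumerate(row[2:], start=3):
                    try:
                        float(cell)
                    except ValueError:
                        raise MalformedRecordError(
                            f"{path} row {row_idx}, column {col}: "
                            f"non-numeric cell {cell!r}"
                        ) from None
                raise
            seqs.append(unflatten_record(values, subject_id=subject_id,
                                         label=label))
    return seqs


def parse_pose_json(path: str | Path, frames: int = DEFAULT_FRAMES,
                    label: Label = Label.UNKNOWN,
                    subject_id: str | None = None) -> list[GaitSequence]:
    """Parse pose-estimator JSON output into a single-subject sequence list.

    The expected shape is an array of
    ``{"frame_index": i, "people": [{"keypoints": [x, y, score] * 17}]}``.
    When several people are detected, the one with the highest mean
    keypoint score across frames is kept (the recordings are
    single-patient).  Scores are clamped to [0, 1]; a frame with zero
    detections is recorded with all keypoints sentinel and scores 0.
    """
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        entries = json.load(fh)
    if not isinstance(entries, list):
        raise MalformedRecordError(f"{path}: expected a JSON array of frames")
    if len(entries) > frames:
        warnings.warn(
            f"{path}: {len(entries)} frame entries, truncating to {frames}",
            stacklevel=2,
        )
        entries = entries[:frames]

    n_people = max((len(e.get("people", [])) for e in entries), default=0)
    # per-candidate stacked (frames, 17, 3) arrays, NaN where undetected
    kp = np.full((max(n_people, 1), frames, N_KEYPOINTS, 3), np.nan)
    for f, entry in enumerate(entries):
        people = entry.get("people", [])
        for p, person in enumerate(people):
            flat = np.asarray(person["keypoints"], dtype=float)
            if flat.size != N_KEYPOINTS * 3:
                raise MalformedRecordError(
                    f"{path} frame {f + 1}: keypoints must hold "
                    f"{N_KEYPOINTS * 3} values, got {flat.size}"
                )
            kp[p, f] = flat.reshape(N_KEYPOINTS, 3)

    with np.errstate(invalid="ignore"):
        mean_scores = np.nanmean(np.nan_to_num(kp[..., 2], nan=0.0),
                                 axis=(1, 2))
    best = int(np.argmax(mean_scores)) if n_people else 0
    person = kp[best]

    coords = np.nan_to_num(person[..., :2], nan=0.0)
    scores = np.nan_to_num(person[..., 2], nan=0.0)
    if np.any((scores < 0) | (scores > 1)):
        logger.warning("%s: clamping %d out-of-range confidence scores",
                       path, int(np.sum((scores < 0) | (scores > 1))))
        scores = np.clip(scores, 0.0, 1.0)
    seq = GaitSequence(
        subject_id=subject_id or path.stem,
        label=label,
        coords=coords,
        scores=scores,
    )
    return [seq]


def group_indices(group: BodyPart | str) -> tuple[int, ...]:
    """Keypoint indices of a body-part group (accepts name strings)."""
    if isinstance(group, str):
        group = BodyPart.from_name(group)
    return GROUP_INDICES[group]
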