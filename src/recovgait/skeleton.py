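"""COCO-17 skeleton constants and the four body-part keypoint groups.

The 17-keypoint convention (nose, eyes, ears, shoulders, elbows, wrists,
hips, knees, ankles) is partitioned into four regions used for occlusion
simulation and per-region reporting.  Note the slightly unusual grouping:
the wrists travel with the hips region because during walking the hands
swing at hip height, so their occlusion statistics behave like the hips'.
"""

from __future__ import annotations

import enum

N_KEYPOINTS = 17

KEYPOINT_NAMES = (
    "nose",
    "left_eye",
    "right_eye",
    "left_ear",
    "right_ear",
    "left_shoulder",
    "right_shoulder",
    "left_elbow",
    "right_elbow",
    "left_wrist",
    "right_wrist",
    "left_hip",
    "right_hip",
    "left_knee",
    "right_knee",
    "left_ankle",
    "right_ankle",
)


class BodyPart(str, enum.Enum):
    """The four keypoint regions driving occlusion simulation."""

    HEAD = "head"
    BODY = "body"
    HIPS = "hips"
    LEGS = "legs"

    @property
    def indices(self) -> tuple[int, ...]:
        return GROUP_INDICES[self]

    @classmethod
    def from_name(cls, name: str) -> "BodyPart":
        try:
            return cls(name.lower())
        except ValueError:
            valid = ", ".join(p.value for p in cls)
            raise ValueError(
                f"unknown body-part group {name!r}; valid groups: {valid}"
            ) from None


# head = facial keypoints; body = shoulders + elbows; hips = wrists + hips;
# legs = knees + ankles.  The groups partition {0..16}.
GROUP_INDICES: dict[BodyPart, tuple[int, ...]] = {
    BodyPart.HEAD: (0, 1, 2, 3, 4),
    BodyPart.BODY: (5, 6, 7, 8),
    BodyPart.HIPS: (9, 10, 11, 12),
    BodyPart.LEGS: (13, 14, 15, 16),
}
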