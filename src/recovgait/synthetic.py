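"""Synthetic walking-skeleton generator and the x4 augmentation scheme.

The generator emits labeled COCO-17 keypoint sequences of two classes,
built from the simplest kinematic model with the cyclic, non-linear
structure a tracker must handle: the pelvis translates at constant walking
speed while legs and arms oscillate sinusoidally (left/right antiphase,
arms counter-phase to the ipsilateral leg).  The Parkinsonian profile has
strictly smaller stride amplitude, arm swing and walking speed than the
healthy profile — the reduced, shuffling step and diminished arm swing
that characterise the PD gait phenotype — plus a slightly slower cadence.

Anatomical realism is a non-goal; the model exists so that every
downstream stage (occlusion, imputation, unscented tracking,
classification) can be exercised and validated without any recording.
The canvas offset guarantees every true coordinate is strictly positive,
so the (0, 0) missing-value sentinel is unambiguous and the analytic
zero-fill error identities hold exactly.

Augmentation mirrors the study design of flip / scale / translate,
yielding exactly four samples per subject (the original plus one variant
per transform).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .sequences import DEFAULT_FRAMES, GaitSequence, Label
from .skeleton import N_KEYPOINTS

__all__ = [
    "GaitProfile",
    "HEALTHY_PROFILE",
    "PD_PROFILE",
    "generate_subject",
    "augment",
    "make_dataset",
]


@dataclass(frozen=True)
class GaitProfile:
    """Kinematic parameters of one walking subject (pixels / frames)."""

    label: Label
    stride_amplitude: float  # px, leg swing about the hip
    arm_swing_amplitude: float  # px, wrist/elbow counter-swing
    cadence: float  # gait cycles per frame, in (0, 0.5)
    trunk_height: float  # px, pelvis to shoulder line
    jitter_sd: float  # px, detector noise on every coordinate
    walk_speed: float  # px per frame, pelvis drift

    def __post_init__(self) -> None:
        if not (0.0 < self.cadence < 0.5):
            raise ValueError(f"cadence must lie in (0, 0.5), got {self.cadence}")
        for name in ("stride_amplitude", "arm_swing_amplitude", "jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


# Defaults: a 2-second clip at 25 fps spans 50 frames; a healthy cadence of
# ~1 cycle/s maps to 0.04 cycles/frame — we use 0.08 so the 50-frame window
# holds four full cycles, giving the recurrent imputer enough repetitions.
HEALTHY_PROFILE = GaitProfile(
    label=Label.HEALTHY,
    stride_amplitude=20.0,
    arm_swing_amplitude=12.0,
    cadence=0.08,
    trunk_height=120.0,
    jitter_sd=0.5,
    walk_speed=4.0,
)

# Reduced stride, arm swing and speed; mildly slower cadence.
PD_PROFILE = GaitProfile(
    label=Label.PD,
    stride_amplitude=8.0,
    arm_swing_amplitude=4.0,
    cadence=0.065,
    trunk_height=120.0,
    jitter_sd=0.5,
    walk_speed=2.0,
)

# canvas offsets keep every coordinate strictly positive
_X0 = 120.0
_PELVIS_Y = 300.0

# (dx, dy) neutral offsets from the pelvis, in units of trunk_height,
# image convention (y grows downward).  Left = +x half of the body.
_NEUTRAL = {
    0: (0.00, -1.30),   # nose
    1: (0.04, -1.34),   # left_eye
    2: (-0.04, -1.34),  # right_eye
    3: (0.09, -1.30),   # left_ear
    4: (-0.09, -1.30),  # right_ear
    5: (0.18, -1.00),   # left_shoulder
    6: (-0.18, -1.00),  # right_shoulder
    7: (0.22, -0.60),   # left_elbow
    8: (-0.22, -0.60),  # right_elbow
    9: (0.24, -0.15),   # left_wrist
    10: (-0.24, -0.15),  # right_wrist
    11: (0.12, 0.00),   # left_hip
    12: (-0.12, 0.00),  # right_hip
    13: (0.12, 0.45),   # left_knee
    14: (-0.12, 0.45),  # right_knee
    15: (0.12, 0.90),   # left_ankle
    16: (-0.12, 0.90),  # right_ankle
}

# per-keypoint horizontal oscillation: (amplitude key, phase offset, gain)
# legs swing in the walking direction; arms counter-swing.
_LEG_GAIN = {13: 0.55, 14: 0.55, 15: 1.0, 16: 1.0}
_ARM_GAIN = {7: 0.6, 8: 0.6, 9: 1.0, 10: 1.0}
# left side leads by half a cycle
_LEFT = {1, 3, 5, 7, 9, 11, 13, 15}


def ankle_x_trajectory(profile: GaitProfile, frames: int,
                       side: str = "left") -> np.ndarray:
    """Closed-form noiseless ankle x trace: linear drift plus sinusoid.

    Exposed so tests can check the generator against the analytic model.
    """
    t = np.arange(frames)
    phase = 0.0 if side == "left" else np.pi
    k = 15 if side == "left" else 16
    return (
        _X0
        + profile.walk_speed * t
        + profile.trunk_height * _NEUTRAL[k][0]
        + profile.stride_amplitude
        * np.sin(2 * np.pi * profile.cadence * t + phase)
    )


def generate_subject(profile: GaitProfile, frames: int = DEFAULT_FRAMES,
                     seed: int = 0, subject_id: str | None = None) -> GaitSequence:
    """Generate one subject's walking sequence, deterministic in (profile, seed)."""
    if frames < 6:
        raise ValueError(
            f"frames must be >= 6 (one training window plus target), got {frames}"
        )
    rng = np.random.default_rng(seed)
    t = np.arange(frames)[:, None]  # (frames, 1)
    omega = 2 * np.pi * profile.cadence

    pelvis_x = _X0 + profile.walk_speed * t
    pelvis_y = _PELVIS_Y + 0.02 * profile.trunk_height * np.sin(2 * omega * t)

    coords = np.zeros((frames, N_KEYPOINTS, 2))
    for k in range(N_KEYPOINTS):
        dx, dy = _NEUTRAL[k]
        x = pelvis_x[:, 0] + dx * profile.trunk_height
        y = pelvis_y[:, 0] + dy * profile.trunk_height
        phase = 0.0 if k in _LEFT else np.pi
        if k in _LEG_GAIN:
            x = x + _LEG_GAIN[k] * profile.stride_amplitude * np.sin(
                omega * t[:, 0] + phase)
        elif k in _ARM_GAIN:
            # arms counter-swing: opposite phase to the ipsilateral leg
            x = x + _ARM_GAIN[k] * profile.arm_swing_amplitude * np.sin(
                omega * t[:, 0] + phase + np.pi)
        coords[:, k, 0] = x
        coords[:, k, 1] = y

    if profile.jitter_sd > 0:
        coords += rng.normal(0.0, profile.jitter_sd, size=coords.shape)
    if np.any(np.all(coords == 0.0, axis=2)):  # pragma: no cover - canvas guard
        raise RuntimeError("generated a (0, 0) coordinate; canvas offset too small")

    if subject_id is None:
        subject_id = f"{profile.label.value.lower()}-s{seed}"
    return GaitSequence(
        subject_id=subject_id,
        label=profile.label,
        coords=coords,
        scores=np.ones((frames, N_KEYPOINTS)),
    )


def _mid_hip_center(seq: GaitSequence) -> tuple[float, float]:
    """Mean (x, y) of the visible hip keypoints, the augmentation center."""
    vis = seq.visibility[:, [11, 12]]
    xy = seq.coords[:, [11, 12], :]
    if not np.any(vis):
        if np.any(seq.visibility):
            pts = seq.coords[seq.visibility]
            return float(np.mean(pts[:, 0])), float(np.mean(pts[:, 1]))
        return 0.0, 0.0
    return float(np.mean(xy[vis][:, 0])), float(np.mean(xy[vis][:, 1]))


def _transform(seq: GaitSequence, fn, suffix: str) -> GaitSequence:
    out = seq.copy()
    vis = seq.visibility
    xy = out.coords[vis]
    out.coords[vis] = fn(xy)
    out.subject_id = f"{seq.base_id}#{suffix}"
    return out


def augment(seq: GaitSequence, scale_factor: float = 0.9,
            translation: tuple[float, float] = (15.0, 10.0)) -> list[GaitSequence]:
    """Return ``[original, flipped, scaled, translated]`` variants.

    The flip mirrors x about the sequence's mean mid-hip x; the scale
    contracts both coordinates about the same center; translation adds a
    fixed (dx, dy).  Missing-value sentinels stay exactly (0, 0) under
    every transform, and labels are preserved.
    """
    cx, cy = _mid_hip_center(seq)
    original = seq.copy()
    original.subject_id = f"{seq.base_id}#orig"

    def flip(xy):
        out = xy.copy()
        out[:, 0] = 2.0 * cx - out[:, 0]
        return out

    def scale(xy):
        out = xy.copy()
        out[:, 0] = cx + scale_factor * (out[:, 0] - cx)
        out[:, 1] = cy + scale_factor * (out[:, 1] - cy)
        return out

    def translate(xy):
        return xy + np.asarray(translation)

    return [
        original,
        _transform(seq, flip, "flip"),
        _transform(seq, scale, "scale"),
        _transform(seq, translate, "translate"),
    ]


def _vary(profile: GaitProfile, rng: np.random.Generator) -> GaitProfile:
    """Between-subject variation: lognormal multipliers, sd ~10%."""
    m = rng.lognormal(mean=0.0, sigma=0.1, size=4)
    return replace(
        profile,
        stride_amplitude=profile.stride_amplitude * m[0],
        arm_swing_amplitude=profile.arm_swing_amplitude * m[1],
        walk_speed=profile.walk_speed * m[2],
        cadence=float(np.clip(profile.cadence * m[3], 0.01, 0.49)),
    )


def make_dataset(n_pd: int = 26, n_healthy: int = 50,
                 frames: int = DEFAULT_FRAMES, seed: int = 0,
                 augmented: bool = True,
                 scale_factor: float = 0.9,
                 translation: tuple[float, float] = (15.0, 10.0),
                 ) -> list[GaitSequence]:
    """Generate a labeled cohort; defaults mirror the 26 PD / 50 healthy
    study composition, which the x4 augmentation extends to 104 + 200.
    """
    if n_pd < 1 and n_healthy < 1:
        raise ValueError("at least one subject required")
    root = np.random.SeedSequence(seed)
    subject_seeds = root.spawn(n_pd + n_healthy)
    out: list[GaitSequence] = []
    specs = [(PD_PROFILE, i, f"pd{i:03d}") for i in range(n_pd)]
    specs += [(HEALTHY_PROFILE, n_pd + i, f"hc{i:03d}") for i in range(n_healthy)]
    for profile, idx, sid in specs:
        rng = np.random.default_rng(subject_seeds[idx])
        subj_profile = _vary(profile, rng)
        gen_seed = int(rng.integers(0, 2**31 - 1))
        seq = generate_subject(subj_profile, frames=frames, seed=gen_seed,
                               subject_id=sid)
        if augmented:
            out.extend(augment(seq, scale_factor=scale_factor,
                               translation=translation))
        else:
            out.append(seq)
    return out
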