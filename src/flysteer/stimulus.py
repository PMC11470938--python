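"""Pinwheel stimulus conditions for the freely-walking optomotor arena.

A radial sinusoidal grating ("pinwheel") is projected onto the arena roof,
centred and angle-locked on the fly's body with a fixed closed-loop delay of
three frame updates (<48 ms at 60 Hz).  Rotating the whole pinwheel produces
full-field rotation; splitting it into two half-field segments along the
body axis and rotating only one segment presents front-to-back (FtB) or
back-to-front (BtF) motion to a single eye.

Sign convention (used package-wide): arena angles are measured in degrees,
counter-clockwise positive, y-up.  The labels ``CW``/``CCW`` name the two
rotation directions of the pattern; trial analysis mirrors CCW trials so
that positive angular velocity always means "turning with the stimulus"
(see :func:`flysteer.kinematics.align_to_stimulus`).  Under that contract a
CW-labelled stimulus drives positive (syn) turning in arena coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from enum import Enum

import numpy as np
import pandas as pd

DEFAULT_CLOSED_LOOP_DELAY_FRAMES = 3
DEFAULT_PINWHEEL_DIAMETER_MM = 45.0


class ConditionKind(str, Enum):
    FULL_FIELD = "full_field"
    UNILATERAL_FTB = "unilateral_FtB"
    UNILATERAL_BTF = "unilateral_BtF"
    STATIC = "static"


class RotationDir(str, Enum):
    CW = "CW"
    CCW = "CCW"
    NONE = "none"


class Eye(str, Enum):
    LEFT = "left"
    RIGHT = "right"


class MotionClass(str, Enum):
    FTB = "FtB"
    BTF = "BtF"
    NONE = "none"


class UndefinedContrastError(ValueError):
    """Raised when both grating intensities are zero (0/0 contrast)."""


@dataclass(frozen=True)
class GratingPattern:
    """Luminance extremes and geometry of the pinwheel grating."""

    max_intensity: float = 1.0
    min_intensity: float = 0.0
    spatial_period_deg: float = 30.0
    profile: str = "sinusoidal"

    def __post_init__(self) -> None:
        if self.max_intensity < 0 or self.min_intensity < 0:
            raise ValueError("intensities must be non-negative")
        if self.max_intensity < self.min_intensity:
            raise ValueError("max_intensity must be >= min_intensity")
        if self.spatial_period_deg <= 0:
            raise ValueError("spatial_period_deg must be positive")
        if self.profile not in ("sinusoidal", "square"):
            raise ValueError(f"unknown profile {self.profile!r}")


@dataclass(frozen=True)
class StimulusCondition:
    """One trial condition: pattern, motion kind/direction and timing.

    Defaults follow the behavioural protocol: a 45 mm pinwheel, 5 s static
    then 5 s of rotation.
    """

    kind: ConditionKind
    rotation_dir: RotationDir
    pattern: GratingPattern = field(default_factory=GratingPattern)
    pinwheel_diameter_mm: float = DEFAULT_PINWHEEL_DIAMETER_MM
    rotation_speed_deg_s: float = 180.0
    static_duration_s: float = 5.0
    motion_duration_s: float = 5.0
    segment_split_angle_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.kind is ConditionKind.STATIC and self.rotation_dir is not RotationDir.NONE:
            raise ValueError("static condition requires rotation_dir 'none'")
        if self.kind is not ConditionKind.STATIC and self.rotation_dir is RotationDir.NONE:
            raise ValueError("moving condition requires a rotation direction")
        if self.static_duration_s <= 0 or self.motion_duration_s <= 0:
            raise ValueError("durations must be positive")
        if self.pinwheel_diameter_mm <= 0:
            raise ValueError("pinwheel_diameter_mm must be positive")

    def to_json(self) -> str:
        d = asdict(self)
        d["kind"] = self.kind.value
        d["rotation_dir"] = self.rotation_dir.value
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "StimulusCondition":
        d = json.loads(s)
        d["kind"] = ConditionKind(d["kind"])
        d["rotation_dir"] = RotationDir(d["rotation_dir"])
        d["pattern"] = GratingPattern(**d["pattern"])
        return cls(**d)


def michelson_contrast(pattern: GratingPattern) -> float:
    """(max − min) / (max + min) luminance contrast of the grating.

    Raises :class:`UndefinedContrastError` when both intensities are zero;
    the ratio is then 0/0 and reporting an arbitrary value would silently
    corrupt contrast-tuning summaries.
    """
    total = pattern.max_intensity + pattern.min_intensity
    if total == 0:
        raise UndefinedContrastError("contrast undefined: both intensities are zero")
    return (pattern.max_intensity - pattern.min_intensity) / total


def closed_loop_angle(
    body_angle_deg: np.ndarray,
    delay_frames: int = DEFAULT_CLOSED_LOOP_DELAY_FRAMES,
) -> np.ndarray:
    """Pose-locked stimulus anchor angle with the hardware update delay.

    The projected pattern follows the fly's body angle with a lag of
    ``delay_frames`` frame updates: ``anchor[t] = body_angle[t - delay]``.
    The first ``delay_frames`` samples repeat the initial angle (the pattern
    is already anchored when the trial starts).
    """
    body = np.asarray(body_angle_deg, dtype=float)
    if body.ndim != 1 or body.size == 0:
        raise ValueError("body_angle_deg must be a non-empty 1-D array")
    if delay_frames < 0:
        raise ValueError("delay_frames must be >= 0")
    if delay_frames == 0:
        return body.copy()
    anchor = np.empty_like(body)
    d = min(delay_frames, body.size)
    anchor[:d] = body[0]
    anchor[d:] = body[: body.size - d]
    return anchor


# (kind, rotation_dir) -> {eye: motion class}.  Under the documented
# convention a CW-rotating full pinwheel sweeps front-to-back across the
# left eye and back-to-front across the right eye; CCW mirrors this.  A
# unilateral condition rotates only the segment that produces the named
# motion class, so the direction selects which eye is stimulated.
_MOTION_TABLE = {
    (ConditionKind.FULL_FIELD, RotationDir.CW): {
        Eye.LEFT: MotionClass.FTB,
        Eye.RIGHT: MotionClass.BTF,
    },
    (ConditionKind.FULL_FIELD, RotationDir.CCW): {
        Eye.LEFT: MotionClass.BTF,
        Eye.RIGHT: MotionClass.FTB,
    },
    (ConditionKind.UNILATERAL_FTB, RotationDir.CW): {
        Eye.LEFT: MotionClass.FTB,
        Eye.RIGHT: MotionClass.NONE,
    },
    (ConditionKind.UNILATERAL_FTB, RotationDir.CCW): {
        Eye.LEFT: MotionClass.NONE,
        Eye.RIGHT: MotionClass.FTB,
    },
    (ConditionKind.UNILATERAL_BTF, RotationDir.CW): {
        Eye.LEFT: MotionClass.NONE,
        Eye.RIGHT: MotionClass.BTF,
    },
    (ConditionKind.UNILATERAL_BTF, RotationDir.CCW): {
        Eye.LEFT: MotionClass.BTF,
        Eye.RIGHT: MotionClass.NONE,
    },
}


def local_motion_direction(condition: StimulusCondition, eye: Eye) -> MotionClass:
    """Motion class (FtB / BtF / none) experienced by one eye."""
    eye = Eye(eye)
    if condition.kind is ConditionKind.STATIC:
        return MotionClass.NONE
    return _MOTION_TABLE[(condition.kind, condition.rotation_dir)][eye]


def make_trial_log(
    conditions: list[StimulusCondition],
    fs: float = 60.0,
    inter_trial_gap_s: float = 0.0,
) -> pd.DataFrame:
    """Sequential trial log for a session (one row per trial).

    Columns: trial_id, kind, rotation_dir, contrast, speed, t_start,
    t_motion_onset, t_end (seconds; frame-aligned at ``fs``).
    """
    rows = []
    t = 0.0
    for i, c in enumerate(conditions):
        t_start = t
        t_motion = t_start + c.static_duration_s
        t_end = t_motion + c.motion_duration_s
        rows.append(
            {
                "trial_id": i,
                "kind": c.kind.value,
                "rotation_dir": c.rotation_dir.value,
                "contrast": michelson_contrast(c.pattern),
                "speed": c.rotation_speed_deg_s,
                "t_start": t_start,
                "t_motion_onset": t_motion,
                "t_end": t_end,
            }
        )
        t = t_end + inter_trial_gap_s
    return pd.DataFrame(rows)
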