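"""Pose series → smoothed kinematics, trial segmentation and exclusions.

Speed and angular velocity are differenced from position and unwrapped
heading, then denoised with a rolling median followed by a rolling mean
(3 frames ≈ 50 ms each).  Frames exceeding 100 mm/s or 1000 deg/s are
flagged as jumps; trials containing a jump, approaching within 5 mm of the
arena wall, or inactive throughout are excluded.  Finally CCW-rotation
trials are mirrored so that positive angular velocity always means turning
with the stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

JUMP_SPEED_MM_S = 100.0
JUMP_ANGVEL_DEG_S = 1000.0
WALL_MARGIN_MM = 5.0
DEFAULT_SMOOTHING_WINDOW = 3
DEFAULT_INACTIVITY_SPEED_MM_S = 1.0


@dataclass
class Trial:
    trial_id: int
    kind: str
    rotation_dir: str
    start: int  # frame index (inclusive)
    motion_onset: int
    end: int  # frame index (exclusive)
    excluded: bool = False
    exclusion_reason: str = "none"
    mirrored: bool = False


def smooth_series(x: np.ndarray, window_frames: int = DEFAULT_SMOOTHING_WINDOW) -> np.ndarray:
    """Centred rolling median then centred rolling mean.

    Edges use shrinking windows; NaNs (invalid frames) are skipped rather
    than propagated, so a masked jump frame cannot leak into neighbours
    through the mean stage.
    """
    if window_frames < 1 or window_frames % 2 == 0:
        raise ValueError("window_frames must be odd and >= 1")
    s = pd.Series(np.asarray(x, dtype=float))
    med = s.rolling(window_frames, center=True, min_periods=1).median()
    return med.rolling(window_frames, center=True, min_periods=1).mean().to_numpy()


def unwrap_degrees(angle_deg: np.ndarray) -> np.ndarray:
    return np.degrees(np.unwrap(np.radians(np.asarray(angle_deg, dtype=float))))


def derive_kinematics(
    traj: pd.DataFrame,
    fs: float,
    smoothing_window: int = DEFAULT_SMOOTHING_WINDOW,
    per_trial: bool = True,
) -> pd.DataFrame:
    """Add ``speed`` (mm/s), ``ang_vel`` (deg/s, CCW+) and ``heading_unwrapped_deg``.

    Differencing is backward (value at frame i uses frames i-1, i); the
    first frame repeats the second so the series keeps full length.  When
    ``per_trial`` and a ``trial_id`` column is present, differencing and
    smoothing restart at each trial boundary (trials are separate episodes).
    """
    def _one(df: pd.DataFrame) -> pd.DataFrame:
        df = df.copy()
        hu = unwrap_degrees(df["heading_deg"].to_numpy())
        dx = np.diff(df["x_mm"].to_numpy())
        dy = np.diff(df["y_mm"].to_numpy())
        speed = np.hypot(dx, dy) * fs
        angv = np.diff(hu) * fs
        speed = np.concatenate([[speed[0] if speed.size else 0.0], speed])
        angv = np.concatenate([[angv[0] if angv.size else 0.0], angv])
        valid = df["valid"].to_numpy(dtype=bool) if "valid" in df else np.ones(len(df), bool)
        speed[~valid] = np.nan
        angv[~valid] = np.nan
        df["heading_unwrapped_deg"] = hu
        df["speed"] = smooth_series(speed, smoothing_window)
        df["ang_vel"] = smooth_series(angv, smoothing_window)
        return df

    if per_trial and "trial_id" in traj:
        parts = [_one(g) for _, g in traj.groupby("trial_id", sort=True)]
        return pd.concat(parts, ignore_index=True)
    return _one(traj)


def flag_jumps(
    traj: pd.DataFrame,
    speed_thresh: float = JUMP_SPEED_MM_S,
    angvel_thresh: float = JUMP_ANGVEL_DEG_S,
) -> np.ndarray:
    """Per-frame jump mask: speed > 100 mm/s OR |ang vel| > 1000 deg/s."""
    speed = traj["speed"].to_numpy()
    angv = traj["ang_vel"].to_numpy()
    with np.errstate(invalid="ignore"):
        return (speed > speed_thresh) | (np.abs(angv) > angvel_thresh)


def segment_trials(
    traj: pd.DataFrame,
    trial_log: pd.DataFrame,
    fs: float,
    arena_radius_mm: float = 27.5,
    wall_margin_mm: float = WALL_MARGIN_MM,
    inactivity_speed_mm_s: float = DEFAULT_INACTIVITY_SPEED_MM_S,
) -> list[Trial]:
    """Cut the trajectory at logged trial boundaries and apply exclusions.

    A trial is excluded (with the first applicable reason) if it contains a
    jump-flagged frame, any frame within ``wall_margin_mm`` of the wall, or
    its mean speed stays below ``inactivity_speed_mm_s`` for the whole
    trial.  Raises on overlapping trial spans.
    """
    jumps = flag_jumps(traj)
    r = np.hypot(traj["x_mm"].to_numpy(), traj["y_mm"].to_numpy())
    speed = traj["speed"].to_numpy()
    spans = []
    trials = []
    for _, row in trial_log.sort_values("t_start").iterrows():
        a = int(round(row["t_start"] * fs))
        m = int(round(row["t_motion_onset"] * fs))
        b = int(round(row["t_end"] * fs))
        if not (0 <= a < b <= len(traj)):
            raise ValueError(f"trial {row['trial_id']} outside trajectory span")
        if spans and a < spans[-1][1]:
            raise ValueError("overlapping trial spans in trial log")
        spans.append((a, b))
        reason = "none"
        if jumps[a:b].any():
            reason = "jump"
        elif (r[a:b] > arena_radius_mm - wall_margin_mm).any():
            reason = "wall"
        elif np.nanmean(speed[a:b]) < inactivity_speed_mm_s:
            reason = "inactive"
        trials.append(
            Trial(
                trial_id=int(row["trial_id"]),
                kind=str(row.get("kind", "")),
                rotation_dir=str(row.get("rotation_dir", "none")),
                start=a,
                motion_onset=m,
                end=b,
                excluded=reason != "none",
                exclusion_reason=reason,
            )
        )
    return trials


def align_to_stimulus(traj: pd.DataFrame, trials: list[Trial]) -> tuple[pd.DataFrame, list[Trial]]:
    """Mirror CCW trials so positive ang vel means "with the stimulus".

    Adds an ``ang_vel_rel`` column: identical to ``ang_vel`` for CW trials,
    negated for CCW trials.  Mirroring twice is the identity (the flag
    records the applied sign, not a toggle).
    """
    traj = traj.copy()
    rel = traj["ang_vel"].to_numpy().copy()
    out = []
    for t in trials:
        t2 = Trial(**{**t.__dict__})
        if t.rotation_dir == "CCW":
            rel[t.start : t.end] = -rel[t.start : t.end]
            t2.mirrored = True
        out.append(t2)
    traj["ang_vel_rel"] = rel
    return traj, out


def trial_table(trials: list[Trial]) -> pd.DataFrame:
    """Flat trial table (CSV-ready)."""
    return pd.DataFrame(
        [
            {
                "trial_id": t.trial_id,
                "condition": t.kind,
                "rotation_dir": t.rotation_dir,
                "included": not t.excluded,
                "reason": t.exclusion_reason,
                "mirrored": t.mirrored,
            }
            for t in trials
        ]
    )
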