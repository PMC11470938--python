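"""Forward-walking bouts and windowed path straightness.

A walking bout is an inter-saccade interval longer than 333 ms (20 frames
at 60 Hz) whose mean speed exceeds 5 mm/s.  Straightness slides a 333 ms
window along the bout: each window contributes the chord between its
endpoints (the shortest possible path) and the perpendicular deviation of
the trajectory midpoint from that chord.  The bout statistic is the ratio
of summed chords to summed deviations — large for straight walking,
small for tortuous paths.  On a circle of radius R the window of arc
length L gives chord 2R·sin(L/2R) and sagitta R(1−cos(L/2R)) exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinematics import Trial
from .saccades import SaccadeEvent

BOUT_MIN_DURATION_S = 20 / 60.0  # 333 ms
BOUT_MIN_SPEED_MM_S = 5.0
STRAIGHTNESS_WINDOW_S = 20 / 60.0
EPS_PER_WINDOW_MM = 0.01


@dataclass
class WalkBout:
    start: int  # frame (inclusive)
    end: int  # frame (exclusive)
    mean_speed: float
    trial_id: int = -1


@dataclass
class StraightnessResult:
    per_point: np.ndarray  # chord/deviation per interior point (eps-floored)
    chords: np.ndarray  # mm per window
    deviations: np.ndarray  # mm per window
    bout_value: float  # Σchord / Σdeviation, eps-floored when degenerate
    is_straight: bool  # True when the eps floor engaged (deviations ~ 0)


def segment_bouts(
    traj: pd.DataFrame,
    events: list[SaccadeEvent],
    fs: float,
    trials: list[Trial] | None = None,
    min_duration_s: float = BOUT_MIN_DURATION_S,
    min_speed_mm_s: float = BOUT_MIN_SPEED_MM_S,
) -> list[WalkBout]:
    """Inter-saccade intervals filtered by duration and mean speed.

    Interval edges are saccade offsets/onsets; trial boundaries (when
    given) also delimit bouts so a bout never spans two trials.
    """
    n = len(traj)
    speed = traj["speed"].to_numpy()
    cuts = [0, n]
    for e in events:
        cuts += [e.onset, e.offset + 1]
    spans = [(a, b, -1) for a, b in zip(sorted(cuts)[:-1], sorted(cuts)[1:])]
    if trials is not None:
        clipped = []
        for t in trials:
            for a, b, _ in spans:
                lo, hi = max(a, t.start), min(b, t.end)
                if hi > lo:
                    clipped.append((lo, hi, t.trial_id))
        spans = clipped
    in_event = np.zeros(n, dtype=bool)
    for e in events:
        in_event[e.onset : e.offset + 1] = True
    bouts = []
    for a, b, tid in spans:
        if in_event[a:b].any():
            continue
        if (b - a) / fs <= min_duration_s:
            continue
        ms = float(np.nanmean(speed[a:b]))
        if ms <= min_speed_mm_s:
            continue
        bouts.append(WalkBout(start=a, end=b, mean_speed=ms, trial_id=tid))
    return bouts


def straightness(
    x_mm: np.ndarray,
    y_mm: np.ndarray,
    fs: float,
    window_s: float = STRAIGHTNESS_WINDOW_S,
    eps_per_window_mm: float = EPS_PER_WINDOW_MM,
) -> StraightnessResult:
    """Windowed chord/deviation straightness of one bout's path.

    For each interior sample a window of ``window_s`` is centred on it;
    the chord connects the window's endpoint samples and the deviation is
    the perpendicular distance of the centre sample from that chord.  The
    bout value is Σchord / Σdeviation.  Perfectly straight paths have zero
    deviation and an unbounded ratio; the denominator is floored at
    ``eps_per_window_mm`` per window and the result flagged
    ``is_straight`` (the documented straight-path sentinel).

    Raises ``ValueError`` when the bout is shorter than the window.
    """
    x = np.asarray(x_mm, dtype=float)
    y = np.asarray(y_mm, dtype=float)
    half = int(round(window_s * fs / 2))
    if half < 1 or x.size < 2 * half + 1:
        raise ValueError("bout shorter than the straightness window")
    idx = np.arange(half, x.size - half)
    ax, ay = x[idx - half], y[idx - half]
    bx, by = x[idx + half], y[idx + half]
    mx, my = x[idx], y[idx]
    cx, cy = bx - ax, by - ay
    chord = np.hypot(cx, cy)
    # perpendicular distance of the midpoint from the chord line
    cross = cx * (my - ay) - cy * (mx - ax)
    with np.errstate(invalid="ignore", divide="ignore"):
        dev = np.where(chord > 0, np.abs(cross) / np.where(chord > 0, chord, 1.0), np.hypot(mx - ax, my - ay))
    eps_total = eps_per_window_mm * idx.size
    sum_dev = float(dev.sum())
    degenerate = sum_dev < eps_total
    value = float(chord.sum()) / (eps_total if degenerate else sum_dev)
    per_point = chord / np.maximum(dev, eps_per_window_mm)
    return StraightnessResult(
        per_point=per_point,
        chords=chord,
        deviations=dev,
        bout_value=value,
        is_straight=degenerate,
    )


def bout_table(
    traj: pd.DataFrame,
    bouts: list[WalkBout],
    fs: float,
    window_s: float = STRAIGHTNESS_WINDOW_S,
) -> pd.DataFrame:
    """Per-bout straightness table; bouts shorter than the window get NaN."""
    x = traj["x_mm"].to_numpy()
    y = traj["y_mm"].to_numpy()
    rows = []
    for b in bouts:
        try:
            s = straightness(x[b.start : b.end], y[b.start : b.end], fs, window_s)
            val, flat = s.bout_value, s.is_straight
        except ValueError:
            val, flat = np.nan, False
        rows.append(
            {
                "trial_id": b.trial_id,
                "start_s": b.start / fs,
                "end_s": b.end / fs,
                "mean_speed": b.mean_speed,
                "straightness": val,
                "is_straight": flat,
            }
        )
    return pd.DataFrame(rows)
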