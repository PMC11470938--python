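"""Silhouette tracking: ellipse pose fit and wing-based heading resolution.

Backlit flies appear as dark silhouettes on a bright background.  The body
is the darkest blob; an ellipse fit to it gives position and body-axis
orientation (mod 180°).  The translucent wings form an intermediate-
intensity blob trailing the body, so a two-threshold Otsu segmentation of
the fly's neighbourhood separates background / wings / body, and the
direction from the wing centre of mass to the body centre of mass picks
which of the two axis directions is the head.

Conventions: image pixels are 0-based, rows run downward; angles are
reported in the arena sense (degrees CCW from +x with y up), so row
offsets enter with a negated sign.  Conversion to millimetres (12 px/mm)
is left to export.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.filters import threshold_multiotsu
from skimage.measure import label, regionprops

PX_PER_MM = 12.0
MIN_COMPONENT_PX = 20


@dataclass
class Pose:
    centroid_x: float  # px, column
    centroid_y: float  # px, row
    body_axis_angle_deg: float  # mod 180, y-up CCW from +x
    heading_deg: float = float("nan")  # mod 360 once resolved
    frame_index: int = -1
    failed: bool = False
    degenerate_orientation: bool = False
    heading_unresolved: bool = True
    failure_reason: str = ""


def fit_pose(
    frame: np.ndarray,
    intensity_threshold: float,
    frame_index: int = -1,
    min_component_px: int = MIN_COMPONENT_PX,
) -> Pose:
    """Ellipse fit of the largest dark component.

    Pixels below ``intensity_threshold`` are candidate body pixels.  The
    fit fails (``failed=True``) when no component of at least
    ``min_component_px`` pixels exists or the largest one touches the
    frame border; a near-circular blob yields ``degenerate_orientation``.
    """
    mask = np.asarray(frame) < intensity_threshold
    lab = label(mask)
    props = [p for p in regionprops(lab) if p.area >= min_component_px]
    if not props:
        return Pose(np.nan, np.nan, np.nan, frame_index=frame_index, failed=True,
                    failure_reason="no component")
    p = max(props, key=lambda q: q.area)
    r0, c0, r1, c1 = p.bbox
    h, w = np.asarray(frame).shape
    if r0 == 0 or c0 == 0 or r1 == h or c1 == w:
        return Pose(np.nan, np.nan, np.nan, frame_index=frame_index, failed=True,
                    failure_reason="component touches border")
    cy, cx = p.centroid
    if p.axis_major_length <= 0 or (
        p.axis_minor_length / p.axis_major_length > 0.95
    ):
        return Pose(cx, cy, np.nan, frame_index=frame_index,
                    degenerate_orientation=True)
    # regionprops orientation is measured from the row axis; empirically a
    # y-up heading h renders to orientation h − 90°, so invert with h = o + 90°.
    angle = (math.degrees(p.orientation) + 90.0) % 180.0
    return Pose(cx, cy, angle, frame_index=frame_index)


def resolve_heading(
    frame: np.ndarray,
    pose: Pose,
    crop_margin_px: int = 48,
    flip: bool = False,
) -> Pose:
    """Disambiguate the 180° heading using the wing blob.

    A two-threshold Otsu on the fly's neighbourhood yields three classes:
    body (darkest), wings (intermediate), background.  The heading is the
    body-axis direction closer to the wing-COM → body-COM vector (wings
    trail the body; ``flip`` reverses the convention).  Leaves the pose's
    body-axis angle untouched; sets ``heading_unresolved`` when no wing
    pixels are found.
    """
    if pose.failed or not np.isfinite(pose.body_axis_angle_deg):
        return pose
    img = np.asarray(frame)
    h, w = img.shape
    r0 = max(0, int(pose.centroid_y) - crop_margin_px)
    r1 = min(h, int(pose.centroid_y) + crop_margin_px + 1)
    c0 = max(0, int(pose.centroid_x) - crop_margin_px)
    c1 = min(w, int(pose.centroid_x) + crop_margin_px + 1)
    crop = img[r0:r1, c0:c1]
    try:
        t_body, t_wing = threshold_multiotsu(crop, classes=3)
    except ValueError:
        return pose
    # inclusive comparisons: with few discrete grey levels the Otsu
    # thresholds coincide with class values
    body = crop <= t_body
    wings = (crop > t_body) & (crop <= t_wing)
    if not wings.any() or not body.any():
        return pose
    br, bc = np.argwhere(body).mean(axis=0)
    wr, wc = np.argwhere(wings).mean(axis=0)
    # wing COM -> body COM, expressed y-up
    vx, vy = bc - wc, -(br - wr)
    if flip:
        vx, vy = -vx, -vy
    if vx == 0 and vy == 0:
        return pose
    axis = math.radians(pose.body_axis_angle_deg)
    ux, uy = math.cos(axis), math.sin(axis)
    heading = pose.body_axis_angle_deg if (ux * vx + uy * vy) >= 0 else pose.body_axis_angle_deg + 180.0
    pose.heading_deg = heading % 360.0
    pose.heading_unresolved = False
    return pose


def track_stack(
    frames: list[np.ndarray] | np.ndarray,
    intensity_threshold: float,
    fs: float = 60.0,
) -> pd.DataFrame:
    """Track a frame stack; one row per frame with QC flags.

    Output columns mirror the synthetic trajectory schema (pixel units):
    frame, t_s, x_px, y_px, body_angle_deg, heading_deg, valid, qc.
    """
    rows = []
    for i, fr in enumerate(frames):
        pose = resolve_heading(fr, fit_pose(fr, intensity_threshold, frame_index=i))
        qc = "ok"
        if pose.failed:
            qc = pose.failure_reason or "failed"
        elif pose.degenerate_orientation:
            qc = "degenerate_orientation"
        elif pose.heading_unresolved:
            qc = "heading_unresolved"
        rows.append(
            {
                "frame": i,
                "t_s": i / fs,
                "x_px": pose.centroid_x,
                "y_px": pose.centroid_y,
                "body_angle_deg": pose.body_axis_angle_deg,
                "heading_deg": pose.heading_deg,
                "valid": not pose.failed,
                "qc": qc,
            }
        )
    return pd.DataFrame(rows)


def px_to_mm(df: pd.DataFrame, image_size: int, px_per_mm: float = PX_PER_MM) -> pd.DataFrame:
    """Convert pixel trajectory to arena millimetres (centre origin, y up)."""
    out = df.copy()
    c = (image_size - 1) / 2
    out["x_mm"] = (df["x_px"] - c) / px_per_mm
    out["y_mm"] = -(df["y_px"] - c) / px_per_mm
    return out
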