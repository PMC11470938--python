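"""Synthetic inputs with known ground truth for every analysis stage.

Four generators emulate the experiment's raw data:

* :func:`simulate_walker` — closed-loop walking in a 55 mm circular arena at
  60 Hz: smooth optomotor turning plus Poisson-timed raised-cosine saccade
  pulses, with the stimulus anchor following the body angle at a 3-frame
  delay and specular wall reflection.
* :func:`render_silhouette` — backlit camera frames: dark body ellipse and
  a dimmer trailing wing blob on a bright background, the geometry the
  tracking stage must invert.
* :func:`simulate_scan_responses` — membrane-potential responses of a
  linear cell with a planted receptive vector field to a scanning-bar
  protocol, for the receptive-field reconstruction stage.
* :func:`simulate_baseline` — baseline voltage traces with controlled
  sinusoidal components and drift, for the power-spectrum stage.

Every generator is a pure function of its parameters and seed.

The walker's *linearity mode* sets the study conditions for the
prediction-error analysis.  In ``linear`` mode the full-field drive is by
construction the sum of the two unilateral drives (smooth gains and saccade
rates both add), giving a null in which the linear prediction is exact in
expectation.  In ``nonlinear`` mode unilateral front-to-back motion evokes
anti-saccades (turns against the stimulus) with little smooth turning,
while full-field rotation evokes strong smooth syn turning — the
phenomenology whose departure from linear summation the analysis is built
to expose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .stimulus import (
    ConditionKind,
    RotationDir,
    StimulusCondition,
    closed_loop_angle,
)

ARENA_RADIUS_MM = 27.5  # 55 mm circular arena
FRAME_RATE_HZ = 60.0


class GenerationError(RuntimeError):
    """Raised when requested event density cannot be placed without overlap."""


# --------------------------------------------------------------------------
# closed-loop walker
# --------------------------------------------------------------------------

# Stimulus-relative smooth drive (deg/s at gain 1) and saccade rates
# (events/s during motion) per condition kind.  Linear mode: full-field
# drive and rates are the sums of the unilateral ones, so the linear
# prediction holds by construction.  Nonlinear mode mirrors the wild-type
# phenomenology: FtB -> anti-saccades, full-field -> strong smooth syn
# turning.
_LINEAR_DRIVES = {
    "unilateral_FtB": dict(smooth=12.0, syn_rate=0.20, anti_rate=0.05),
    "unilateral_BtF": dict(smooth=18.0, syn_rate=0.30, anti_rate=0.05),
    "full_field": dict(smooth=30.0, syn_rate=0.50, anti_rate=0.10),
    "static": dict(smooth=0.0, syn_rate=0.0, anti_rate=0.0),
}
_NONLINEAR_DRIVES = {
    "unilateral_FtB": dict(smooth=-2.0, syn_rate=0.0, anti_rate=1.0),
    "unilateral_BtF": dict(smooth=10.0, syn_rate=0.20, anti_rate=0.05),
    "full_field": dict(smooth=35.0, syn_rate=0.60, anti_rate=0.05),
    "static": dict(smooth=0.0, syn_rate=0.0, anti_rate=0.0),
}


@dataclass
class WalkerParams:
    """Parameters of the synthetic closed-loop walker."""

    fs: float = FRAME_RATE_HZ
    arena_radius_mm: float = ARENA_RADIUS_MM
    speed_mean: float = 8.0  # mm/s
    speed_sd: float = 2.0
    smooth_turn_gain: float = 1.0  # (deg/s) per unit stimulus drive
    smooth_turn_noise_sd: float = 25.0  # deg/s after low-pass filtering
    noise_cutoff_hz: float = 2.0
    saccade_peak_range: tuple[float, float] = (300.0, 600.0)  # deg/s
    saccade_duration_range: tuple[float, float] = (0.08, 0.20)  # s
    spontaneous_rate: float = 0.05  # events/s during the static period
    wall_buffer_mm: float = 5.0  # specular reflection radius margin; 0 disables
    linearity_mode: str = "linear"
    seed: int = 0
    drive_overrides: dict | None = None  # per-kind {smooth, syn_rate, anti_rate}

    def __post_init__(self) -> None:
        lo, hi = self.saccade_duration_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("saccade durations must lie in (0, 500] ms")
        if self.arena_radius_mm <= 0:
            raise ValueError("arena_radius_mm must be positive")
        if self.linearity_mode not in ("linear", "nonlinear"):
            raise ValueError("linearity_mode must be 'linear' or 'nonlinear'")

    @property
    def drives(self) -> dict:
        table = _LINEAR_DRIVES if self.linearity_mode == "linear" else _NONLINEAR_DRIVES
        out = {k: dict(v) for k, v in table.items()}
        for k, v in (self.drive_overrides or {}).items():
            out[k].update(v)
        return out


@dataclass
class GroundTruth:
    """Planted decomposition of the walker's turning, per session.

    ``smooth + saccadic`` equals the planted angular velocity exactly at
    every frame.  Wall-reflection heading jumps are not part of the planted
    turning; they are listed separately in ``reflection_frames``.
    """

    events: pd.DataFrame  # trial_id, onset, offset (frames), peak, displacement, klass
    smooth: np.ndarray  # deg/s, stimulus-relative sign not applied (arena frame)
    saccadic: np.ndarray
    reflection_frames: np.ndarray


def _lowpass_noise(rng: np.random.Generator, n: int, fs: float, cutoff: float, sd: float) -> np.ndarray:
    if sd == 0 or n < 20:
        return np.zeros(n)
    b, a = butter(4, cutoff / (fs / 2))
    x = filtfilt(b, a, rng.standard_normal(n))
    s = x.std()
    return x / s * sd if s > 0 else np.zeros(n)


def raised_cosine_pulse(n: int, fs: float, onset_s: float, duration_s: float, peak: float) -> np.ndarray:
    """Angular-velocity pulse ``peak * sin^2(pi t / D)`` on its support.

    The raised cosine concentrates its spectrum near 1/duration, which for
    80–200 ms events falls in or near the detector's 10–20 Hz band.
    """
    t = np.arange(n) / fs
    y = np.zeros(n)
    m = (t >= onset_s) & (t < onset_s + duration_s)
    y[m] = peak * np.sin(np.pi * (t[m] - onset_s) / duration_s) ** 2
    return y


def _place_events(
    rng: np.random.Generator,
    n_events: int,
    t_lo: float,
    t_hi: float,
    dur_range: tuple[float, float],
    min_gap: float = 0.05,
    max_tries: int = 1000,
) -> list[tuple[float, float]]:
    """Rejection-sample non-overlapping (onset, duration) pairs."""
    placed: list[tuple[float, float]] = []
    for _ in range(n_events):
        for attempt in range(max_tries):
            d = rng.uniform(*dur_range)
            t0 = rng.uniform(t_lo, t_hi - d)
            if all(t0 + d + min_gap <= s or s + sd + min_gap <= t0 for s, sd in placed):
                placed.append((t0, d))
                break
        else:
            raise GenerationError(
                "could not place non-overlapping saccades; rate too high for the window"
            )
    return sorted(placed)


def _rotation_sign(condition: StimulusCondition) -> float:
    # Arena-frame sign of "with the stimulus": +1 for CW-labelled trials
    # (mirroring leaves them unchanged), -1 for CCW.
    return {RotationDir.CW: 1.0, RotationDir.CCW: -1.0, RotationDir.NONE: 1.0}[
        condition.rotation_dir
    ]


def simulate_walker(
    params: WalkerParams,
    condition: StimulusCondition,
    n_trials: int,
) -> tuple[pd.DataFrame, GroundTruth, pd.DataFrame]:
    """Simulate ``n_trials`` closed-loop trials of one stimulus condition.

    Returns ``(trajectory, ground_truth, trial_log)``.  The trajectory has
    one row per frame with columns ``frame, t_s, x_mm, y_mm,
    body_angle_deg, heading_deg, valid`` (body angle and heading coincide:
    the walker moves along its body axis).  Trials are concatenated; each
    starts at a uniformly drawn position within 10 mm of the centre with a
    random heading.
    """
    rng = np.random.default_rng(params.seed)
    fs = params.fs
    n_static = round(condition.static_duration_s * fs)
    n_motion = round(condition.motion_duration_s * fs)
    n_frames = n_static + n_motion
    drv = params.drives[condition.kind.value]
    sgn = _rotation_sign(condition)

    traj_rows = []
    ev_rows = []
    smooth_all = np.empty(n_trials * n_frames)
    sacc_all = np.empty(n_trials * n_frames)
    refl_frames = []
    r_wall = params.arena_radius_mm - params.wall_buffer_mm

    for trial in range(n_trials):
        base = trial * n_frames
        # --- planted angular velocity (arena frame) -----------------------
        smooth = _lowpass_noise(rng, n_frames, fs, params.noise_cutoff_hz, params.smooth_turn_noise_sd)
        smooth[n_static:] += sgn * params.smooth_turn_gain * drv["smooth"]
        sacc = np.zeros(n_frames)

        t_mot_lo, t_mot_hi = n_static / fs, n_frames / fs
        events: list[tuple[float, float, float, str]] = []
        for klass, rate in (("syn", drv["syn_rate"]), ("anti", drv["anti_rate"])):
            k = rng.poisson(rate * condition.motion_duration_s)
            if k:
                rel_sign = 1.0 if klass == "syn" else -1.0
                for t0, d in _place_events(rng, k, t_mot_lo, t_mot_hi, params.saccade_duration_range):
                    events.append((t0, d, rel_sign * sgn, klass))
        k_sp = rng.poisson(params.spontaneous_rate * condition.static_duration_s)
        if k_sp:
            for t0, d in _place_events(rng, k_sp, 0.0, t_mot_lo, params.saccade_duration_range):
                events.append((t0, d, float(rng.choice([-1.0, 1.0])), "spont"))
        # re-check overlaps across classes: drop later-placed conflicts
        events.sort()
        kept: list[tuple[float, float, float, str]] = []
        for e in events:
            if all(e[0] >= p[0] + p[1] + 0.05 or e[0] + e[1] + 0.05 <= p[0] for p in kept):
                kept.append(e)
        for t0, d, s, klass in kept:
            pk = rng.uniform(*params.saccade_peak_range)
            pulse = raised_cosine_pulse(n_frames, fs, t0, d, pk) * s
            sacc += pulse
            ev_rows.append(
                {
                    "trial_id": trial,
                    "onset": base + int(round(t0 * fs)),
                    "offset": base + int(round((t0 + d) * fs)),
                    "peak_deg_s": pk * s,
                    "displacement_deg": np.trapezoid(pulse, dx=1 / fs),
                    "klass": klass,
                    "pre_motion": t0 < t_mot_lo,
                }
            )

        omega = smooth + sacc
        smooth_all[base : base + n_frames] = smooth
        sacc_all[base : base + n_frames] = sacc

        # --- integrate pose with specular wall reflection -----------------
        speed = np.clip(
            params.speed_mean + _lowpass_noise(rng, n_frames, fs, 1.0, params.speed_sd),
            0.0,
            None,
        )
        r0 = math.sqrt(rng.uniform(0, 100.0))
        th0 = rng.uniform(0, 2 * math.pi)
        x, y = r0 * math.cos(th0), r0 * math.sin(th0)
        h = rng.uniform(0, 360.0)
        dt = 1 / fs
        xs = np.empty(n_frames)
        ys = np.empty(n_frames)
        hs = np.empty(n_frames)
        for i in range(n_frames):
            h = h + omega[i] * dt
            hr = math.radians(h)
            x += speed[i] * dt * math.cos(hr)
            y += speed[i] * dt * math.sin(hr)
            if params.wall_buffer_mm > 0:
                r = math.hypot(x, y)
                if r > r_wall:
                    # reflect velocity direction about the wall tangent
                    nx, ny = x / r, y / r
                    vx, vy = math.cos(hr), math.sin(hr)
                    dot = vx * nx + vy * ny
                    vx, vy = vx - 2 * dot * nx, vy - 2 * dot * ny
                    h = math.degrees(math.atan2(vy, vx))
                    x, y = nx * r_wall, ny * r_wall
                    refl_frames.append(base + i)
            xs[i], ys[i], hs[i] = x, y, h % 360.0
        tr = pd.DataFrame(
            {
                "frame": base + np.arange(n_frames),
                "t_s": (base + np.arange(n_frames)) / fs,
                "x_mm": xs,
                "y_mm": ys,
                "body_angle_deg": hs % 180.0,
                "heading_deg": hs,
                "valid": True,
            }
        )
        tr["trial_id"] = trial
        traj_rows.append(tr)

    traj = pd.concat(traj_rows, ignore_index=True)
    traj["stimulus_anchor_deg"] = closed_loop_angle(traj["heading_deg"].to_numpy())
    events_df = pd.DataFrame(
        ev_rows,
        columns=[
            "trial_id", "onset", "offset", "peak_deg_s",
            "displacement_deg", "klass", "pre_motion",
        ],
    )
    gt = GroundTruth(
        events=events_df,
        smooth=smooth_all,
        saccadic=sacc_all,
        reflection_frames=np.array(refl_frames, dtype=int),
    )
    log = pd.DataFrame(
        {
            "trial_id": np.arange(n_trials),
            "kind": condition.kind.value,
            "rotation_dir": condition.rotation_dir.value,
            "t_start": np.arange(n_trials) * n_frames / fs,
            "t_motion_onset": (np.arange(n_trials) * n_frames + n_static) / fs,
            "t_end": (np.arange(n_trials) + 1) * n_frames / fs,
        }
    )
    return traj, gt, log


# --------------------------------------------------------------------------
# silhouette frames
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ImageParams:
    """Geometry and intensity levels of a rendered silhouette frame.

    Levels are chosen well apart so a two-threshold Otsu separates
    background / wings / body.
    """

    size: int = 256
    background: int = 200
    wing_level: int = 120
    body_level: int = 30
    body_major_px: float = 40.0  # full major-axis length
    body_minor_px: float = 12.0
    wing_major_px: float = 26.0
    wing_minor_px: float = 14.0
    wing_offset_frac: float = 0.55  # wing-blob centre, in body major lengths behind


def render_silhouette(
    centroid_xy: tuple[float, float],
    heading_deg: float,
    image_params: ImageParams | None = None,
) -> np.ndarray:
    """Render a fly silhouette: body ellipse plus trailing wing blob.

    ``heading_deg`` is measured counter-clockwise from +x with y up;
    image rows run downwards, so the rendered row offset negates the sine.
    The wing blob centre sits behind the body centre along −heading.
    Raises ``ValueError`` if the body ellipse does not fit in the frame.
    """
    from skimage.draw import ellipse as draw_ellipse

    p = image_params or ImageParams()
    cx, cy = centroid_xy
    h = math.radians(heading_deg)
    ux, uy = math.cos(h), -math.sin(h)  # image coords, y-down

    a = p.body_major_px / 2
    if not (a <= cx <= p.size - 1 - a and a <= cy <= p.size - 1 - a):
        raise ValueError("body ellipse partially outside frame")

    frame = np.full((p.size, p.size), p.background, dtype=np.uint8)
    wx = cx - p.wing_offset_frac * p.body_major_px * ux
    wy = cy - p.wing_offset_frac * p.body_major_px * uy
    # skimage.draw.ellipse rotation is CCW about the row axis; pass the
    # image-frame polar angle of the major axis.
    rot = math.atan2(uy, ux)
    rr, cc = draw_ellipse(
        wy, wx, p.wing_minor_px / 2, p.wing_major_px / 2,
        shape=frame.shape, rotation=-rot,
    )
    frame[rr, cc] = p.wing_level
    rr, cc = draw_ellipse(
        cy, cx, p.body_minor_px / 2, p.body_major_px / 2,
        shape=frame.shape, rotation=-rot,
    )
    frame[rr, cc] = p.body_level
    return frame


# --------------------------------------------------------------------------
# planted receptive fields and scanning-bar responses
# --------------------------------------------------------------------------

@dataclass
class PlantedRF:
    """Ground-truth local-motion-sensitivity vector field on an az×el grid."""

    azimuths_deg: np.ndarray  # (n_az,)
    elevations_deg: np.ndarray  # (n_el,)
    vectors: np.ndarray  # (n_az, n_el, 2), mV per unit bar speed
    noise_sd: float = 0.0  # mV, per stimulus frame
    midline_azimuth_deg: float = 0.0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("planted vectors must be finite")
        if np.ptp(self.azimuths_deg) > 140 or np.ptp(self.elevations_deg) > 80:
            raise ValueError("grid exceeds the 140°×80° screen span")


def make_planted_rf(
    az_range: tuple[float, float] = (-70.0, 70.0),
    el_range: tuple[float, float] = (-20.0, 20.0),
    step_deg: float = 5.0,
    peak_mv: float = 6.0,
    centre: tuple[float, float] = (30.0, 0.0),
    sigma_deg: float = 35.0,
    contra_fraction: float | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> PlantedRF:
    """Smooth horizontal-motion-sensitive field with a Gaussian envelope.

    Directions point along +azimuth with a mild elevation-dependent curl,
    magnitudes follow a Gaussian centred ipsilaterally.  When
    ``contra_fraction`` is given, the contralateral half (azimuth < 0) is
    rescaled so that it carries exactly that fraction of the summed vector
    magnitude — bookkeeping used to test the contralateral-share metric.
    """
    az = np.arange(az_range[0], az_range[1] + step_deg / 2, step_deg)
    el = np.arange(el_range[0], el_range[1] + step_deg / 2, step_deg)
    A, E = np.meshgrid(az, el, indexing="ij")
    mag = peak_mv * np.exp(-((A - centre[0]) ** 2 + (E - centre[1]) ** 2) / (2 * sigma_deg**2))
    tilt = np.radians(0.3 * E)  # slight vertical curl away from the equator
    vec = np.stack([mag * np.cos(tilt), mag * np.sin(tilt)], axis=-1)
    if contra_fraction is not None:
        m = np.linalg.norm(vec, axis=-1)
        contra = A < 0.0
        s_c, s_i = m[contra].sum(), m[~contra].sum()
        if s_c == 0:
            raise ValueError("no contralateral mass to rescale")
        # scale contra side so s_c' / (s_c' + s_i) == contra_fraction
        vec[contra] *= (contra_fraction / (1 - contra_fraction)) * (s_i / s_c)
    return PlantedRF(az, el, vec, noise_sd=noise_sd)


def simulate_scan_responses(
    rf: PlantedRF,
    protocol,
    seed: int = 0,
    fs: float = 10_000.0,
    resting_potential_mv: float = -50.0,
    drift_amplitude_mv: float = 0.0,
    drift_period_s: float = 50.0,
):
    """Voltage recording of a linear cell driven by the scanning bar.

    For every stimulus frame the membrane response is the dot product of
    the planted vector at the bar position with the unit motion direction,
    plus one Gaussian noise draw per frame (held over the frame's samples,
    so frame binning cannot average it away).  Returns a
    :class:`flysteer.ephys.VoltageRecording`.
    """
    from .ephys import VoltageRecording

    rng = np.random.default_rng(seed)
    frames = protocol.frames
    az_idx = np.searchsorted(rf.azimuths_deg, frames["azimuth_deg"].to_numpy())
    el_idx = np.searchsorted(rf.elevations_deg, frames["elevation_deg"].to_numpy())
    d = frames[["dx", "dy"]].to_numpy()
    resp = np.einsum("ij,ij->i", rf.vectors[az_idx, el_idx], d)
    if rf.noise_sd > 0:
        resp = resp + rng.normal(0.0, rf.noise_sd, size=resp.shape)

    spf = int(round(protocol.frame_duration_s * fs))
    v = np.repeat(resp, spf).astype(float)
    t = np.arange(v.size) / fs
    if drift_amplitude_mv:
        v += drift_amplitude_mv * np.sin(2 * np.pi * t / drift_period_s)
    v += resting_potential_mv
    # frame onsets on the realised sample grid (spf samples per frame), so
    # downstream binning recovers each frame's samples exactly
    frame_times = np.arange(len(frames)) * spf / fs
    return VoltageRecording(v=v, fs=fs, frame_times=frame_times, junction_corrected=True)


# --------------------------------------------------------------------------
# baseline traces
# --------------------------------------------------------------------------

def simulate_baseline(
    duration_s: float,
    fs: float,
    components: list[tuple[float, float]] = (),
    drift_sd: float = 0.0,
    seed: int = 0,
    white_sd: float = 0.0,
) -> np.ndarray:
    """Sum of sinusoids plus random-walk drift and white noise, seeded.

    ``components`` is a list of ``(frequency_hz, amplitude_mv)``.  Raises
    on components at or above the Nyquist frequency.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    v = np.zeros(n)
    for f, amp in components:
        if f >= fs / 2:
            raise ValueError(f"component at {f} Hz aliases at fs={fs} Hz")
        v += amp * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    if drift_sd > 0:
        walk = np.cumsum(rng.standard_normal(n))
        v += drift_sd * walk / max(walk.std(), 1e-12)
    if white_sd > 0:
        v += rng.normal(0, white_sd, n)
    return v


# --------------------------------------------------------------------------
# saccade-detector benchmark
# --------------------------------------------------------------------------

def brickwall_lowpass(x: np.ndarray, fs: float, cutoff_hz: float) -> np.ndarray:
    """Ideal (FFT) low-pass; used to band-limit benchmark backgrounds."""
    X = np.fft.rfft(x)
    f = np.fft.rfftfreq(len(x), 1 / fs)
    X[f >= cutoff_hz] = 0
    return np.fft.irfft(X, len(x))


def make_detector_benchmark(
    n_trials: int,
    seed: int = 0,
    fs: float = FRAME_RATE_HZ,
    duration_s: float = 10.0,
    peak_range: tuple[float, float] = (300.0, 600.0),
    width_range: tuple[float, float] = (0.08, 0.20),
    min_separation_s: float = 0.30,
    bg_max_range: tuple[float, float] = (60.0, 100.0),
    bg_cutoff_hz: float = 5.0,
    with_pulses: bool = True,
) -> list[tuple[np.ndarray, pd.DataFrame]]:
    """Planted-saccade benchmark trials for detector validation.

    Each trial is a smooth background (band-limited below ``bg_cutoff_hz``,
    peak magnitude ≤ 100 deg/s) with raised-cosine pulses of random sign,
    peak 300–600 deg/s and width 80–200 ms, separated by at least 300 ms
    edge to edge.  Returns ``[(angular_velocity, events), ...]`` where
    events has columns onset_s, offset_s, peak_deg_s.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    out = []
    for _ in range(n_trials):
        bg = brickwall_lowpass(rng.standard_normal(n), fs, bg_cutoff_hz)
        bg = bg / np.abs(bg).max() * rng.uniform(*bg_max_range)
        w = bg.copy()
        rows = []
        if with_pulses:
            t = 0.3
            while True:
                d = rng.uniform(*width_range)
                if t + d > duration_s - 0.5:
                    break
                pk = rng.uniform(*peak_range) * rng.choice([-1.0, 1.0])
                w += raised_cosine_pulse(n, fs, t, d, abs(pk)) * np.sign(pk)
                rows.append({"onset_s": t, "offset_s": t + d, "peak_deg_s": pk})
                t += d + min_separation_s + rng.exponential(0.5)
        out.append(
            (w, pd.DataFrame(rows, columns=["onset_s", "offset_s", "peak_deg_s"]))
        )
    return out
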