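"""Patch-clamp analysis: baselines, flashes, tuning, spectra and receptive fields.

Whole-cell recordings of lobula plate tangential cells (10 kHz digitisation)
are analysed in five steps:

* a 60 s centred rolling mean removes slow baseline drift;
* responses are discretised into 16.6 ms bins (one stimulus frame);
* the scanning-bar protocol (a 10° × 2° rectangle moving in the four
  cardinal directions across the visual field) is inverted into a
  receptive-field vector field: at each grid point the per-direction mean
  responses weight the corresponding unit direction vectors and are
  vector-summed — for a linear cell with local sensitivity F this sum
  equals 2F exactly;
* summary metrics: area above 30 %/60 % of the maximal vector length
  (solid-angle weighted) and the contralateral/ipsilateral sensitivity
  split;
* baseline power spectra, normalised to unit total energy, summarised as
  the power fractions in 0–10 Hz and 11–50 Hz (half-open band edges
  [0, 10] and (10, 50] so the 10 Hz bin is counted once).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import periodogram

FRAME_BIN_S = 1 / 60.0  # 16.6 ms stimulus frame
BASELINE_WINDOW_S = 60.0
LOW_BAND_HZ = (0.0, 10.0)
MID_BAND_HZ = (10.0, 50.0)  # half-open: (10, 50]
JUNCTION_POTENTIAL_MV = 12.0

CARDINAL_DIRECTIONS = {
    "+az": (1.0, 0.0),
    "-az": (-1.0, 0.0),
    "+el": (0.0, 1.0),
    "-el": (0.0, -1.0),
}


@dataclass
class VoltageRecording:
    v: np.ndarray  # mV
    fs: float  # Hz
    frame_times: np.ndarray | None = None  # stimulus frame onsets, s
    junction_corrected: bool = False

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        if not np.all(np.isfinite(self.v)):
            raise ValueError("voltage trace must be finite")


@dataclass
class ScanProtocol:
    """Bar positions and motion directions, one row per stimulus frame."""

    azimuths_deg: np.ndarray
    elevations_deg: np.ndarray
    frames: pd.DataFrame  # azimuth_deg, elevation_deg, direction, dx, dy, repetition
    frame_duration_s: float = FRAME_BIN_S
    n_repetitions: int = 1


def make_scan_protocol(
    azimuths_deg: np.ndarray,
    elevations_deg: np.ndarray,
    n_repetitions: int = 1,
    frame_duration_s: float = FRAME_BIN_S,
) -> ScanProtocol:
    """Enumerate the four cardinal sweeps over the grid, repeated."""
    rows = []
    for rep in range(n_repetitions):
        for name, (dx, dy) in CARDINAL_DIRECTIONS.items():
            for az in azimuths_deg:
                for el in elevations_deg:
                    rows.append(
                        {
                            "azimuth_deg": az,
                            "elevation_deg": el,
                            "direction": name,
                            "dx": dx,
                            "dy": dy,
                            "repetition": rep,
                        }
                    )
    return ScanProtocol(
        azimuths_deg=np.asarray(azimuths_deg, dtype=float),
        elevations_deg=np.asarray(elevations_deg, dtype=float),
        frames=pd.DataFrame(rows),
        frame_duration_s=frame_duration_s,
        n_repetitions=n_repetitions,
    )


@dataclass
class VectorFieldRF:
    azimuths_deg: np.ndarray  # (n_az,)
    elevations_deg: np.ndarray  # (n_el,)
    vectors: np.ndarray  # (n_az, n_el, 2)
    normalisation: float = 1.0  # max vector length divided out, mV
    midline_azimuth_deg: float = 0.0

    def magnitudes(self) -> np.ndarray:
        return np.linalg.norm(self.vectors, axis=-1)

    def normalised(self) -> "VectorFieldRF":
        m = self.magnitudes().max()
        if m == 0:
            raise ValueError("all-zero field cannot be normalised")
        return VectorFieldRF(
            self.azimuths_deg, self.elevations_deg, self.vectors / m,
            normalisation=m, midline_azimuth_deg=self.midline_azimuth_deg,
        )

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for i, az in enumerate(self.azimuths_deg):
            for j, el in enumerate(self.elevations_deg):
                rows.append({"azimuth_deg": az, "elevation_deg": el,
                             "vx": self.vectors[i, j, 0], "vy": self.vectors[i, j, 1]})
        return pd.DataFrame(rows)


def rolling_baseline_subtract(
    v: np.ndarray, fs: float, window_s: float = BASELINE_WINDOW_S
) -> tuple[np.ndarray, bool]:
    """Subtract a centred rolling-mean baseline.

    Records shorter than the window fall back to global-mean subtraction;
    the returned flag is True when that fallback was used.
    """
    v = np.asarray(v, dtype=float)
    w = int(round(window_s * fs))
    if v.size < w:
        return v - v.mean(), True
    base = pd.Series(v).rolling(w, center=True, min_periods=1).mean().to_numpy()
    return v - base, False


def bin_responses(
    v: np.ndarray,
    fs: float,
    frame_times: np.ndarray,
    bin_s: float = FRAME_BIN_S,
) -> np.ndarray:
    """Mean voltage within each stimulus frame's bin; empty bins give NaN."""
    v = np.asarray(v, dtype=float)
    ft = np.asarray(frame_times, dtype=float)
    if np.any(np.diff(ft) < 0):
        raise ValueError("frame times must be non-decreasing")
    starts = np.round(ft * fs).astype(int)
    ends = np.round((ft + bin_s) * fs).astype(int)
    out = np.full(ft.size, np.nan)
    for i, (a, b) in enumerate(zip(starts, ends)):
        a, b = max(a, 0), min(b, v.size)
        if b > a:
            out[i] = v[a:b].mean()
    return out


def reconstruct_rf(
    binned: np.ndarray,
    protocol: ScanProtocol,
    latency_shift_s: float = 0.0,
    midline_azimuth_deg: float = 0.0,
) -> VectorFieldRF:
    """Receptive-field vector field from binned scanning-bar responses.

    Responses are optionally shifted earlier by a fixed latency before
    being attributed to bar position; at each grid point the mean response
    per cardinal direction weights that unit vector and the four are
    summed (averaging across repetitions).  Raises when a direction is
    missing from the protocol.
    """
    frames = protocol.frames
    missing = set(CARDINAL_DIRECTIONS) - set(frames["direction"].unique())
    if missing:
        raise ValueError(f"protocol missing directions: {sorted(missing)}")
    binned = np.asarray(binned, dtype=float)
    if latency_shift_s:
        shift = int(round(latency_shift_s / protocol.frame_duration_s))
        binned = np.roll(binned, -shift)
    df = frames.copy()
    df["response"] = binned
    mean_resp = (
        df.groupby(["azimuth_deg", "elevation_deg", "direction"], sort=False)["response"]
        .mean()
    )
    n_az, n_el = protocol.azimuths_deg.size, protocol.elevations_deg.size
    vec = np.zeros((n_az, n_el, 2))
    az_pos = {a: i for i, a in enumerate(protocol.azimuths_deg)}
    el_pos = {e: j for j, e in enumerate(protocol.elevations_deg)}
    for (az, el, dname), r in mean_resp.items():
        if np.isnan(r):
            continue
        dx, dy = CARDINAL_DIRECTIONS[dname]
        vec[az_pos[az], el_pos[el], 0] += r * dx
        vec[az_pos[az], el_pos[el], 1] += r * dy
    return VectorFieldRF(
        protocol.azimuths_deg.copy(), protocol.elevations_deg.copy(), vec,
        midline_azimuth_deg=midline_azimuth_deg,
    )


@dataclass
class RFMetrics:
    areas_sr: dict  # level -> solid-angle weighted area (steradian-like units)
    contra_share_sum: float  # Σ|F| contra / Σ|F| total
    contra_share_resultant: float  # |Σ F contra| / |Σ F total|
    contra_ipsi_ratio: float  # Σ|F| contra / Σ|F| ipsi


def rf_metrics(
    rf: VectorFieldRF,
    levels: tuple[float, ...] = (0.3, 0.6),
) -> RFMetrics:
    """Receptive-field size and laterality metrics.

    Area at each level counts grid cells with vector length ≥ level × max,
    weighted by cos(elevation) (the solid angle of an az×el cell).  The
    contralateral share is reported both as the fraction of summed vector
    magnitudes and as the resultant-vector fraction (the two readings of
    "total sensitivity"); azimuths below the midline are contralateral.
    """
    mags = rf.magnitudes()
    mx = mags.max()
    if mx == 0:
        raise ValueError("all-zero field: metrics undefined")
    cosw = np.cos(np.radians(rf.elevations_deg))[None, :]
    cell = np.ones_like(mags) * cosw
    areas = {lv: float(cell[mags >= lv * mx].sum()) for lv in levels}
    contra = rf.azimuths_deg < rf.midline_azimuth_deg
    s_contra = float(mags[contra].sum())
    s_ipsi = float(mags[~contra].sum())
    res_contra = np.linalg.norm(rf.vectors[contra].reshape(-1, 2).sum(axis=0))
    res_total = np.linalg.norm(rf.vectors.reshape(-1, 2).sum(axis=0))
    return RFMetrics(
        areas_sr=areas,
        contra_share_sum=s_contra / (s_contra + s_ipsi),
        contra_share_resultant=float(res_contra / res_total) if res_total > 0 else np.nan,
        contra_ipsi_ratio=s_contra / s_ipsi if s_ipsi > 0 else np.inf,
    )


@dataclass
class BandPower:
    low_fraction: float  # [0, 10] Hz
    mid_fraction: float  # (10, 50] Hz
    freqs: np.ndarray
    spectrum: np.ndarray  # normalised to unit total


def power_bands(trace: np.ndarray, fs: float) -> BandPower:
    """Normalised one-sided power spectrum and its band fractions.

    The caller supplies the flash-OFF-period trace; the global mean is
    subtracted here so the DC bin does not swamp the normalisation.
    Raises for traces shorter than 1 s (insufficient resolution).
    """
    x = np.asarray(trace, dtype=float)
    if x.size < fs:
        raise ValueError("trace shorter than 1 s: spectral resolution too coarse")
    f, p = periodogram(x - x.mean(), fs=fs)
    total = p.sum()
    if total == 0:
        raise ValueError("flat trace has no power to normalise")
    p = p / total
    low = float(p[(f >= LOW_BAND_HZ[0]) & (f <= LOW_BAND_HZ[1])].sum())
    mid = float(p[(f > MID_BAND_HZ[0]) & (f <= MID_BAND_HZ[1])].sum())
    return BandPower(low_fraction=low, mid_fraction=mid, freqs=f, spectrum=p)


def average_power_spectrum(traces: list[np.ndarray], fs: float) -> BandPower:
    """Per-repetition periodograms averaged, then normalised to unit total."""
    specs = []
    f = None
    for tr in traces:
        x = np.asarray(tr, dtype=float)
        f, p = periodogram(x - x.mean(), fs=fs)
        specs.append(p)
    p = np.mean(specs, axis=0)
    p = p / p.sum()
    low = float(p[(f >= LOW_BAND_HZ[0]) & (f <= LOW_BAND_HZ[1])].sum())
    mid = float(p[(f > MID_BAND_HZ[0]) & (f <= MID_BAND_HZ[1])].sum())
    return BandPower(low_fraction=low, mid_fraction=mid, freqs=f, spectrum=p)


def flash_response(
    v: np.ndarray,
    fs: float,
    events: list[tuple[float, str]],
    response_window_s: float = 0.5,
    baseline_window_s: float = 0.2,
) -> pd.DataFrame:
    """Peak |deviation from pre-event baseline| within 0.5 s of each flash.

    ``events`` is a list of (onset_s, kind) with kind "ON" or "OFF";
    returns per-kind mean transient amplitude and the per-event values.
    """
    v = np.asarray(v, dtype=float)
    rows = []
    for t0, kind in events:
        i0 = int(round(t0 * fs))
        ib = max(0, i0 - int(round(baseline_window_s * fs)))
        i1 = min(v.size, i0 + int(round(response_window_s * fs)))
        if i1 <= i0:
            continue
        base = v[ib:i0].mean() if i0 > ib else 0.0
        rows.append({"onset_s": t0, "kind": kind,
                     "amplitude_mv": float(np.abs(v[i0:i1] - base).max())})
    return pd.DataFrame(rows, columns=["onset_s", "kind", "amplitude_mv"])


def tuning_curves(
    v: np.ndarray,
    fs: float,
    trials: pd.DataFrame,
    static_s: float = 2.0,
    motion_s: float = 2.0,
    normalise_by: str | None = "direction",
) -> pd.DataFrame:
    """Grating responses: motion-period mean minus preceding-static mean.

    ``trials`` needs columns ``t_start`` (static onset, s) and one or more
    parameter columns (direction / contrast / temporal_frequency).  The
    trial structure is 2 s static, 2 s motion (1 s static tail unused).
    When ``normalise_by`` names a parameter column, responses are divided
    by the cell's maximum absolute response over that curve.
    """
    v = np.asarray(v, dtype=float)
    rows = []
    for _, tr in trials.iterrows():
        a = int(round(tr["t_start"] * fs))
        m = a + int(round(static_s * fs))
        b = m + int(round(motion_s * fs))
        if b > v.size or m <= a:
            raise ValueError("trial extends past the recording or has no static period")
        resp = v[m:b].mean() - v[a:m].mean()
        row = dict(tr)
        row["response_mv"] = float(resp)
        rows.append(row)
    out = pd.DataFrame(rows)
    if normalise_by is not None and normalise_by in out:
        mx = out["response_mv"].abs().max()
        out["response_norm"] = out["response_mv"] / mx if mx > 0 else np.nan
    return out
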