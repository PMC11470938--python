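"""Saccade detection by stationary-wavelet band isolation.

Walking flies alternate smooth turning with brief, large angular-velocity
spikes (body saccades).  The detector follows a wavelet strategy: the
stationary wavelet transform (bior2.6) of the angular velocity is computed,
the detail levels whose dyadic bands intersect 10–20 Hz are retained, and
the inverse transform yields a shift-invariant band-limited reconstruction
in which saccades stand out as isolated excursions while smooth turning
(<5 Hz) and DC are suppressed.

Candidate events are local maxima of the reconstruction magnitude.  Because
band-passing attenuates a raised-cosine pulse several-fold (and more the
longer the pulse), amplitude and width criteria are evaluated on the raw
angular-velocity excursion backing each candidate: peak angular speed must
exceed 200 deg/s, and the excursion width — measured between the sub-frame
interpolated crossings of 20 % of the peak — must lie strictly between
50 and 250 ms.  Onset/offset are those boundary crossings; displacement is
integrated on the raw signal between them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt
from scipy.signal import find_peaks

from .kinematics import Trial

PEAK_THRESHOLD_DEG_S = 200.0
WIDTH_MIN_S = 0.050
WIDTH_MAX_S = 0.250
WAVELET = "bior2.6"
BAND_HZ = (10.0, 20.0)
RECON_FLOOR_DEG_S = 2.0  # skip numerically-null wiggles of the reconstruction
BOUNDARY_FRACTION = 0.2  # excursion edges at this fraction of the peak


class SamplingRateError(ValueError):
    """Raised when fs cannot represent the 10–20 Hz detection band."""


def swt_bandpass(
    x: np.ndarray,
    fs: float,
    band: tuple[float, float] = BAND_HZ,
    wavelet: str = WAVELET,
) -> np.ndarray:
    """Band-limited reconstruction via the stationary wavelet transform.

    Decomposes to the level whose detail band falls below the band's lower
    edge, zeroes the approximation and any detail whose nominal dyadic band
    [fs/2^(j+1), fs/2^j] does not intersect ``band``, and inverts.  At
    60 Hz this keeps d1 (15–30 Hz) and d2 (7.5–15 Hz).  Input is padded
    symmetrically to a multiple of 2^levels; padding is stripped after
    reconstruction.
    """
    x = np.asarray(x, dtype=float)
    if fs <= 2 * band[1]:
        raise SamplingRateError(f"fs={fs} Hz cannot represent the {band} Hz band")
    n = x.size
    level = 1
    while fs / 2 ** (level + 1) > band[0]:
        level += 1
    m = 2**level
    pad = (-n) % m
    left, right = pad // 2, pad - pad // 2
    xp = np.pad(x, (left, right), mode="symmetric")
    coeffs = pywt.swt(xp, wavelet, level=level)
    filtered = []
    for i, (cA, cD) in enumerate(coeffs):
        j = level - i
        lo, hi = fs / 2 ** (j + 1), fs / 2**j
        keep = hi > band[0] and lo < band[1]
        filtered.append((np.zeros_like(cA), cD if keep else np.zeros_like(cD)))
    rec = pywt.iswt(filtered, wavelet)
    return rec[left : left + n]


def fft_bandpass(x: np.ndarray, fs: float, band: tuple[float, float] = BAND_HZ) -> np.ndarray:
    """Ideal brick-wall band-pass; the independent oracle for the SWT path."""
    x = np.asarray(x, dtype=float)
    X = np.fft.rfft(x)
    f = np.fft.rfftfreq(x.size, 1 / fs)
    X[(f < band[0]) | (f > band[1])] = 0
    return np.fft.irfft(X, x.size)


@dataclass
class SaccadeEvent:
    onset: int
    offset: int
    peak_frame: int
    onset_time_s: float  # sub-frame interpolated boundary crossings
    offset_time_s: float
    peak_speed: float  # deg/s, raw angular speed at the peak
    peak_recon: float  # deg/s, reconstruction magnitude at the candidate
    displacement_deg: float  # signed, integrated raw ang vel over the event
    klass: str = ""  # syn / anti, filled by classify_saccades
    trial_id: int = -1
    pre_motion: bool = False


def _excursion_bounds(
    w: np.ndarray, p: int, sign: float, peak: float, frac: float
) -> tuple[int, int, float, float]:
    """Walk out from the raw peak to the ``frac``·peak crossings.

    Descent stops early at a local minimum once below half peak, so an
    event riding on strong smooth background does not bleed into it.
    Returns integer bounds plus interpolated fractional crossing times.
    """
    thr = frac * peak

    def walk(step: int) -> int:
        i = p
        while 0 <= i + step < w.size:
            cur, nxt = w[i] * sign, w[i + step] * sign
            if nxt > thr and not (cur < 0.5 * peak and nxt >= cur):
                i += step
            else:
                break
        return i

    a, b = walk(-1), walk(1)
    af, bf = float(a), float(b)
    if a > 0 and w[a] * sign > thr > w[a - 1] * sign:
        af = a - (w[a] * sign - thr) / (w[a] * sign - w[a - 1] * sign)
    if b < w.size - 1 and w[b] * sign > thr > w[b + 1] * sign:
        bf = b + (w[b] * sign - thr) / (w[b] * sign - w[b + 1] * sign)
    return a, b, af, bf


def detect_saccades(
    ang_vel: np.ndarray,
    fs: float,
    method: str = "swt",
    peak_threshold: float = PEAK_THRESHOLD_DEG_S,
    width_bounds_s: tuple[float, float] = (WIDTH_MIN_S, WIDTH_MAX_S),
    recon_floor: float = RECON_FLOOR_DEG_S,
    boundary_fraction: float = BOUNDARY_FRACTION,
) -> list[SaccadeEvent]:
    """Detect saccades in one angular-velocity series.

    ``method`` selects the band-isolation backend: ``"swt"`` (the wavelet
    detector) or ``"fft"`` (the brick-wall oracle used for equivalence
    testing).  NaNs (invalid frames) are treated as zero turning for the
    band isolation; events are never reported on invalid frames.
    """
    w = np.asarray(ang_vel, dtype=float)
    nanmask = ~np.isfinite(w)
    if nanmask.any():
        w = np.where(nanmask, 0.0, w)
    band_fn = {"swt": swt_bandpass, "fft": fft_bandpass}[method]
    r = band_fn(w, fs)

    half_window = max(1, int(round(0.125 * fs)))  # candidate→raw-peak search span
    cand, _ = find_peaks(np.abs(r), height=recon_floor)
    events: list[SaccadeEvent] = []
    used_peaks: set[int] = set()
    wmin, wmax = width_bounds_s
    for c in cand:
        lo, hi = max(0, c - half_window), min(w.size, c + half_window + 1)
        p = lo + int(np.argmax(np.abs(w[lo:hi])))
        if p in used_peaks:
            continue
        sign = 1.0 if w[p] >= 0 else -1.0
        peak = abs(w[p])
        if peak <= peak_threshold:
            continue
        a, b, af, bf = _excursion_bounds(w, p, sign, peak, boundary_fraction)
        width = (bf - af) / fs
        if not (wmin < width < wmax):
            continue
        if nanmask[a : b + 1].any():
            continue
        used_peaks.add(p)
        events.append(
            SaccadeEvent(
                onset=a,
                offset=b,
                peak_frame=p,
                onset_time_s=af / fs,
                offset_time_s=bf / fs,
                peak_speed=peak,
                peak_recon=abs(r[c]),
                displacement_deg=float(np.trapezoid(w[a : b + 1], dx=1 / fs)) * 1.0,
            )
        )
    # resolve overlaps: keep the larger peak
    events.sort(key=lambda e: -e.peak_speed)
    kept: list[SaccadeEvent] = []
    for e in events:
        if all(e.offset < k.onset or e.onset > k.offset for k in kept):
            kept.append(e)
    kept.sort(key=lambda e: e.onset)
    return kept


def score_benchmark(
    benchmark: list[tuple[np.ndarray, pd.DataFrame]],
    fs: float,
    method: str = "swt",
    match_tolerance_s: float = 0.033,
) -> dict:
    """Detector performance against planted ground truth.

    A detection matches a planted event when its peak falls inside the
    event's support (± ``match_tolerance_s``) with the same turning sign;
    each planted event absorbs at most one detection.  Returns hit rate,
    false-discovery rate, mean |onset error| (detected boundary vs planted
    support start, seconds) and the per-trial detection counts.
    """
    hits = total = false_pos = detections = 0
    onset_errors: list[float] = []
    counts: list[int] = []
    for w, gt in benchmark:
        events = detect_saccades(w, fs, method=method)
        counts.append(len(events))
        detections += len(events)
        total += len(gt)
        matched: set[int] = set()
        for e in events:
            hit = False
            for gi, row in gt.iterrows():
                if gi in matched:
                    continue
                if (
                    row.onset_s - match_tolerance_s
                    <= e.peak_frame / fs
                    <= row.offset_s + match_tolerance_s
                    and np.sign(e.displacement_deg) == np.sign(row.peak_deg_s)
                ):
                    matched.add(gi)
                    hit = True
                    onset_errors.append(abs(e.onset_time_s - row.onset_s))
                    break
            if not hit:
                false_pos += 1
        hits += len(matched)
    return {
        "hit_rate": hits / total if total else float("nan"),
        "false_discovery_rate": false_pos / detections if detections else 0.0,
        "mean_onset_error_s": float(np.mean(onset_errors)) if onset_errors else float("nan"),
        "n_planted": total,
        "n_detected": detections,
        "counts_per_trial": counts,
    }


def events_to_frame(events: list[SaccadeEvent]) -> pd.DataFrame:
    cols = [
        "trial_id", "onset", "offset", "peak_frame", "onset_time_s", "offset_time_s",
        "peak_speed", "peak_recon", "displacement_deg", "klass", "pre_motion",
    ]
    return pd.DataFrame([{c: getattr(e, c) for c in cols} for e in events], columns=cols)


def classify_saccades(
    events: list[SaccadeEvent],
    trial: Trial,
    mirror_sign: float | None = None,
) -> list[SaccadeEvent]:
    """Label events in one trial as syn (with stimulus) or anti (against).

    The trial must already be in the stimulus-relative frame
    (``align_to_stimulus``); ``mirror_sign`` overrides the sign inferred
    from the trial's mirrored flag when events were detected on the raw
    (unmirrored) series.  Zero displacement ties break to syn.  Events
    whose peak precedes motion onset keep the upcoming trial's frame but
    are flagged ``pre_motion``.
    """
    s = mirror_sign if mirror_sign is not None else (-1.0 if trial.mirrored else 1.0)
    out = []
    for e in events:
        d = e.displacement_deg * s
        out.append(
            SaccadeEvent(
                **{
                    **e.__dict__,
                    "klass": "syn" if d >= 0 else "anti",
                    "trial_id": trial.trial_id,
                    "pre_motion": e.peak_frame < trial.motion_onset,
                }
            )
        )
    return out


@dataclass
class TurningDecomposition:
    smooth: np.ndarray
    saccadic: np.ndarray
    mean_smooth: float  # deg/s over the motion period
    mean_saccadic: float
    cum_smooth_deg: float
    cum_syn_deg: float
    cum_anti_deg: float


def decompose_turning(
    ang_vel: np.ndarray,
    events: list[SaccadeEvent],
    fs: float,
    motion_slice: slice | None = None,
) -> TurningDecomposition:
    """Split turning into saccadic (inside event windows) and smooth parts.

    ``smooth + saccadic`` equals the input exactly at every frame.
    Cumulative displacements are trapezoidal integrals over the motion
    period (the whole series when ``motion_slice`` is None), with the
    saccadic part split by syn/anti label.
    """
    w = np.asarray(ang_vel, dtype=float)
    sacc = np.zeros_like(w)
    for i, e in enumerate(events):
        for j, other in enumerate(events):
            if i < j and not (e.offset < other.onset or e.onset > other.offset):
                raise ValueError("overlapping saccade events")
    syn_mask = np.zeros(w.size, dtype=bool)
    anti_mask = np.zeros(w.size, dtype=bool)
    for e in events:
        sl = slice(e.onset, e.offset + 1)
        sacc[sl] = w[sl]
        (syn_mask if e.klass != "anti" else anti_mask)[sl] = True
    smooth = w - sacc
    sl = motion_slice if motion_slice is not None else slice(0, w.size)
    dt = 1 / fs

    def _integ(y: np.ndarray) -> float:
        y = np.nan_to_num(y[sl])
        return float(np.trapezoid(y, dx=dt))

    return TurningDecomposition(
        smooth=smooth,
        saccadic=sacc,
        mean_smooth=float(np.nanmean(smooth[sl])),
        mean_saccadic=float(np.nanmean(sacc[sl])),
        cum_smooth_deg=_integ(smooth),
        cum_syn_deg=_integ(np.where(syn_mask, sacc, 0.0)),
        cum_anti_deg=_integ(np.where(anti_mask, sacc, 0.0)),
    )


def saccade_summary(
    trials: list[Trial],
    events: list[SaccadeEvent],
    fs: float,
    fly_id: int | str = 0,
) -> pd.DataFrame:
    """Per-condition aggregates for one fly.

    Counts, rates (events/s of motion period), mean |displacement|, mean
    peak speed and per-trial cumulative syn/anti displacement, with SEM
    across trials.  Conditions without kept trials yield a zero-count row.
    """
    ev = events_to_frame(events)
    rows = []
    for kind in sorted({t.kind for t in trials}):
        kept = [t for t in trials if t.kind == kind and not t.excluded]
        ids = {t.trial_id for t in kept}
        sub = ev[ev["trial_id"].isin(ids) & ~ev["pre_motion"]] if len(ev) else ev
        motion_s = sum((t.end - t.motion_onset) for t in kept) / fs if kept else 0.0
        per_trial_syn = []
        per_trial_anti = []
        for t in kept:
            tsub = sub[sub["trial_id"] == t.trial_id] if len(sub) else sub
            per_trial_syn.append(tsub[tsub["klass"] == "syn"]["displacement_deg"].abs().sum() if len(tsub) else 0.0)
            per_trial_anti.append(tsub[tsub["klass"] == "anti"]["displacement_deg"].abs().sum() if len(tsub) else 0.0)
        n_ev = len(sub)
        rows.append(
            {
                "fly_id": fly_id,
                "condition": kind,
                "n_trials": len(kept),
                "n_saccades": n_ev,
                "rate_hz": n_ev / motion_s if motion_s > 0 else 0.0,
                "mean_amplitude_deg": sub["displacement_deg"].abs().mean() if n_ev else 0.0,
                "mean_peak_speed": sub["peak_speed"].mean() if n_ev else 0.0,
                "cum_syn_deg": float(np.mean(per_trial_syn)) if kept else 0.0,
                "cum_syn_sem": float(np.std(per_trial_syn, ddof=1) / np.sqrt(len(kept))) if len(kept) > 1 else 0.0,
                "cum_anti_deg": float(np.mean(per_trial_anti)) if kept else 0.0,
                "cum_anti_sem": float(np.std(per_trial_anti, ddof=1) / np.sqrt(len(kept))) if len(kept) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)
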