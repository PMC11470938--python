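"""The central nonlinearity test: full-field response vs summed unilateral responses.

If each eye's optic-flow drive were combined linearly, the turning response
to full-field rotation would equal the sum of the responses to unilateral
front-to-back and back-to-front motion.  The analysis builds that linear
prediction from per-fly condition means, subtracts it from the measured
full-field response, and tests the per-fly mean prediction error (over the
motion period) against zero with a one-sample two-sided t-test.  Group
comparisons (e.g. between genotypes) use the two-sided Mann–Whitney U test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import kinematics, saccades, synthetic_data
from .stimulus import ConditionKind, RotationDir, StimulusCondition


@dataclass
class PredictionErrorResult:
    predicted: np.ndarray  # deg/s, trial time
    actual: np.ndarray
    error: np.ndarray  # actual − predicted, framewise
    mean_error: float  # over the motion period
    mean_error_smooth: float = np.nan  # channel-wise variants, when provided
    mean_error_saccadic: float = np.nan


@dataclass
class GroupStatResult:
    test: str
    statistic: float
    p_value: float
    n: tuple[int, ...]


def linear_prediction(mean_ftb: np.ndarray, mean_btf: np.ndarray) -> np.ndarray:
    """Predicted full-field response: framewise sum of the unilateral means."""
    a = np.asarray(mean_ftb, dtype=float)
    b = np.asarray(mean_btf, dtype=float)
    if a.shape != b.shape:
        raise ValueError("unilateral mean series must have equal length")
    return a + b


def prediction_error(
    actual_full_field: np.ndarray,
    predicted: np.ndarray,
    motion_slice: slice | None = None,
    actual_channels: tuple[np.ndarray, np.ndarray] | None = None,
    predicted_channels: tuple[np.ndarray, np.ndarray] | None = None,
) -> PredictionErrorResult:
    """Framewise error series and its mean over the motion period.

    Optional ``*_channels`` are (smooth, saccadic) decompositions; their
    channel errors sum to the total error framewise by construction.
    """
    actual = np.asarray(actual_full_field, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if actual.shape != predicted.shape:
        raise ValueError("series must share trial-time alignment and length")
    err = actual - predicted
    sl = motion_slice if motion_slice is not None else slice(0, err.size)
    res = PredictionErrorResult(
        predicted=predicted,
        actual=actual,
        error=err,
        mean_error=float(np.nanmean(err[sl])),
    )
    if actual_channels is not None and predicted_channels is not None:
        res.mean_error_smooth = float(
            np.nanmean(actual_channels[0][sl] - predicted_channels[0][sl])
        )
        res.mean_error_saccadic = float(
            np.nanmean(actual_channels[1][sl] - predicted_channels[1][sl])
        )
    return res


def one_sample_t(values: np.ndarray) -> GroupStatResult:
    """Two-sided one-sample t-test of the mean against zero."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    if np.allclose(v.std(ddof=1), 0):
        raise ValueError("zero variance: t statistic undefined")
    t, p = stats.ttest_1samp(v, 0.0)
    return GroupStatResult("one_sample_t_two_sided", float(t), float(p), (v.size,))


def mann_whitney_u(group_a: np.ndarray, group_b: np.ndarray) -> GroupStatResult:
    """Two-sided Mann–Whitney U test.

    Exact enumeration for small untied samples (combined n ≤ 12), normal
    approximation with tie correction otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size + b.size <= 12 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupStatResult(
        "mann_whitney_u_two_sided", float(res.statistic), float(res.pvalue), (a.size, b.size)
    )


# --------------------------------------------------------------------------
# full synthetic experiment: walker → pipeline → prediction error per fly
# --------------------------------------------------------------------------

_CONDITIONS = {
    "full_field": (ConditionKind.FULL_FIELD, RotationDir.CW),
    "unilateral_FtB": (ConditionKind.UNILATERAL_FTB, RotationDir.CW),
    "unilateral_BtF": (ConditionKind.UNILATERAL_BTF, RotationDir.CW),
}


def _fly_condition_mean(
    params: synthetic_data.WalkerParams,
    condition: StimulusCondition,
    n_trials: int,
    fs: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean stimulus-relative (total, smooth, saccadic) series over kept trials."""
    traj, _, log = synthetic_data.simulate_walker(params, condition, n_trials)
    traj = kinematics.derive_kinematics(traj, fs)
    trials = kinematics.segment_trials(traj, log, fs, params.arena_radius_mm)
    traj, trials = kinematics.align_to_stimulus(traj, trials)
    rel = traj["ang_vel_rel"].to_numpy()
    n_frames = trials[0].end - trials[0].start
    tot = np.zeros(n_frames)
    smo = np.zeros(n_frames)
    sac = np.zeros(n_frames)
    kept = 0
    for t in trials:
        if t.excluded:
            continue
        seg = rel[t.start : t.end]
        ev = saccades.detect_saccades(seg, fs)
        dec = saccades.decompose_turning(seg, ev, fs)
        tot += np.nan_to_num(seg)
        smo += np.nan_to_num(dec.smooth)
        sac += np.nan_to_num(dec.saccadic)
        kept += 1
    if kept == 0:
        raise RuntimeError("no kept trials for condition")
    return tot / kept, smo / kept, sac / kept


def run_linearity_experiment(
    n_flies: int = 15,
    trials_per_fly: int = 200,
    linearity_mode: str = "linear",
    seed: int = 0,
    fs: float = 60.0,
    walker_kwargs: dict | None = None,
) -> dict:
    """Simulate a cohort and run the full linearity analysis.

    ``trials_per_fly`` is split evenly across the three motion conditions.
    Returns a dict with per-fly mean errors (total / smooth / saccadic
    channels) and the one-sample t-test on the total-channel errors.
    """
    rng = np.random.default_rng(seed)
    per_cond = trials_per_fly // 3
    fly_errors = []
    fly_errors_smooth = []
    fly_errors_sacc = []
    for fly in range(n_flies):
        fly_seed = int(rng.integers(0, 2**31 - 1))
        means = {}
        for i, (name, (kind, rot)) in enumerate(_CONDITIONS.items()):
            params = synthetic_data.WalkerParams(
                linearity_mode=linearity_mode,
                seed=fly_seed + i,
                **(walker_kwargs or {}),
            )
            cond = StimulusCondition(kind=kind, rotation_dir=rot)
            means[name] = _fly_condition_mean(params, cond, per_cond, fs)
        n_static = round(5.0 * fs)
        motion = slice(n_static, means["full_field"][0].size)
        pred = linear_prediction(means["unilateral_FtB"][0], means["unilateral_BtF"][0])
        pred_ch = (
            means["unilateral_FtB"][1] + means["unilateral_BtF"][1],
            means["unilateral_FtB"][2] + means["unilateral_BtF"][2],
        )
        res = prediction_error(
            means["full_field"][0],
            pred,
            motion_slice=motion,
            actual_channels=means["full_field"][1:],
            predicted_channels=pred_ch,
        )
        fly_errors.append(res.mean_error)
        fly_errors_smooth.append(res.mean_error_smooth)
        fly_errors_sacc.append(res.mean_error_saccadic)
    t = one_sample_t(np.array(fly_errors))
    return {
        "per_fly_mean_error": np.array(fly_errors),
        "per_fly_mean_error_smooth": np.array(fly_errors_smooth),
        "per_fly_mean_error_saccadic": np.array(fly_errors_sacc),
        "group_mean_error": float(np.mean(fly_errors)),
        "t_statistic": t.statistic,
        "p_value": t.p_value,
    }
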