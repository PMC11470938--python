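import numpy as np
import pytest

from flysteer import saccades as sc
from flysteer import synthetic_data as sd
from flysteer.kinematics import Trial

FS = 60.0


def pulse(n=600, t0=5.0, duration=0.12, peak=500.0, sign=1.0):
    return sd.raised_cosine_pulse(n, FS, t0, duration, peak) * sign


class TestDetector:
    def test_constant_rotation_no_events(self):
        assert sc.detect_saccades(np.full(600, 150.0), FS) == []

    def test_single_planted_pulse_detected(self):
        w = pulse()
        ev = sc.detect_saccades(w, FS)
        assert len(ev) == 1
        planted_peak_frame = round((5.0 + 0.06) * FS)
        assert abs(ev[0].peak_frame - planted_peak_frame) <= 2
        assert ev[0].peak_speed > 200
        assert 0.05 < ev[0].offset_time_s - ev[0].onset_time_s < 0.25

    def test_long_pulse_rejected_by_width(self):
        assert sc.detect_saccades(pulse(duration=0.4), FS) == []

    def test_subthreshold_pulse_rejected(self):
        assert sc.detect_saccades(pulse(peak=150.0), FS) == []

    def test_sign_equivariance(self):
        w = pulse() + pulse(t0=2.0, sign=-1.0)
        ev = sc.detect_saccades(w, FS)
        ev_neg = sc.detect_saccades(-w, FS)
        assert len(ev) == len(ev_neg) == 2
        d1 = sorted(e.displacement_deg for e in ev)
        d2 = sorted(-e.displacement_deg for e in ev_neg)
        assert np.allclose(d1, d2)

    def test_low_sampling_rate_raises(self):
        with pytest.raises(sc.SamplingRateError):
            sc.detect_saccades(np.zeros(100), fs=30.0)

    def test_swt_band_selection_at_60hz(self):
        """At 60 Hz the retained levels are d1 (15-30 Hz) and d2 (7.5-15 Hz):
        a 1 Hz tone is annihilated while a 15 Hz tone survives."""
        t = np.arange(512) / FS
        slow = sc.swt_bandpass(np.sin(2 * np.pi * 1.0 * t) * 100, FS)
        fast = sc.swt_bandpass(np.sin(2 * np.pi * 15.0 * t) * 100, FS)
        assert np.abs(slow[50:-50]).max() < 0.1 * np.abs(fast[50:-50]).max()

    def test_benchmark_recovery(self, detector_benchmark):
        """Planted pulses on smooth background: all found, none invented."""
        hits = tot = fp = det = 0
        for w, gt in detector_benchmark:
            ev = sc.detect_saccades(w, FS)
            det += len(ev)
            tot += len(gt)
            matched = set()
            for e in ev:
                ok = False
                for gi, row in gt.iterrows():
                    if gi in matched:
                        continue
                    if (
                        row.onset_s - 0.033 <= e.peak_frame / FS <= row.offset_s + 0.033
                        and np.sign(e.displacement_deg) == np.sign(row.peak_deg_s)
                    ):
                        matched.add(gi)
                        ok = True
                        break
                if not ok:
                    fp += 1
            hits += len(matched)
        assert hits / tot >= 0.9
        assert fp / max(det, 1) <= 0.1

    def test_swt_and_fft_oracle_agree(self, detector_benchmark):
        same = sum(
            len(sc.detect_saccades(w, FS)) == len(sc.detect_saccades(w, FS, method="fft"))
            for w, _ in detector_benchmark
        )
        assert same >= 0.95 * len(detector_benchmark)


def _trial(mirrored=False, motion_onset=300):
    return Trial(
        trial_id=1, kind="full_field", rotation_dir="CCW" if mirrored else "CW",
        start=0, motion_onset=motion_onset, end=600, mirrored=mirrored,
    )


class TestClassification:
    def _event(self, disp, peak_frame=350):
        return sc.SaccadeEvent(
            onset=peak_frame - 3, offset=peak_frame + 3, peak_frame=peak_frame,
            onset_time_s=0, offset_time_s=0, peak_speed=400.0, peak_recon=50.0,
            displacement_deg=disp,
        )

    def test_positive_displacement_is_syn(self):
        out = sc.classify_saccades([self._event(35.0)], _trial())
        assert out[0].klass == "syn" and not out[0].pre_motion

    def test_negative_displacement_is_anti(self):
        assert sc.classify_saccades([self._event(-20.0)], _trial())[0].klass == "anti"

    def test_mirroring_composition(self):
        # CCW trial, raw displacement +20 -> -20 stimulus-relative -> anti
        out = sc.classify_saccades([self._event(20.0)], _trial(mirrored=True), mirror_sign=-1.0)
        assert out[0].klass == "anti"

    def test_zero_displacement_ties_to_syn(self):
        assert sc.classify_saccades([self._event(0.0)], _trial())[0].klass == "syn"

    def test_pre_motion_flagged(self):
        out = sc.classify_saccades([self._event(10.0, peak_frame=100)], _trial())
        assert out[0].pre_motion


class TestDecomposition:
    def test_no_events_identity(self):
        w = np.sin(np.arange(600) / 20.0) * 50
        d = sc.decompose_turning(w, [], FS)
        assert np.array_equal(d.saccadic, np.zeros_like(w))
        assert np.array_equal(d.smooth, w)

    def test_conservation_exact(self, detector_benchmark):
        for w, _ in detector_benchmark:
            ev = sc.detect_saccades(w, FS)
            d = sc.decompose_turning(w, ev, FS)
            assert np.array_equal(d.smooth + d.saccadic, w)

    def test_hand_integrated_displacement(self):
        # event spanning frames 100..107 at a constant 300 deg/s
        w = np.zeros(600)
        w[100:108] = 300.0
        ev = [
            sc.SaccadeEvent(
                onset=100, offset=107, peak_frame=103, onset_time_s=100 / FS,
                offset_time_s=107 / FS, peak_speed=300.0, peak_recon=0.0,
                displacement_deg=0.0, klass="syn",
            )
        ]
        d = sc.decompose_turning(w, ev, FS)
        # 8 frames at 300 deg/s: 300 * 8 / 60 = 40 deg (the trapezoid's ramp
        # edges onto the zero baseline contribute the two half-frames)
        assert d.cum_syn_deg == pytest.approx(40.0)

    def test_overlapping_events_rejected(self):
        e1 = sc.SaccadeEvent(10, 20, 15, 0, 0, 300, 0, 5.0)
        e2 = sc.SaccadeEvent(18, 30, 25, 0, 0, 300, 0, 5.0)
        with pytest.raises(ValueError):
            sc.decompose_turning(np.zeros(100), [e1, e2], FS)


class TestSummary:
    def test_two_syn_saccades_cumulative(self):
        trial = _trial()
        evs = []
        for f, disp in ((320, 30.0), (400, 10.0)):
            e = sc.SaccadeEvent(f - 3, f + 3, f, 0, 0, 400, 50, disp)
            evs += sc.classify_saccades([e], trial)
        table = sc.saccade_summary([trial], evs, FS)
        row = table.iloc[0]
        assert row.n_saccades == 2
        assert row.cum_syn_deg == pytest.approx(40.0)
        assert row.cum_anti_deg == 0.0

    def test_no_events_zero_aggregates(self):
        table = sc.saccade_summary([_trial()], [], FS)
        assert table.iloc[0].n_saccades == 0
        assert table.iloc[0].cum_syn_deg == 0.0

    def test_recovered_rate_close_to_generator(self, full_field_cw):
        """Detected syn-saccade rate tracks the planted Poisson rate."""
        params = sd.WalkerParams(seed=3, smooth_turn_noise_sd=15.0)
        traj, gt, log = sd.simulate_walker(params, full_field_cw, 40)
        from flysteer import kinematics as km

        traj = km.derive_kinematics(traj, FS)
        trials = km.segment_trials(traj, log, FS)
        traj, trials = km.align_to_stimulus(traj, trials)
        w = traj["ang_vel_rel"].to_numpy()
        n_det = 0
        motion_s = 0.0
        for t in trials:
            if t.excluded:
                continue
            seg = w[t.start : t.end]
            ev = sc.detect_saccades(seg, FS)
            n_det += sum(1 for e in ev if e.peak_frame >= t.motion_onset - t.start)
            motion_s += (t.end - t.motion_onset) / FS
        planted_rate = 0.5 + 0.1  # syn + anti events/s during motion
        assert n_det / motion_s == pytest.approx(planted_rate, rel=0.35)
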