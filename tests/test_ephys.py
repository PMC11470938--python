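import numpy as np
import pandas as pd
import pytest

from flysteer import ephys
from flysteer import synthetic_data as sd


class TestBaseline:
    def test_constant_trace_zeroed(self):
        v, fallback = ephys.rolling_baseline_subtract(np.full(5000, -50.0), fs=50.0)
        assert np.allclose(v, 0.0)
        assert not fallback

    def test_slow_ramp_interior_near_zero(self):
        fs = 50.0
        t = np.arange(int(300 * fs)) / fs
        v, _ = ephys.rolling_baseline_subtract(t * (1.0 / 60.0), fs)  # 1 mV/min drift
        w = int(60 * fs)
        # interior residual is bounded by the even-window half-sample
        # asymmetry, slope/(2 fs) ~ 1.7e-4 mV; the 5 mV drift is gone
        assert np.abs(v[w:-w]).max() < 1e-3

    def test_fast_oscillation_preserved(self):
        fs = 1000.0
        t = np.arange(int(150 * fs)) / fs
        x = np.sin(2 * np.pi * 20.0 * t)
        v, _ = ephys.rolling_baseline_subtract(x, fs)
        half = int(30 * fs)  # interior, clear of the shrinking edge windows
        assert np.corrcoef(v[half:-half], x[half:-half])[0, 1] > 0.999

    def test_short_record_falls_back_to_global_mean(self):
        v, fallback = ephys.rolling_baseline_subtract(np.array([1.0, 2.0, 3.0]), fs=1.0)
        assert fallback
        assert v.mean() == pytest.approx(0.0)


class TestBinning:
    def test_constant_trace(self):
        ft = np.arange(10) / 60.0
        out = ephys.bin_responses(np.full(2000, 2.0), 10_000.0, ft)
        assert np.allclose(out, 2.0)

    def test_step_at_bin_boundary(self):
        fs = 600.0  # 10 samples per 16.6 ms bin
        v = np.concatenate([np.zeros(10), np.ones(10)])
        out = ephys.bin_responses(v, fs, np.array([0.0, 10 / fs]))
        assert out[0] == 0.0 and out[1] == 1.0

    def test_empty_bin_is_nan(self):
        out = ephys.bin_responses(np.zeros(5), 60.0, np.array([0.0, 100.0]))
        assert np.isnan(out[1])

    def test_decreasing_times_raise(self):
        with pytest.raises(ValueError):
            ephys.bin_responses(np.zeros(100), 60.0, np.array([0.5, 0.1]))


def _identity_setup(contra_fraction=None, noise_sd=0.0, reps=1, seed=0):
    rf = sd.make_planted_rf(contra_fraction=contra_fraction, noise_sd=noise_sd)
    proto = ephys.make_scan_protocol(rf.azimuths_deg, rf.elevations_deg, n_repetitions=reps)
    rec = sd.simulate_scan_responses(rf, proto, seed=seed, fs=2000, resting_potential_mv=0.0)
    binned = ephys.bin_responses(rec.v, rec.fs, rec.frame_times)
    return rf, proto, ephys.reconstruct_rf(binned, proto)


class TestReconstructRF:
    def test_noiseless_identity_factor_two(self):
        rf, _, vf = _identity_setup()
        denom = np.abs(2 * rf.vectors).max()
        assert np.abs(vf.vectors - 2 * rf.vectors).max() / denom < 1e-9

    def test_linearity_in_responses(self):
        rf, proto, vf = _identity_setup()
        rec = sd.simulate_scan_responses(rf, proto, fs=2000, resting_potential_mv=0.0)
        binned = ephys.bin_responses(rec.v, rec.fs, rec.frame_times)
        vf3 = ephys.reconstruct_rf(3.0 * binned, proto)
        assert np.allclose(vf3.vectors, 3.0 * vf.vectors)

    def test_zero_responses_zero_field(self):
        rf, proto, _ = _identity_setup()
        vf = ephys.reconstruct_rf(np.zeros(len(proto.frames)), proto)
        assert np.allclose(vf.vectors, 0.0)

    def test_missing_direction_raises(self):
        rf, proto, _ = _identity_setup()
        bad = ephys.ScanProtocol(
            proto.azimuths_deg,
            proto.elevations_deg,
            proto.frames[proto.frames["direction"] != "+el"].reset_index(drop=True),
        )
        with pytest.raises(ValueError):
            ephys.reconstruct_rf(np.zeros(len(bad.frames)), bad)

    def test_noisy_recovery_cosine_similarity(self):
        rf = sd.make_planted_rf()
        rf.noise_sd = np.linalg.norm(rf.vectors, axis=-1).max() / 5  # SNR 5
        proto = ephys.make_scan_protocol(rf.azimuths_deg, rf.elevations_deg, n_repetitions=3)
        rec = sd.simulate_scan_responses(rf, proto, seed=7, fs=2000, resting_potential_mv=0.0)
        vf = ephys.reconstruct_rf(ephys.bin_responses(rec.v, rec.fs, rec.frame_times), proto)
        m = np.linalg.norm(rf.vectors, axis=-1)
        strong = m >= 0.3 * m.max()
        a, b = vf.vectors[strong], rf.vectors[strong]
        cos = np.einsum("ij,ij->i", a, b) / (
            np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
        )
        assert cos.mean() >= 0.9


class TestRFMetrics:
    def test_uniform_field_full_area(self):
        az, el = np.arange(-10, 11, 5.0), np.arange(-10, 11, 5.0)
        vec = np.ones((az.size, el.size, 2))
        rf = ephys.VectorFieldRF(az, el, vec)
        m = ephys.rf_metrics(rf.normalised())
        expected = float((np.ones((az.size, el.size)) * np.cos(np.radians(el))).sum())
        assert m.areas_sr[0.3] == pytest.approx(expected)

    def test_ipsi_only_field_zero_contra_share(self):
        az = np.arange(-10, 11, 5.0)
        el = np.arange(-5, 6, 5.0)
        vec = np.zeros((az.size, el.size, 2))
        vec[az > 0, :, 0] = 1.0
        m = ephys.rf_metrics(ephys.VectorFieldRF(az, el, vec))
        assert m.contra_share_sum == 0.0

    def test_planted_quarter_contra_share_recovered(self):
        _, _, vf = _identity_setup(contra_fraction=0.25)
        m = ephys.rf_metrics(vf.normalised())
        assert m.contra_share_sum == pytest.approx(0.25, abs=0.02)

    def test_all_zero_field_raises(self):
        rf = ephys.VectorFieldRF(np.array([0.0]), np.array([0.0]), np.zeros((1, 1, 2)))
        with pytest.raises(ValueError):
            ephys.rf_metrics(rf)


class TestPowerBands:
    def test_20hz_tone_mid_band(self):
        tr = sd.simulate_baseline(10.0, 1000.0, [(20.0, 1.0)], seed=0)
        bp = ephys.power_bands(tr, 1000.0)
        assert bp.mid_fraction >= 0.99

    def test_5hz_tone_low_band(self):
        tr = sd.simulate_baseline(10.0, 1000.0, [(5.0, 1.0)], seed=0)
        assert ephys.power_bands(tr, 1000.0).low_fraction >= 0.99

    def test_equal_tones_split_evenly(self):
        tr = sd.simulate_baseline(10.0, 1000.0, [(5.0, 1.0), (20.0, 1.0)], seed=0)
        bp = ephys.power_bands(tr, 1000.0)
        assert bp.low_fraction == pytest.approx(0.5, abs=0.01)
        assert bp.mid_fraction == pytest.approx(0.5, abs=0.01)

    def test_spectrum_sums_to_one(self):
        tr = sd.simulate_baseline(5.0, 500.0, [(7.0, 2.0), (30.0, 1.0)], drift_sd=0.5, seed=1)
        bp = ephys.power_bands(tr, 500.0)
        assert bp.spectrum.sum() == pytest.approx(1.0, abs=1e-9)

    def test_short_trace_raises(self):
        with pytest.raises(ValueError):
            ephys.power_bands(np.zeros(100), 1000.0)

    def test_averaged_spectrum_normalised(self):
        traces = [
            sd.simulate_baseline(4.0, 500.0, [(20.0, 1.0)], white_sd=0.2, seed=s)
            for s in range(3)
        ]
        bp = ephys.average_power_spectrum(traces, 500.0)
        assert bp.spectrum.sum() == pytest.approx(1.0, abs=1e-9)
        assert bp.mid_fraction > 0.8


class TestFlashAndTuning:
    def test_step_response_amplitude(self):
        fs = 1000.0
        v = np.zeros(3000)
        v[1000:] = 5.0
        out = ephys.flash_response(v, fs, [(1.0, "ON")])
        assert out.iloc[0]["amplitude_mv"] == pytest.approx(5.0)

    def test_flat_trace_zero(self):
        out = ephys.flash_response(np.zeros(2000), 1000.0, [(0.5, "OFF")])
        assert out.iloc[0]["amplitude_mv"] == 0.0

    def test_decaying_exponential_peak(self):
        fs = 1000.0
        t = np.arange(2000) / fs
        v = np.zeros(2000)
        after = t >= 0.5
        v[after] = 8.0 * np.exp(-(t[after] - 0.58) ** 2 / (2 * 0.03**2))
        out = ephys.flash_response(v, fs, [(0.5, "ON")])
        assert out.iloc[0]["amplitude_mv"] == pytest.approx(8.0, rel=1e-6)

    def test_tuning_static_subtraction(self):
        fs = 100.0
        v = np.full(int(5 * fs), -2.0)
        v[int(2 * fs) : int(4 * fs)] = 6.0
        trials = pd.DataFrame({"t_start": [0.0], "direction": [0.0]})
        out = ephys.tuning_curves(v, fs, trials)
        assert out.iloc[0]["response_mv"] == pytest.approx(8.0)

    def test_cosine_tuned_cell_preferred_direction(self):
        fs = 100.0
        dirs = np.arange(0, 360, 45.0)
        pref = 90.0
        segs = []
        rows = []
        for i, d in enumerate(dirs):
            resp = 5.0 * np.cos(np.radians(d - pref))
            seg = np.zeros(int(5 * fs))
            seg[int(2 * fs) : int(4 * fs)] = resp
            segs.append(seg)
            rows.append({"t_start": 5.0 * i, "direction": d})
        out = ephys.tuning_curves(np.concatenate(segs), fs, pd.DataFrame(rows))
        best = out.loc[out["response_mv"].idxmax(), "direction"]
        assert abs(best - pref) <= 45.0
        assert out["response_norm"].max() == pytest.approx(1.0)

    def test_missing_static_period_raises(self):
        with pytest.raises(ValueError):
            ephys.tuning_curves(np.zeros(10), 100.0, pd.DataFrame({"t_start": [0.0]}))
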