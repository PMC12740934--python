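"""ECG preprocessing: filtering, beat detection, artifact repair, segmentation."""

import numpy as np
import pytest

from spikeformer.ecg import (
    BeatSeries,
    ECGRecord,
    RecordingQualityError,
    bandpass_ecg,
    correct_beat_series,
    detect_r_peaks,
    make_apnea_segments,
    make_ucddb_windows,
)
from spikeformer.synth import SynthECGSpec, gen_ecg


def tone(freq, fs, seconds):
    t = np.arange(int(seconds * fs)) / fs
    return np.sin(2 * np.pi * freq * t)


def band_gain(freq, fs=100.0, seconds=120.0):
    """Output/input RMS ratio of the band-pass for a pure sinusoid."""
    x = tone(freq, fs, seconds)
    rec = ECGRecord(x + 0.5 * np.random.default_rng(0).standard_normal(len(x)), fs)
    # measure attenuation on the pure tone but keep normalisation honest:
    # filter the raw tone with the same taps by z-scoring manually
    from scipy import signal as sps

    taps = sps.firwin(int(16 * fs) | 1, [0.5, 40.0], pass_zero=False, fs=fs)
    y = sps.fftconvolve(x, taps, mode="same")
    core = slice(int(10 * fs), -int(10 * fs))  # avoid edge transients
    return np.sqrt(np.mean(y[core] ** 2)) / np.sqrt(np.mean(x[core] ** 2))


class TestBandpass:
    def test_drift_attenuated_20db(self):
        assert 20 * np.log10(band_gain(0.1)) <= -20.0

    def test_qrs_band_passes(self):
        assert 20 * np.log10(band_gain(10.0)) >= -1.0

    def test_output_is_zscored(self, rng):
        rec = ECGRecord(rng.standard_normal(20000), 100.0)
        out = bandpass_ecg(rec)
        assert out.signal.mean() == pytest.approx(0.0, abs=1e-6)
        assert out.signal.std() == pytest.approx(1.0, abs=1e-6)

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            bandpass_ecg(ECGRecord(np.zeros(100), 100.0))


class TestDetectRPeaks:
    def test_recovers_60bpm_train(self):
        spec = SynthECGSpec(duration_min=5, base_hr=60, jitter_sd=0.0)
        rec, truth, _ = gen_ecg(spec)
        beats = detect_r_peaks(bandpass_ecg(rec))
        assert abs(len(beats.r_times) - 300) <= 1
        assert np.all(np.abs(beats.rri - 1.0) < 0.02)

    def test_tracks_heart_rate_ramp(self):
        # piecewise train: 45 bpm then 90 bpm; detected rate tracks within 5%
        fs = 100.0
        r_times = np.concatenate(
            [np.arange(0.3, 120, 60 / 45.0), np.arange(120.5, 240, 60 / 90.0)]
        )
        t = np.arange(int(240 * fs)) / fs
        sig = np.zeros(len(t))
        for rt in r_times:
            sig += np.exp(-0.5 * ((t - rt) / 0.0127) ** 2)
        beats = detect_r_peaks(bandpass_ecg(ECGRecord(sig, fs)))
        mid = beats.r_times[:-1]
        early = beats.rri[(mid > 5) & (mid < 115)]
        late = beats.rri[(mid > 125) & (mid < 235)]
        assert np.abs(early.mean() - 60 / 45.0) / (60 / 45.0) < 0.05
        assert np.abs(late.mean() - 60 / 90.0) / (60 / 90.0) < 0.05

    def test_flat_line_flagged_empty(self):
        with pytest.warns(UserWarning):
            beats = detect_r_peaks(ECGRecord(np.zeros(60000), 100.0))
        assert beats.empty

    @pytest.mark.parametrize("bpm", [45, 60, 80, 100, 120])
    def test_mean_rri_recovered_within_2pct(self, bpm):
        spec = SynthECGSpec(duration_min=4, base_hr=bpm, jitter_sd=0.02,
                            seed=bpm)
        rec, truth, _ = gen_ecg(spec)
        beats = correct_beat_series(detect_r_peaks(bandpass_ecg(rec)))
        assert abs(beats.rri.mean() - truth.rri.mean()) / truth.rri.mean() < 0.02


class TestCorrectBeatSeries:
    def _series(self, rri):
        rri = np.asarray(rri, dtype=float)
        r_times = np.concatenate([[0.0], np.cumsum(rri)])
        return BeatSeries(r_times, rri, np.ones(len(r_times)))

    def test_false_peak_pair_repaired(self):
        rri = [1.0] * 10 + [0.4, 0.6] + [1.0] * 10
        fixed = correct_beat_series(self._series(rri))
        assert np.all(np.abs(fixed.rri[10:12] - 1.0) < 0.05)
        assert fixed.flagged[10] and fixed.flagged[11]

    def test_clean_series_unchanged(self, rng):
        rri = 1.0 + 0.01 * rng.standard_normal(50)
        beats = self._series(rri)
        fixed = correct_beat_series(beats)
        np.testing.assert_array_equal(fixed.rri, beats.rri)
        assert not fixed.flagged.any()

    def test_single_outlier_replaced_rest_untouched(self):
        rri = np.ones(21)
        rri[10] = 3.0
        fixed = correct_beat_series(self._series(rri))
        assert fixed.flagged.sum() == 1
        assert fixed.rri[10] == pytest.approx(1.0, abs=1e-6)
        np.testing.assert_array_equal(np.delete(fixed.rri, 10), np.ones(20))

    def test_majority_flagged_raises_quality_error(self):
        # wildly erratic series: most RRIs deviate >20% from the local median
        rri = np.random.default_rng(42).uniform(0.3, 3.0, 40)
        with pytest.raises(RecordingQualityError):
            correct_beat_series(self._series(rri))

    def test_too_few_beats_rejected(self):
        with pytest.raises(ValueError):
            correct_beat_series(self._series([1.0, 1.0]))


class TestMakeApneaSegments:
    def _beats(self, duration_s, rri=1.0):
        r_times = np.arange(0.2, duration_s, rri)
        return BeatSeries(r_times, np.diff(r_times), np.ones(len(r_times)))

    def test_constant_rri_gives_constant_channel(self):
        labels = np.zeros(10, dtype=int)
        segs = make_apnea_segments(self._beats(600), labels, "r")
        assert segs.features.shape[1:] == (2, 900)  # 300 s x 3 Hz
        np.testing.assert_allclose(segs.features[:, 0], 1.0, atol=1e-6)

    def test_boundary_minutes_dropped(self):
        labels = np.zeros(10, dtype=int)
        segs = make_apnea_segments(self._beats(600), labels, "r")
        # minutes 0,1 and 8,9 lack a centred 5-minute context
        assert len(segs) == 6
        assert segs.n_faulty == 4
        assert [m for _, m in segs.segment_index] == [2, 3, 4, 5, 6, 7]

    def test_sparse_beats_dropped_as_faulty(self):
        # 2 s RRI -> ~150 beats per 5-minute window < 100 is false; use 4 s
        beats = self._beats(600, rri=4.0)
        beats = BeatSeries(beats.r_times, beats.rri, beats.r_amp)
        segs = make_apnea_segments(beats, np.zeros(10, dtype=int), "r")
        assert len(segs) == 0
        assert segs.n_faulty == 10

    def test_out_of_range_rri_dropped(self):
        r_times = np.arange(0.2, 600, 1.0)
        rri = np.diff(r_times).copy()
        rri[300] = 3.5  # outside [0.3, 3.0] after "correction"
        beats = BeatSeries(r_times, rri, np.ones(len(r_times)))
        segs = make_apnea_segments(beats, np.zeros(10, dtype=int), "r")
        assert segs.n_faulty > 4  # the boundary 4 plus windows covering the spike

    def test_label_comes_from_central_minute(self):
        labels = np.zeros(10, dtype=int)
        labels[4] = 1
        segs = make_apnea_segments(self._beats(600), labels, "r")
        by_minute = dict(zip([m for _, m in segs.segment_index], segs.labels))
        assert by_minute[4] == 1
        assert all(v == 0 for m, v in by_minute.items() if m != 4)

    def test_deterministic(self):
        labels = np.zeros(10, dtype=int)
        a = make_apnea_segments(self._beats(600), labels, "r")
        b = make_apnea_segments(self._beats(600), labels, "r")
        np.testing.assert_array_equal(a.features, b.features)


class TestUCDDBWindows:
    def _record(self, seconds, fs=128.0):
        rng = np.random.default_rng(0)
        labels = np.zeros(seconds, dtype=int)
        labels[20:40] = 1
        return ECGRecord(
            rng.standard_normal(int(seconds * fs)), fs,
            second_labels=labels, record_id="u",
        )

    def test_window_count_arithmetic(self):
        segs = make_ucddb_windows(self._record(100))
        assert len(segs) == int(100 - 11) + 1 == 90

    def test_window_length_1408_samples_at_128hz(self):
        segs = make_ucddb_windows(self._record(60))
        assert segs.features.shape[1:] == (1, 11 * 128)

    def test_label_is_second_2_of_window(self):
        segs = make_ucddb_windows(self._record(100))
        # window starting at second s covers [s, s+11); its 2nd second is s+1
        assert segs.labels[19] == 1  # second 20 is apneic
        assert segs.labels[18] == 0
        assert segs.labels[38] == 1
        assert segs.labels[39] == 0

    def test_too_short_recording_rejected(self):
        rec = ECGRecord(np.zeros(5 * 128), 128.0,
                        second_labels=np.zeros(5, dtype=int))
        with pytest.raises(ValueError):
            make_ucddb_windows(rec)
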