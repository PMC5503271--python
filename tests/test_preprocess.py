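import numpy as np
import pytest

from emgknee import (
    EmgRecording,
    FilterSpec,
    SegmentationSpec,
    SynthConfig,
    detect_onset_zc,
    generate_recording,
    highpass,
    segment_trials,
)
from emgknee.errors import OnsetNotFoundError, ParameterError


def make_recording(emg, angle=None, **kw):
    emg = np.asarray(emg, float)
    angle = np.zeros_like(emg) if angle is None else np.asarray(angle, float)
    return EmgRecording(emg=emg, angle=angle, fs=1000.0, **kw)


def middle(x):
    n = len(x)
    return x[n // 3: 2 * n // 3]


class TestHighpass:
    def test_dc_rejection(self):
        rec = make_recording(np.full(2000, 5.0))
        out = highpass(rec)
        assert np.max(np.abs(middle(out.emg))) < 1e-6
        np.testing.assert_array_equal(out.angle, rec.angle)

    def test_passband_100hz_preserved(self):
        t = np.arange(4000) / 1000.0
        rec = make_recording(np.sin(2 * np.pi * 100 * t))
        out = highpass(rec)
        in_amp = np.sqrt(np.mean(middle(rec.emg) ** 2))
        out_amp = np.sqrt(np.mean(middle(out.emg) ** 2))
        assert out_amp == pytest.approx(in_amp, rel=0.01)

    def test_stopband_5hz_attenuated(self):
        t = np.arange(8000) / 1000.0
        rec = make_recording(np.sin(2 * np.pi * 5 * t))
        out = highpass(rec)
        ratio = np.sqrt(np.mean(middle(out.emg) ** 2) / np.mean(middle(rec.emg) ** 2))
        assert 20 * np.log10(1 / ratio) >= 20.0  # ≥ 20 dB down

    def test_cutoff_above_nyquist_rejected(self):
        rec = make_recording(np.zeros(100))
        with pytest.raises(ParameterError):
            highpass(rec, FilterSpec(cutoff_hz=600.0))

    def test_same_length_output(self):
        rec = make_recording(np.random.default_rng(0).normal(size=3333))
        assert highpass(rec).n_samples == 3333


class TestSegmentation:
    def test_standing_sitting_recovery(self):
        rec, manifest = generate_recording(SynthConfig(seed=4), "standing-sitting")
        segs = segment_trials(highpass(rec))
        assert len(segs) == 10
        labels = [s.label for s in segs]
        assert labels.count("standing") == 5 and labels.count("sitting") == 5
        for seg, row in zip(segs, manifest):
            assert seg.label == row["label"]
            assert abs(seg.start_idx - row["start_idx"]) <= 50  # ±50 ms at 1 kHz
            assert abs(seg.end_idx - row["end_idx"]) <= 50

    def test_walking_recovery(self):
        rec, manifest = generate_recording(SynthConfig(seed=4), "walking", n_cycles=9)
        segs = segment_trials(highpass(rec))
        labels = [s.label for s in segs]
        assert labels.count("stance") == 9 and labels.count("swing") == 9
        for seg, row in zip(segs, manifest):
            assert seg.label == row["label"]
            assert abs(seg.start_idx - row["start_idx"]) <= 50
            assert abs(seg.end_idx - row["end_idx"]) <= 50

    def test_flat_angle_gives_empty_list(self):
        rec = make_recording(np.random.default_rng(1).normal(size=5000),
                             session="walking")
        assert segment_trials(rec) == []

    def test_segments_disjoint_and_inside_recording(self):
        rec, _ = generate_recording(SynthConfig(seed=9), "walking", n_cycles=6)
        segs = segment_trials(highpass(rec))
        assert segs
        prev_end = 0
        for s in segs:
            assert 0 <= s.start_idx < s.end_idx <= rec.n_samples
            assert s.start_idx >= prev_end
            prev_end = s.end_idx

    def test_unknown_session_rejected(self):
        rec = make_recording(np.zeros(100))
        rec.session = "hopping"
        from emgknee.errors import LabelingError
        with pytest.raises(LabelingError):
            segment_trials(rec)

    def test_duration_bounds_validated(self):
        with pytest.raises(ParameterError):
            SegmentationSpec(min_duration_ms=500, max_duration_ms=400)


class TestOnsetDetection:
    def burst_signal(self, start, n=2000, rng=None):
        rng = rng or np.random.default_rng(7)
        x = np.zeros(n)
        x[start:] = rng.normal(size=n - start)
        return x

    def test_onset_after_tone_near_burst(self):
        x = self.burst_signal(500)
        onset = detect_onset_zc(x, tone_index=400, fs=1000.0)
        assert 450 <= onset <= 550

    def test_all_zero_signal(self):
        with pytest.raises(OnsetNotFoundError):
            detect_onset_zc(np.zeros(3000), tone_index=400)

    def test_burst_before_tone_only(self):
        rng = np.random.default_rng(7)
        x = np.zeros(3000)
        x[100:300] = rng.normal(size=200)
        with pytest.raises(OnsetNotFoundError):
            detect_onset_zc(x, tone_index=500)
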