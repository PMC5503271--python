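"""High-pass filtering and goniometry-guided trial segmentation.

Raw surface EMG carries motion-artifact and baseline drift below ~20 Hz, so
recordings are first passed through a 20 Hz Butterworth high-pass filter.
The filter is applied forward–backward (zero-phase) by default so that
filtering does not shift burst onsets relative to the synchronized knee
angle trace used for segmentation.

Segmentation follows the goniometer: a trial is a contiguous excursion of
the knee angle above a threshold, with its boundaries refined outward to
where the angle falls back to a small floor. Trials are labelled
kinematically — in a standing-sitting session by the depth of the flexion
peak (the standing leg-lift flexes the knee further than the seated leg
extension), in a walking session by whether the excursion is the cycle's
flexion peak (swing) or the shallower load-bearing bump (stance).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import (
    DomainError,
    LabelingError,
    OnsetNotFoundError,
    ParameterError,
    ValidationError,
)
from .features_time import ZcSpec
from .types import EmgRecording, MIN_SEGMENT_SAMPLES, MotionSegment

logger = logging.getLogger("emgknee")


@dataclass
class FilterSpec:
    """Butterworth high-pass: 20 Hz cutoff, order 4, zero-phase by default."""

    kind: str = "butterworth-highpass"
    cutoff_hz: float = 20.0
    order: int = 4
    zero_phase: bool = True

    def __post_init__(self):
        if self.cutoff_hz <= 0:
            raise ParameterError(f"cutoff must be positive, got {self.cutoff_hz}")
        if self.order < 1:
            raise ParameterError(f"order must be ≥ 1, got {self.order}")


@dataclass
class SegmentationSpec:
    """Goniometry segmentation parameters.

    ``angle_threshold_deg`` detects an excursion; ``boundary_floor_deg``
    refines its edges outward to near-rest angle. A standing-sitting trial
    whose peak flexion reaches ``standing_peak_threshold_deg`` is labelled
    standing, otherwise sitting; a walking excursion peaking at
    ``swing_peak_threshold_deg`` or more is the swing phase, otherwise
    stance.
    """

    angle_threshold_deg: float = 10.0
    boundary_floor_deg: float = 1.0
    min_duration_ms: float = 500.0
    max_duration_ms: float = 5000.0
    use_tone: bool = True
    tone_horizon_ms: float = 4000.0
    standing_peak_threshold_deg: float = 55.0
    swing_peak_threshold_deg: float = 40.0
    zc_onset_threshold: float = 3.0

    def __post_init__(self):
        if not (0 < self.min_duration_ms < self.max_duration_ms):
            raise ParameterError(
                "duration bounds must satisfy 0 < min < max, got "
                f"[{self.min_duration_ms}, {self.max_duration_ms}]"
            )


def highpass(recording: EmgRecording, spec: FilterSpec | None = None) -> EmgRecording:
    """High-pass filter the EMG channel; the angle channel is untouched."""
    spec = spec or FilterSpec()
    nyq = recording.fs / 2.0
    if spec.cutoff_hz >= nyq:
        raise ParameterError(
            f"cutoff {spec.cutoff_hz} Hz is at or above Nyquist ({nyq} Hz)"
        )
    sos = signal.butter(spec.order, spec.cutoff_hz, btype="highpass",
                        fs=recording.fs, output="sos")
    if spec.zero_phase:
        emg = signal.sosfiltfilt(sos, recording.emg)
    else:
        emg = signal.sosfilt(sos, recording.emg)
    return EmgRecording(
        emg=emg, angle=recording.angle.copy(), fs=recording.fs,
        tone_onsets=recording.tone_onsets, subject_id=recording.subject_id,
        session=recording.session,
    )


def _excursions(angle: np.ndarray, threshold: float, floor: float) -> list[tuple[int, int]]:
    """Contiguous angle excursions above ``threshold``, edges extended
    outward to where the angle drops below ``floor``. Half-open [start, end)."""
    above = angle > threshold
    if not above.any():
        return []
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = ([0] if above[0] else []) + [int(e) + 1 for e in edges if not above[e]]
    ends = [int(e) + 1 for e in edges if above[e]] + ([angle.size] if above[-1] else [])
    regions = []
    prev_end = 0
    for s, e in zip(starts, ends):
        while s > prev_end and angle[s - 1] >= floor:
            s -= 1
        while e < angle.size and angle[e] >= floor:
            e += 1
        # never overlap the previous excursion; ties go to the earlier one
        s = max(s, prev_end)
        if e > s:
            regions.append((s, e))
            prev_end = e
    return regions


def segment_trials(
    recording: EmgRecording, spec: SegmentationSpec | None = None
) -> list[MotionSegment]:
    """Cut a filtered recording into labelled per-trial motion segments."""
    spec = spec or SegmentationSpec()
    if recording.session not in ("standing-sitting", "walking"):
        raise LabelingError(f"unknown session label {recording.session!r}")
    if recording.session == "standing-sitting" and spec.use_tone and not recording.tone_onsets:
        raise ValidationError("standing-sitting segmentation with use_tone requires tone markers")

    fs = recording.fs
    regions = _excursions(recording.angle, spec.angle_threshold_deg, spec.boundary_floor_deg)
    if not regions:
        logger.warning(
            "no angle excursion above %.1f deg in %s recording; nothing segmented",
            spec.angle_threshold_deg, recording.session,
        )
        return []

    min_n = max(int(round(spec.min_duration_ms * fs / 1000.0)), MIN_SEGMENT_SAMPLES)
    max_n = int(round(spec.max_duration_ms * fs / 1000.0))
    horizon = int(round(spec.tone_horizon_ms * fs / 1000.0))

    segments: list[MotionSegment] = []
    for s, e in regions:
        if not (min_n <= e - s <= max_n):
            continue
        if recording.session == "standing-sitting" and spec.use_tone:
            # a trial must follow a pacing tone within the horizon
            preceding = [t for t in recording.tone_onsets if t <= s]
            if not preceding or s - preceding[-1] > horizon:
                continue
        peak = float(recording.angle[s:e].max())
        if recording.session == "standing-sitting":
            label = "standing" if peak >= spec.standing_peak_threshold_deg else "sitting"
        else:
            label = "swing" if peak >= spec.swing_peak_threshold_deg else "stance"
        segments.append(
            MotionSegment(
                samples=recording.emg[s:e],
                label=label,
                subject_id=recording.subject_id,
                segment_index=len(segments),
                start_idx=int(s),
                end_idx=int(e),
            )
        )
    return segments


def detect_onset_zc(
    samples,
    tone_index: int,
    fs: float = 1000.0,
    threshold: float = 3.0,
    zc_spec: ZcSpec | None = None,
    window_ms: float = 100.0,
    baseline_ms: float = 500.0,
    horizon_ms: float = 2000.0,
    min_crossings: int = 5,
) -> int:
    """Detect movement onset after a pacing tone from the zero-crossing rate.

    The gated zero-crossing rate is computed in a sliding window centred on
    each sample; the onset is the first index at or after ``tone_index``
    whose rate exceeds ``threshold`` times the mean rate over the
    ``baseline_ms`` preceding the tone (and an absolute floor of
    ``min_crossings`` per window, so a silent baseline cannot trigger on
    nothing).
    """
    zc_spec = zc_spec or ZcSpec()
    x = np.asarray(samples, dtype=float)
    if threshold < 0:
        raise ParameterError("threshold factor must be ≥ 0")
    if x.size < 2:
        raise DomainError("need at least two samples")
    w = max(int(round(window_ms * fs / 1000.0)), 2)
    cross = ((x[:-1] * x[1:] < 0) & (np.abs(x[:-1] - x[1:]) >= zc_spec.threshold)).astype(float)
    # rate[i] = crossings in the window centred on sample i
    half = w // 2
    csum = np.concatenate(([0.0], np.cumsum(cross)))
    idx = np.arange(x.size)
    lo = np.clip(idx - half, 0, cross.size)
    hi = np.clip(idx + half, 0, cross.size)
    rate = csum[hi] - csum[lo]

    b0 = max(int(tone_index - baseline_ms * fs / 1000.0), 0)
    baseline = float(rate[b0:tone_index].mean()) if tone_index > b0 else 0.0
    required = max(threshold * baseline, float(min_crossings))

    end = min(int(tone_index + horizon_ms * fs / 1000.0), x.size)
    for i in range(int(tone_index), end):
        if rate[i] >= required:
            return i
    raise OnsetNotFoundError(
        f"no onset within {horizon_ms:.0f} ms after tone at sample {tone_index}"
    )
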