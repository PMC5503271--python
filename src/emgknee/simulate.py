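"""Seeded synthetic generator for single-channel knee-exercise EMG.

Surface EMG recorded during movement is well approximated, for pipeline
testing purposes, as amplitude-modulated band-limited Gaussian noise: the
interference pattern of many motor units has a roughly Gaussian amplitude
distribution with a class- and muscle-dependent spectral shape inside the
physiological 10–500 Hz band. Each motion class here carries its own
spectral band, modulation envelope, amplitude and knee-angle profile:

* standing (leg lift): lower-band activity, trapezoidal flex-hold-extend
  envelope, deep knee flexion;
* sitting (seated leg extension): low-mid band, trapezoidal envelope,
  shallower angle excursion;
* stance phase of gait: mid-high band, double-burst envelope
  (loading response and push-off), shallow load-bearing knee bump;
* swing phase of gait: high band, nearly flat envelope, deep flexion peak.

Everything is deterministic under a seed at every granularity. Default
trial counts are 40 standing, 40 sitting, 90 stance, 90 swing (260 total),
spread round-robin over 14 subject labels with a per-subject gain factor
and a per-segment gain jitter.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import ParameterError
from .types import Dataset, EmgRecording, MotionSegment

DEFAULT_COUNTS = {"standing": 40, "sitting": 40, "swing": 90, "stance": 90}


@dataclass
class MotionClassModel:
    """Generative signature of one motion class."""

    name: str
    band_hz: tuple[float, float]
    envelope: str  # "trapezoid" | "double-burst" | "low-flat"
    amplitude_uv: float
    duration_ms: float
    peak_angle_deg: float

    def __post_init__(self):
        low, high = self.band_hz
        if not (10.0 <= low < high <= 500.0):
            raise ParameterError(
                f"band {self.band_hz} must satisfy 10 ≤ low < high ≤ 500 Hz"
            )
        if self.amplitude_uv < 0:
            raise ParameterError("amplitude must be non-negative")
        if self.envelope not in ("trapezoid", "double-burst", "low-flat"):
            raise ParameterError(f"unknown envelope {self.envelope!r}")


def default_class_models() -> dict[str, MotionClassModel]:
    """Default class signatures: spectrally staggered but overlapping bands,
    gait phases stronger and faster than the slow volitional motions."""
    return {
        "standing": MotionClassModel("standing", (30.0, 120.0), "trapezoid", 12.0, 2000.0, 70.0),
        "sitting": MotionClassModel("sitting", (60.0, 200.0), "trapezoid", 14.0, 2000.0, 40.0),
        "stance": MotionClassModel("stance", (100.0, 320.0), "double-burst", 22.0, 840.0, 18.0),
        "swing": MotionClassModel("swing", (160.0, 450.0), "low-flat", 18.0, 560.0, 60.0),
    }


@dataclass
class SynthConfig:
    """Generator configuration; defaults reproduce the study conditions."""

    fs: float = 1000.0
    counts: dict = field(default_factory=lambda: dict(DEFAULT_COUNTS))
    class_models: dict = field(default_factory=default_class_models)
    noise_floor_uv: float = 8.0
    seed: int = 0
    segment_gain_sigma: float = 0.4  # lognormal σ of per-trial gain jitter
    subject_gain_sigma: float = 0.15  # lognormal σ of per-subject gain
    n_subjects: int = 14

    def __post_init__(self):
        if any(c <= 0 for c in self.counts.values()):
            raise ParameterError("class counts must be positive")
        if self.fs <= 0:
            raise ParameterError("fs must be positive")


def _envelope(kind: str, n: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n, endpoint=False)
    if kind == "trapezoid":
        ramp = 0.25
        env = np.minimum(1.0, np.minimum(t / ramp, (1.0 - t) / ramp))
        return np.clip(env, 0.0, 1.0)
    if kind == "double-burst":
        b1 = np.exp(-0.5 * ((t - 0.25) / 0.10) ** 2)
        b2 = 0.8 * np.exp(-0.5 * ((t - 0.72) / 0.09) ** 2)
        return 0.15 + b1 + b2
    if kind == "low-flat":
        return 0.9 + 0.1 * np.sin(np.pi * t)
    raise ParameterError(f"unknown envelope {kind!r}")


def _angle_profile(peak_deg: float, n: int, ramp: float = 0.15) -> np.ndarray:
    """Trapezoidal flexion curve: brisk rise, plateau, brisk return."""
    t = np.linspace(0.0, 1.0, n, endpoint=False)
    env = np.clip(np.minimum(t / ramp, (1.0 - t) / ramp), 0.0, 1.0)
    return peak_deg * env


def generate_segment(
    model: MotionClassModel,
    fs: float = 1000.0,
    seed: int | np.random.SeedSequence = 0,
    noise_floor_uv: float = 2.0,
    gain: float = 1.0,
    subject_id: str = "synthetic",
) -> MotionSegment:
    """One trial: envelope × band-shaped Gaussian noise + white noise floor."""
    low, high = model.band_hz
    if not (0 < low < high < fs / 2):
        raise ParameterError(
            f"band {model.band_hz} must lie inside (0, {fs / 2}) Hz at fs={fs}"
        )
    rng = np.random.default_rng(seed)
    n = int(round(model.duration_ms * fs / 1000.0))
    sos = signal.butter(4, (low, high), btype="bandpass", fs=fs, output="sos")
    shaped = signal.sosfiltfilt(sos, rng.standard_normal(n))
    rms = np.sqrt(np.mean(shaped**2))
    if rms > 0:
        shaped /= rms
    env = _envelope(model.envelope, n)
    x = gain * model.amplitude_uv * env * shaped
    x = x + noise_floor_uv * rng.standard_normal(n)
    return MotionSegment(samples=x, label=model.name, subject_id=subject_id)


def generate_dataset(cfg: SynthConfig | None = None) -> Dataset:
    """A labelled segment dataset at the configured per-class trial counts."""
    cfg = cfg or SynthConfig()
    root = np.random.SeedSequence(cfg.seed)
    gain_rng = np.random.default_rng(root.spawn(1)[0])
    subject_gains = np.exp(cfg.subject_gain_sigma * gain_rng.standard_normal(cfg.n_subjects))
    total = sum(cfg.counts.values())
    seg_seeds = root.spawn(total + 1)[1:]
    items = []
    k = 0
    for name in ("standing", "sitting", "stance", "swing"):
        if name not in cfg.counts:
            continue
        model = cfg.class_models[name]
        for _ in range(cfg.counts[name]):
            subj = k % cfg.n_subjects
            jitter_rng = np.random.default_rng(seg_seeds[k].spawn(1)[0])
            gain = subject_gains[subj] * float(
                np.exp(cfg.segment_gain_sigma * jitter_rng.standard_normal())
            )
            seg = generate_segment(
                model, fs=cfg.fs, seed=seg_seeds[k],
                noise_floor_uv=cfg.noise_floor_uv, gain=gain,
                subject_id=f"s{subj + 1:02d}",
            )
            seg.segment_index = k
            items.append(seg)
            k += 1
    return Dataset(items=items)


def generate_recording(
    cfg: SynthConfig | None = None,
    session: str = "standing-sitting",
    n_repeats: int = 5,
    n_cycles: int = 9,
    subject_id: str = "s01",
    seed: int | None = None,
) -> tuple[EmgRecording, list[dict]]:
    """A continuous session recording plus its ground-truth trial manifest.

    Standing-sitting: ``n_repeats`` trials per motion, alternating, each
    paced by a tone one second before movement and followed by a rest gap.
    Walking: ``n_cycles`` gait cycles of contiguous stance+swing phases,
    one tone at the start of the bout.

    Manifest rows: ``{"label", "start_idx", "end_idx", "subject"}`` with
    half-open sample intervals of the true motion phases.
    """
    cfg = cfg or SynthConfig()
    if seed is None:
        seed = cfg.seed
    root = np.random.SeedSequence(entropy=seed, spawn_key=(1,))
    fs = cfg.fs

    if session == "standing-sitting":
        order = ["standing", "sitting"] * n_repeats
        t = int(1.0 * fs)  # lead-in rest
        tones = []
        manifest = []
        for label in order:
            model = cfg.class_models[label]
            tones.append(t)
            t += int(1.0 * fs)  # one-second tone-paced interval
            n = int(round(model.duration_ms * fs / 1000.0))
            manifest.append({"label": label, "start_idx": t, "end_idx": t + n,
                             "subject": subject_id})
            t += n
            t += int(5.0 * fs)  # rest interval
        total_n = t
    elif session == "walking":
        t = int(1.0 * fs)
        tones = [t]
        t += int(1.0 * fs)
        manifest = []
        for _ in range(n_cycles):
            for label in ("stance", "swing"):
                model = cfg.class_models[label]
                n = int(round(model.duration_ms * fs / 1000.0))
                manifest.append({"label": label, "start_idx": t, "end_idx": t + n,
                                 "subject": subject_id})
                t += n
        t += int(1.0 * fs)
        total_n = t
    else:
        raise ParameterError(f"unknown session {session!r}")

    rng = np.random.default_rng(root.spawn(1)[0])
    emg = cfg.noise_floor_uv * rng.standard_normal(total_n)
    angle = np.zeros(total_n)
    trial_seeds = root.spawn(len(manifest))
    for row, ss in zip(manifest, trial_seeds):
        model = cfg.class_models[row["label"]]
        s, e = row["start_idx"], row["end_idx"]
        seg = generate_segment(model, fs=fs, seed=ss, noise_floor_uv=0.0,
                               subject_id=subject_id)
        emg[s:e] += seg.samples
        angle[s:e] = _angle_profile(model.peak_angle_deg, e - s)
    rec = EmgRecording(
        emg=emg, angle=angle, fs=fs, tone_onsets=tuple(tones),
        subject_id=subject_id, session=session,
    )
    return rec, manifest
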