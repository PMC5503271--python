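"""Core data model: recordings, segments, feature vectors and datasets.

A recording is one continuous acquisition of a single surface-EMG channel
over the vastus medialis together with a synchronized goniometer (knee
angle) channel and auditory-tone onset markers. Segments are the labelled
per-trial windows cut from a recording; feature vectors are what the
classifier consumes.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError

#: The four lower-limb motion classes, in canonical order.
MOTION_CLASSES = ("standing", "sitting", "stance", "swing")

#: Shortest segment accepted for feature extraction: 2**6 samples is the
#: shortest dyadic length whose five-level decomposition has a non-empty
#: level-5 approximation.
MIN_SEGMENT_SAMPLES = 64

#: All feature names the extraction layer understands.
KNOWN_FEATURES = (
    "MAV", "RMS", "iEMG", "ZC", "MNF", "MDF",
    "cD1", "cD2", "cD3", "cD4", "cD5", "cA5",
)


@dataclass
class EmgRecording:
    """Raw single-channel EMG plus knee angle at a shared sampling rate.

    Parameters
    ----------
    emg : array-like
        EMG samples, µV scale (units carried as metadata only).
    angle : array-like
        Knee flexion angle in degrees, same length as ``emg``.
    fs : float
        Sampling rate in Hz (default 1000).
    tone_onsets : sequence of int
        Sample indices of auditory tone onsets, strictly increasing.
    subject_id : str
        Subject label.
    session : str
        ``"standing-sitting"`` or ``"walking"``.
    """

    emg: np.ndarray
    angle: np.ndarray
    fs: float = 1000.0
    tone_onsets: tuple[int, ...] = ()
    subject_id: str = "unknown"
    session: str = "standing-sitting"

    def __post_init__(self):
        self.emg = np.asarray(self.emg, dtype=float)
        self.angle = np.asarray(self.angle, dtype=float)
        if self.emg.size == 0:
            raise ValidationError("recording must contain at least one sample")
        if self.emg.shape != self.angle.shape:
            raise ValidationError(
                f"emg and angle lengths differ: {self.emg.size} vs {self.angle.size}"
            )
        if not self.fs > 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        onsets = tuple(int(t) for t in self.tone_onsets)
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValidationError("tone_onsets must be strictly increasing")
        if onsets and (onsets[0] < 0 or onsets[-1] >= self.emg.size):
            raise ValidationError("tone_onsets must lie inside the recording")
        self.tone_onsets = onsets

    @property
    def n_samples(self) -> int:
        return int(self.emg.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class MotionSegment:
    """One trial's EMG window with its motion label.

    ``samples`` is the potential sequence x_k, k = 1..N, for a single
    segmented trial.
    """

    samples: np.ndarray
    label: str
    subject_id: str = "unknown"
    segment_index: int = 0
    #: position within the source recording, when cut from one (else None)
    start_idx: int | None = None
    end_idx: int | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size < MIN_SEGMENT_SAMPLES:
            raise ValidationError(
                f"segment has {self.samples.size} samples; at least "
                f"{MIN_SEGMENT_SAMPLES} required for five-level decomposition"
            )
        if self.label not in MOTION_CLASSES:
            raise ValidationError(
                f"unknown motion label {self.label!r}; expected one of {MOTION_CLASSES}"
            )

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)


@dataclass
class FeatureVector:
    """Named feature values for one segment."""

    names: tuple[str, ...]
    values: np.ndarray
    label: str
    subject_id: str = "unknown"

    def __post_init__(self):
        self.names = tuple(self.names)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != self.values.size:
            raise ValidationError(
                f"{len(self.names)} names but {self.values.size} values"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("feature values must all be finite")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))


@dataclass
class Dataset:
    """A collection of segments or feature vectors grouped by class."""

    items: list = field(default_factory=list)

    @property
    def labels(self) -> list[str]:
        return [it.label for it in self.items]

    @property
    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for lab in self.labels:
            counts[lab] = counts.get(lab, 0) + 1
        return counts

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    def __getitem__(self, i):
        return self.items[i]

    def require_all_classes(self) -> None:
        missing = [c for c in MOTION_CLASSES if c not in self.class_counts]
        if missing:
            raise ValidationError(f"classes absent from dataset: {missing}")


def feature_matrix(
    vectors: Sequence[FeatureVector] | Dataset,
    names: Sequence[str] | None = None,
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """Stack feature vectors into (X, y, names).

    All vectors must share one name tuple; ``names`` optionally selects and
    reorders a subset of columns.
    """
    items = list(vectors)
    if not items:
        raise ValidationError("no feature vectors given")
    base = items[0].names
    for v in items[1:]:
        if v.names != base:
            raise ValidationError(
                f"inconsistent feature names: {v.names} vs {base}"
            )
    if names is None:
        names = base
    idx = []
    for n in names:
        if n not in base:
            raise ValidationError(f"feature {n!r} not present in vectors")
        idx.append(base.index(n))
    X = np.array([v.values[idx] for v in items], dtype=float)
    y = np.array([v.label for v in items])
    return X, y, tuple(names)
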