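"""Time-domain EMG features: MAV, RMS, iEMG and threshold-gated zero crossings.

For a segment x_1..x_N:

    MAV  = (1/N) Σ |x_k|
    RMS  = sqrt((1/N) Σ x_k²)
    iEMG = Σ |x_k|                      (so iEMG = N·MAV)
    ZC   = #{ k : x_k·x_{k+1} < 0  and  |x_k − x_{k+1}| ≥ threshold }

The ZC gate counts a crossing only for strictly opposite signs — a sample
exactly at zero never contributes — and only when the consecutive-sample
amplitude jump clears the threshold, which suppresses noise-floor dither.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, ParameterError
from .types import MotionSegment


@dataclass
class ZcSpec:
    """Zero-crossing gate: minimum consecutive-sample amplitude difference (µV)."""

    threshold: float = 0.0

    def __post_init__(self):
        if self.threshold < 0:
            raise ParameterError(f"ZC threshold must be ≥ 0, got {self.threshold}")


def _samples(segment) -> np.ndarray:
    x = segment.samples if isinstance(segment, MotionSegment) else np.asarray(segment, float)
    if x.size == 0:
        raise DomainError("empty segment")
    return x


def mav(segment) -> float:
    """Mean absolute value of the segment."""
    x = _samples(segment)
    return float(np.mean(np.abs(x)))


def rms(segment) -> float:
    """Root-mean-square amplitude of the segment."""
    x = _samples(segment)
    return float(np.sqrt(np.mean(x * x)))


def iemg(segment) -> float:
    """Integrated EMG: the summed absolute value over the segment."""
    x = _samples(segment)
    return float(np.sum(np.abs(x)))


def zero_crossings(segment, spec: ZcSpec | None = None) -> int:
    """Count threshold-gated sign changes between consecutive samples."""
    spec = spec or ZcSpec()
    x = _samples(segment)
    if x.size < 2:
        raise DomainError("zero crossings need at least two samples")
    prod = x[:-1] * x[1:]
    jump = np.abs(x[:-1] - x[1:])
    return int(np.count_nonzero((prod < 0) & (jump >= spec.threshold)))
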