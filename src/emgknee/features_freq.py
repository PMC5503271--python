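"""Frequency-domain EMG features: Welch PSD, mean and median frequency.

MNF is the power-weighted mean frequency, Σ P_j f_j / Σ P_j. MDF is the
frequency at which the spectrum splits into two equal-power halves,
resolved discretely: the frequency of the first bin where the cumulative
power exceeds half the total. Both are invariant to positive rescaling of
the power vector, so the PSD normalisation convention does not matter.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import DomainError, ParameterError
from .types import MotionSegment


@dataclass
class WelchSpec:
    """Welch averaged-periodogram settings: Hamming window, 256-sample
    sub-windows with 50% overlap by default."""

    window: str = "hamming"
    nperseg: int = 256
    overlap_fraction: float = 0.5

    def __post_init__(self):
        if not (0 <= self.overlap_fraction < 1):
            raise ParameterError(
                f"overlap_fraction must be in [0, 1), got {self.overlap_fraction}"
            )
        if self.nperseg < 2:
            raise ParameterError(f"nperseg must be ≥ 2, got {self.nperseg}")


@dataclass
class SpectrumEstimate:
    """One-sided PSD for a single segment: frequency bins and power values."""

    freqs: np.ndarray
    power: np.ndarray
    segment_index: int = 0

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.size != self.power.size:
            raise DomainError("freqs and power must have equal lengths")
        if self.freqs.size == 0:
            raise DomainError("empty spectrum")
        if np.any(np.diff(self.freqs) <= 0):
            raise DomainError("frequencies must be strictly increasing")
        if np.any(self.power < 0):
            raise DomainError("power values must be non-negative")

    @property
    def n_bins(self) -> int:
        return int(self.freqs.size)


def welch_psd(segment, fs: float, spec: WelchSpec | None = None) -> SpectrumEstimate:
    """One-sided Welch PSD estimate for a segment (density scaling)."""
    spec = spec or WelchSpec()
    x = segment.samples if isinstance(segment, MotionSegment) else np.asarray(segment, float)
    if x.size < spec.nperseg:
        raise ParameterError(
            f"segment of {x.size} samples is shorter than nperseg={spec.nperseg}"
        )
    noverlap = int(round(spec.overlap_fraction * spec.nperseg))
    freqs, power = signal.welch(
        x, fs=fs, window=spec.window, nperseg=spec.nperseg,
        noverlap=noverlap, detrend=False, scaling="density",
    )
    idx = getattr(segment, "segment_index", 0)
    return SpectrumEstimate(freqs=freqs, power=power, segment_index=idx)


def _checked_power(spectrum: SpectrumEstimate) -> tuple[np.ndarray, np.ndarray, float]:
    total = float(spectrum.power.sum())
    if total <= 0:
        raise DomainError("spectrum has no power; MNF/MDF undefined")
    return spectrum.freqs, spectrum.power, total


def mnf(spectrum: SpectrumEstimate) -> float:
    """Mean (power-weighted average) frequency in Hz."""
    freqs, power, total = _checked_power(spectrum)
    return float(np.dot(power, freqs) / total)


def mdf(spectrum: SpectrumEstimate) -> float:
    """Median frequency in Hz: first bin whose cumulative power exceeds half
    the total."""
    freqs, power, total = _checked_power(spectrum)
    cum = np.cumsum(power)
    j = int(np.argmax(cum > 0.5 * total))
    return float(freqs[j])
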