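"""Time-frequency features: five-level db4 wavelet decomposition compressed
by singular value decomposition.

A five-level Daubechies-4 decomposition splits a 1 kHz EMG segment into six
coefficient sequences covering dyadic bands: details cD1 (250–500 Hz) down
to cD5 (15.6–31.25 Hz) and the approximation cA5 (0–15.6 Hz). Each
sequence is then compressed to a single number by SVD. Two compression
modes are provided:

``per-band`` (default)
    Each coefficient sequence is viewed as a 1×L matrix; its only nonzero
    singular value is its Euclidean norm. This retains exactly one
    parameter per band and yields the six named features cD1..cD5, cA5 in
    fixed band order. With a periodized (orthogonal) transform the squared
    per-band values sum to the segment's energy.

``stacked``
    The six sequences are zero-padded to a common length, stacked into a
    6×L matrix, and that matrix's six singular values are returned in
    non-increasing order. Provided for sensitivity analysis; the singular
    values no longer align with individual bands.

The decomposition uses periodized extension so the transform is orthogonal;
segments are zero-padded to the next multiple of 2^levels, which leaves
signal energy unchanged and makes energy conservation exact at any length.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt

from .errors import DomainError, ParameterError
from .types import MIN_SEGMENT_SAMPLES, MotionSegment

WTSVD_FEATURE_NAMES = ("cD1", "cD2", "cD3", "cD4", "cD5", "cA5")


@dataclass
class WaveletSpec:
    """Five-level Daubechies-4 decomposition with periodized extension."""

    wavelet: str = "db4"
    levels: int = 5
    extension_mode: str = "periodization"

    def __post_init__(self):
        if self.levels != 5:
            raise ParameterError("the feature model is defined for exactly 5 levels")


@dataclass
class WaveletBands:
    """The six coefficient sequences with nominal frequency-band annotations.

    ``nominal_bands`` maps each component to its fs-derived dyadic band in
    Hz: cDl ↔ (fs/2^(l+1), fs/2^l), cA5 ↔ (0, fs/64).
    """

    cD1: np.ndarray
    cD2: np.ndarray
    cD3: np.ndarray
    cD4: np.ndarray
    cD5: np.ndarray
    cA5: np.ndarray
    nominal_bands: dict = field(default_factory=dict)

    def components(self) -> list[tuple[str, np.ndarray]]:
        return [(n, getattr(self, n)) for n in WTSVD_FEATURE_NAMES]

    def total_energy(self) -> float:
        return float(sum(np.sum(c * c) for _, c in self.components()))


@dataclass
class SvdFeatures:
    """Six compressed band values in a fixed order (per-band) or sorted
    non-increasing (stacked)."""

    sigma: np.ndarray
    mode: str

    def __post_init__(self):
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.sigma.size != 6:
            raise DomainError("expected exactly six singular values")
        if np.any(self.sigma < 0):
            raise DomainError("singular values must be non-negative")


def nominal_bands(fs: float, levels: int = 5) -> dict[str, tuple[float, float]]:
    """fs-derived dyadic band edges for each wavelet component."""
    bands = {
        f"cD{l}": (fs / 2 ** (l + 1), fs / 2 ** l) for l in range(1, levels + 1)
    }
    bands[f"cA{levels}"] = (0.0, fs / 2 ** (levels + 1))
    return bands


def wavelet_decompose(
    segment, fs: float = 1000.0, spec: WaveletSpec | None = None
) -> WaveletBands:
    """Five-level db4 decomposition of a segment into six band sequences."""
    spec = spec or WaveletSpec()
    x = segment.samples if isinstance(segment, MotionSegment) else np.asarray(segment, float)
    if x.size < MIN_SEGMENT_SAMPLES:
        raise DomainError(
            f"segment of {x.size} samples is too short; need ≥ {MIN_SEGMENT_SAMPLES}"
        )
    block = 2 ** spec.levels
    if spec.extension_mode == "periodization" and x.size % block:
        padded = np.zeros(int(np.ceil(x.size / block)) * block)
        padded[: x.size] = x
        x = padded
    with warnings.catch_warnings():
        # pywt warns about boundary effects at the shortest admissible lengths
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(x, spec.wavelet, mode=spec.extension_mode, level=spec.levels)
    cA5, cD5, cD4, cD3, cD2, cD1 = coeffs
    return WaveletBands(
        cD1=cD1, cD2=cD2, cD3=cD3, cD4=cD4, cD5=cD5, cA5=cA5,
        nominal_bands=nominal_bands(fs, spec.levels),
    )


def svd_singular_values(matrix) -> np.ndarray:
    """Singular values of a matrix, non-increasing.

    These equal the square roots of the eigenvalues of AᵀA; their count is
    min(rows, cols).
    """
    A = np.atleast_2d(np.asarray(matrix, dtype=float))
    if A.size == 0:
        raise DomainError("empty matrix")
    return np.linalg.svd(A, compute_uv=False)


def wtsvd_features(bands: WaveletBands, mode: str = "per-band") -> SvdFeatures:
    """Compress the six coefficient sequences to six singular values."""
    if mode == "per-band":
        sigma = np.array(
            [svd_singular_values(c[np.newaxis, :])[0] for _, c in bands.components()]
        )
    elif mode == "stacked":
        seqs = [c for _, c in bands.components()]
        width = max(c.size for c in seqs)
        M = np.zeros((6, width))
        for i, c in enumerate(seqs):
            M[i, : c.size] = c
        sigma = svd_singular_values(M)
    else:
        raise ParameterError(f"unknown SVD compression mode {mode!r}")
    return SvdFeatures(sigma=sigma, mode=mode)
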