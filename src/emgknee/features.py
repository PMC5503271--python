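"""Feature-extraction dispatch: turn labelled segments into feature vectors.

The five standard feature-set configurations compared in the evaluation are
registered in :data:`FEATURE_SETS`:

* ``time``      — MAV + RMS + iEMG + ZC
* ``freq``      — MNF + MDF
* ``timefreq``  — the union of the two above
* ``wtsvd``     — cD1 + cD2 + cD3 + cD4 + cD5 + cA5 (per-band SVD values)
* ``all``       — everything combined
"""
from __future__ import annotations

from typing import Sequence

from .errors import ConfigurationError
from .features_freq import WelchSpec, mdf, mnf, welch_psd
from .features_time import ZcSpec, iemg, mav, rms, zero_crossings
from .features_wtsvd import (
    WTSVD_FEATURE_NAMES,
    WaveletSpec,
    wavelet_decompose,
    wtsvd_features,
)
from .types import Dataset, FeatureVector, KNOWN_FEATURES, MotionSegment

FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "time": ("MAV", "RMS", "iEMG", "ZC"),
    "freq": ("MNF", "MDF"),
    "timefreq": ("MAV", "RMS", "iEMG", "ZC", "MNF", "MDF"),
    "wtsvd": WTSVD_FEATURE_NAMES,
    "all": ("MAV", "RMS", "iEMG", "ZC", "MNF", "MDF") + WTSVD_FEATURE_NAMES,
}


def extract_features(
    segments: Sequence[MotionSegment] | Dataset,
    names: Sequence[str],
    fs: float = 1000.0,
    zc_spec: ZcSpec | None = None,
    welch_spec: WelchSpec | None = None,
    wavelet_spec: WaveletSpec | None = None,
    svd_mode: str = "per-band",
) -> list[FeatureVector]:
    """Compute the named features for every segment.

    Welch PSD and the wavelet decomposition are computed once per segment
    and shared among the features that need them.
    """
    names = tuple(names)
    unknown = [n for n in names if n not in KNOWN_FEATURES]
    if unknown:
        raise ConfigurationError(f"unknown feature name(s): {unknown}")
    need_freq = any(n in ("MNF", "MDF") for n in names)
    need_wt = any(n in WTSVD_FEATURE_NAMES for n in names)
    out = []
    for seg in segments:
        values: dict[str, float] = {}
        if "MAV" in names:
            values["MAV"] = mav(seg)
        if "RMS" in names:
            values["RMS"] = rms(seg)
        if "iEMG" in names:
            values["iEMG"] = iemg(seg)
        if "ZC" in names:
            values["ZC"] = float(zero_crossings(seg, zc_spec))
        if need_freq:
            spectrum = welch_psd(seg, fs=fs, spec=welch_spec)
            if "MNF" in names:
                values["MNF"] = mnf(spectrum)
            if "MDF" in names:
                values["MDF"] = mdf(spectrum)
        if need_wt:
            bands = wavelet_decompose(seg, fs=fs, spec=wavelet_spec)
            sv = wtsvd_features(bands, mode=svd_mode)
            for band_name, sigma in zip(WTSVD_FEATURE_NAMES, sv.sigma):
                if band_name in names:
                    values[band_name] = float(sigma)
        out.append(
            FeatureVector(
                names=names,
                values=[values[n] for n in names],
                label=seg.label,
                subject_id=seg.subject_id,
            )
        )
    return out


def feature_set_names(set_name: str) -> tuple[str, ...]:
    """Resolve a registered feature-set name to its feature tuple."""
    try:
        return FEATURE_SETS[set_name]
    except KeyError:
        raise ConfigurationError(
            f"unknown feature set {set_name!r}; known: {sorted(FEATURE_SETS)}"
        ) from None
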