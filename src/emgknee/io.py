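"""Readers and writers for recordings, segments and feature tables.

File dialect: comma-separated text with a header row. A recording file has
one sample per row (columns ``t_ms, emg_uv, angle_deg, tone``); a feature
file has one segment per row (feature columns, then ``label, subject_id``).
Values are treated as dimensionless µV-scale numbers; no unit conversion is
performed.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, ParseError, ValidationError
from .types import Dataset, EmgRecording, FeatureVector, MotionSegment

logger = logging.getLogger("emgknee")

RECORDING_COLUMNS = {"emg": "emg_uv", "angle": "angle_deg", "tone": "tone"}


def read_recording(
    path: str | Path,
    format_spec: Mapping[str, str] | None = None,
    fs: float = 1000.0,
    subject_id: str = "unknown",
    session: str = "standing-sitting",
) -> EmgRecording:
    """Read a CSV recording export into an :class:`EmgRecording`.

    ``format_spec`` maps the logical channels ``emg``, ``angle`` and
    optionally ``tone`` to column names; defaults to
    ``emg_uv/angle_deg/tone``. The tone column flags onset samples with 1.
    """
    path = Path(path)
    cols = dict(RECORDING_COLUMNS)
    if format_spec:
        cols.update(format_spec)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:  # malformed CSV structure
        raise ParseError(f"could not parse {path}: {exc}") from exc
    for logical in ("emg", "angle"):
        if cols[logical] not in df.columns:
            raise FormatError(
                f"{path} is missing required column {cols[logical]!r} ({logical})"
            )
    for logical in ("emg", "angle"):
        series = pd.to_numeric(df[cols[logical]], errors="coerce")
        bad = series.index[series.isna() & df[cols[logical]].notna()]
        if len(bad):
            raise ParseError(
                f"non-numeric value in column {cols[logical]!r} at row {bad[0]}",
                row=int(bad[0]),
            )
        if series.isna().any():
            row = int(series.index[series.isna()][0])
            raise ParseError(f"missing value in column {cols[logical]!r} at row {row}", row=row)
    emg = df[cols["emg"]].to_numpy(dtype=float)
    angle = df[cols["angle"]].to_numpy(dtype=float)
    tone_onsets: tuple[int, ...] = ()
    if cols.get("tone") in df.columns:
        tone = df[cols["tone"]].to_numpy()
        tone_onsets = tuple(int(i) for i in np.flatnonzero(tone != 0))
    return EmgRecording(
        emg=emg, angle=angle, fs=fs, tone_onsets=tone_onsets,
        subject_id=subject_id, session=session,
    )


def write_recording(recording: EmgRecording, path: str | Path) -> Path:
    """Write a recording to CSV (columns ``t_ms, emg_uv, angle_deg, tone``)."""
    path = Path(path)
    n = recording.n_samples
    tone = np.zeros(n, dtype=int)
    if recording.tone_onsets:
        tone[list(recording.tone_onsets)] = 1
    df = pd.DataFrame(
        {
            "t_ms": np.arange(n) * 1000.0 / recording.fs,
            "emg_uv": recording.emg,
            "angle_deg": recording.angle,
            "tone": tone,
        }
    )
    df.to_csv(path, index=False)
    return path


def write_features(vectors: Sequence[FeatureVector], path: str | Path) -> Path:
    """Write feature vectors to CSV: feature columns, then label, subject_id."""
    vectors = list(vectors)
    if not vectors:
        raise ValidationError("cannot write an empty feature list")
    names = vectors[0].names
    for v in vectors[1:]:
        if v.names != names:
            raise ValidationError(
                f"inconsistent feature names across vectors: {v.names} vs {names}"
            )
    path = Path(path)
    rows = [
        dict(zip(names, v.values.tolist()), label=v.label, subject_id=v.subject_id)
        for v in vectors
    ]
    pd.DataFrame(rows, columns=list(names) + ["label", "subject_id"]).to_csv(
        path, index=False
    )
    return path


def read_features(path: str | Path) -> list[FeatureVector]:
    """Read a feature CSV written by :func:`write_features`."""
    df = pd.read_csv(path)
    for col in ("label", "subject_id"):
        if col not in df.columns:
            raise FormatError(f"{path} is missing required column {col!r}")
    names = tuple(c for c in df.columns if c not in ("label", "subject_id"))
    out = []
    for _, row in df.iterrows():
        out.append(
            FeatureVector(
                names=names,
                values=row[list(names)].to_numpy(dtype=float),
                label=str(row["label"]),
                subject_id=str(row["subject_id"]),
            )
        )
    return out


def write_segments(
    segments: Sequence[MotionSegment] | Dataset,
    out_dir: str | Path,
    fs: float = 1000.0,
    manifest_name: str = "manifest.csv",
) -> Path:
    """Write one CSV per segment plus a manifest CSV.

    Manifest columns: ``file, label, subject, start_idx, end_idx`` where the
    index range is within the segment's own sample axis (0-based, inclusive
    start, exclusive end).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, seg in enumerate(segments):
        fname = f"segment_{i:04d}.csv"
        pd.DataFrame({"emg_uv": seg.samples}).to_csv(out_dir / fname, index=False)
        rows.append(
            {
                "file": fname,
                "label": seg.label,
                "subject": seg.subject_id,
                "start_idx": 0,
                "end_idx": seg.n_samples,
            }
        )
    manifest = out_dir / manifest_name
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_segments(out_dir: str | Path, manifest_name: str = "manifest.csv") -> Dataset:
    """Read back a segment directory written by :func:`write_segments`."""
    out_dir = Path(out_dir)
    manifest = pd.read_csv(out_dir / manifest_name)
    items = []
    for i, row in manifest.iterrows():
        samples = pd.read_csv(out_dir / row["file"])["emg_uv"].to_numpy(dtype=float)
        items.append(
            MotionSegment(
                samples=samples,
                label=str(row["label"]),
                subject_id=str(row["subject"]),
                segment_index=int(i),
            )
        )
    return Dataset(items=items)


def load_config(path: str | Path) -> dict:
    """Load a YAML configuration file (filter, wavelet, CV, synthesis, seed)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: top-level config must be a mapping")
    return cfg
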