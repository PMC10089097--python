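"""Recording persistence: flat binary samples + JSON sidecar manifest.

A recording is stored as a little-endian float64 matrix (all trials
concatenated along time; multi-source data stored sample-major) next to a
JSON manifest holding sampling metadata, design labels, trial offsets and
a SHA-256 checksum of the data bytes.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from .containers import TimeSeriesRecording


def _checksum(raw: bytes) -> str:
    return hashlib.sha256(raw).hexdigest()


def write_recording(rec: TimeSeriesRecording, directory, stem: str | None = None) -> Path:
    """Write data (.f64) and manifest (.json); returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if stem is None:
        stem = "_".join(
            [rec.subject_id, rec.language, rec.condition, rec.hemisphere]
        )
    data_path = directory / f"{stem}.f64"
    manifest_path = directory / f"{stem}.json"
    if manifest_path.exists():
        raise FileExistsError(f"manifest already exists: {manifest_path}")
    data = np.concatenate([t.reshape(t.shape[0], -1) for t in rec.trials], axis=0)
    raw = np.ascontiguousarray(data, dtype="<f8").tobytes()
    data_path.write_bytes(raw)
    offsets = np.cumsum([0] + [t.shape[0] for t in rec.trials[:-1]]).tolist()
    manifest = {
        "subject_id": rec.subject_id,
        "grade": rec.grade,
        "language": rec.language,
        "condition": rec.condition,
        "hemisphere": rec.hemisphere,
        "fs": rec.fs,
        "n_samples": int(data.shape[0]),
        "source_count": int(data.shape[1]),
        "trial_offsets": offsets,
        "trial_lengths": [int(t.shape[0]) for t in rec.trials],
        "data_path": data_path.name,
        "checksum": _checksum(raw),
    }
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest_path


def read_recording(manifest_path) -> TimeSeriesRecording:
    """Load a recording, verifying the checksum and trial offsets."""
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    data_path = manifest_path.parent / manifest["data_path"]
    if not data_path.exists():
        raise FileNotFoundError(f"data file missing: {data_path}")
    raw = data_path.read_bytes()
    if _checksum(raw) != manifest["checksum"]:
        raise IOError(f"checksum mismatch for {data_path}")
    n_samples = int(manifest["n_samples"])
    n_src = int(manifest["source_count"])
    expected = n_samples * n_src * 8
    if len(raw) != expected:
        raise IOError(f"truncated data: {len(raw)} bytes, expected {expected}")
    data = np.frombuffer(raw, dtype="<f8").reshape(n_samples, n_src)
    offsets = list(manifest["trial_offsets"])
    lengths = list(manifest["trial_lengths"])
    if any(o2 <= o1 for o1, o2 in zip(offsets, offsets[1:])):
        raise IOError("trial offsets must be strictly increasing")
    trials = []
    for off, length in zip(offsets, lengths):
        if off < 0 or off + length > n_samples:
            raise IOError(f"trial at offset {off} (+{length}) exceeds data length {n_samples}")
        chunk = data[off : off + length]
        trials.append(chunk[:, 0] if n_src == 1 else chunk)
    return TimeSeriesRecording(
        trials=trials,
        fs=float(manifest["fs"]),
        subject_id=manifest["subject_id"],
        grade=int(manifest["grade"]),
        language=manifest["language"],
        condition=manifest["condition"],
        hemisphere=manifest["hemisphere"],
    )


def write_cohort(recordings, directory) -> list[Path]:
    """Write every recording of a cohort; returns manifest paths."""
    return [write_recording(rec, directory) for rec in recordings]


def read_cohort(directory) -> list[TimeSeriesRecording]:
    """Load every manifest in a directory (sorted for determinism)."""
    directory = Path(directory)
    manifests = sorted(directory.glob("*.json"))
    if not manifests:
        raise FileNotFoundError(f"no manifests found in {directory}")
    return [read_recording(p) for p in manifests]
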