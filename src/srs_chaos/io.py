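"""Reading and writing datasets and feature tables.

Segments are stored as 16-bit PCM mono WAV at 16 kHz with a sidecar
``labels.csv`` (filename, subject_id, label, duration_s, seed); feature
tables as flat CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .core import SAMPLE_RATE_HZ, AudioSegment, FeatureVector

__all__ = [
    "write_wav_segment",
    "read_wav_segment",
    "write_dataset",
    "read_dataset",
    "features_to_frame",
    "write_features_csv",
    "read_features_csv",
]

_PCM_SCALE = 32767


def write_wav_segment(path: str | Path, segment: AudioSegment) -> None:
    """Write one segment as 16-bit PCM mono WAV, scaled to full range."""
    x = segment.samples
    peak = np.max(np.abs(x)) if len(x) else 0.0
    scaled = x / peak if peak > 0 else x
    pcm = np.round(scaled * (_PCM_SCALE - 1)).astype(np.int16)
    wavfile.write(str(path), SAMPLE_RATE_HZ, pcm)


def read_wav_segment(path: str | Path, label: str, subject_id: str = "s0") -> AudioSegment:
    rate, data = wavfile.read(str(path))
    if rate != SAMPLE_RATE_HZ:
        raise ValueError(f"{path}: expected {SAMPLE_RATE_HZ} Hz, got {rate}")
    if data.ndim != 1:
        raise ValueError(f"{path}: expected mono audio")
    samples = data.astype(float) / _PCM_SCALE
    return AudioSegment(samples=samples, label=label, subject_id=subject_id)


def write_dataset(directory: str | Path, segments: list[AudioSegment], seeds: list[int] | None = None) -> Path:
    """Write segments as WAV files plus a labels.csv sidecar; returns the sidecar path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, seg in enumerate(segments):
        fname = f"segment_{i:05d}.wav"
        write_wav_segment(directory / fname, seg)
        rows.append(
            {
                "filename": fname,
                "subject_id": seg.subject_id,
                "label": seg.label,
                "duration_s": len(seg.samples) / SAMPLE_RATE_HZ,
                "seed": seeds[i] if seeds is not None else -1,
            }
        )
    sidecar = directory / "labels.csv"
    pd.DataFrame(rows).to_csv(sidecar, index=False)
    return sidecar


def read_dataset(directory: str | Path) -> list[AudioSegment]:
    """Read back a WAV + labels.csv dataset directory."""
    directory = Path(directory)
    sidecar = directory / "labels.csv"
    if not sidecar.exists():
        raise FileNotFoundError(f"no labels.csv in {directory}")
    table = pd.read_csv(sidecar)
    return [
        read_wav_segment(directory / row["filename"], row["label"], str(row["subject_id"]))
        for _, row in table.iterrows()
    ]


def features_to_frame(features: list[FeatureVector]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "part_id": [f.part_id for f in features],
            "subject_id": [f.subject_id for f in features],
            "label": [f.label for f in features],
            "segment_index": [f.segment_index for f in features],
            "part_index": [f.part_index for f in features],
            "lle": [f.lle for f in features],
            "entropy": [f.entropy for f in features],
        }
    )


def write_features_csv(path: str | Path, features: list[FeatureVector]) -> None:
    features_to_frame(features).to_csv(path, index=False)


def read_features_csv(path: str | Path) -> list[FeatureVector]:
    df = pd.read_csv(path)
    return [
        FeatureVector(
            lle=row["lle"],
            entropy=row["entropy"],
            label=row["label"],
            subject_id=str(row["subject_id"]),
            part_id=str(row["part_id"]),
            segment_index=int(row["segment_index"]),
            part_index=int(row["part_index"]),
        )
        for _, row in df.iterrows()
    ]
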