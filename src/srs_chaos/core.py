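"""Core domain containers shared across the pipeline.

The unit of analysis is the *segment part*: a 3200-sample window cut from a
labelled snore / breathing / silence segment recorded (or synthesised) at
16 kHz.  Each part is summarised by two scalar features — the largest
Lyapunov exponent of its delay-embedded trajectory and the Shannon entropy
of its amplitude histogram — which feed the classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

SAMPLE_RATE_HZ = 16_000
PART_LENGTH = 3_200

#: Canonical class labels, in the order used for class codes 1/2/3.
CLASSES = ("snore", "breathing", "silence")

CLASS_TO_CODE = {c: i + 1 for i, c in enumerate(CLASSES)}
CODE_TO_CLASS = {i + 1: c for i, c in enumerate(CLASSES)}


def check_label(label: str) -> str:
    if label not in CLASSES:
        raise ValueError(f"unknown class label {label!r}; expected one of {CLASSES}")
    return label


@dataclass(frozen=True)
class SegmentSpec:
    """Recipe for one synthetic labelled segment."""

    label: str
    duration_s: float
    subject_id: str = "s0"
    seed: int = 0

    def __post_init__(self) -> None:
        check_label(self.label)
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * SAMPLE_RATE_HZ))


@dataclass
class AudioSegment:
    """A labelled mono audio segment at 16 kHz."""

    samples: np.ndarray
    label: str
    subject_id: str = "s0"
    sample_rate_hz: int = SAMPLE_RATE_HZ

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        check_label(self.label)
        if self.sample_rate_hz != SAMPLE_RATE_HZ:
            raise ValueError(f"sample_rate_hz must be {SAMPLE_RATE_HZ}")

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class SegmentPart:
    """A fixed-length normalized window of a segment; the classification unit.

    Samples lie in [-0.5, 0.5] because the parent segment is min-max
    normalized to that range before subdivision.
    """

    samples: np.ndarray
    label: str
    subject_id: str
    part_index: int
    segment_index: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        check_label(self.label)
        if len(self.samples) != PART_LENGTH:
            raise ValueError(f"a segment part must have exactly {PART_LENGTH} samples")
        if self.samples.min() < -0.5 - 1e-9 or self.samples.max() > 0.5 + 1e-9:
            raise ValueError("part samples must lie in [-0.5, 0.5]")

    @property
    def part_id(self) -> str:
        return f"{self.subject_id}/{self.label}/{self.segment_index}/{self.part_index}"


@dataclass
class FeatureVector:
    """(LLE, entropy) pair for one part — the 2-D classifier input.

    ``lle`` is in nats per sample (the sampling step is the time unit);
    ``entropy`` is in bits.
    """

    lle: float
    entropy: float
    label: str
    subject_id: str = "s0"
    part_id: str = ""
    segment_index: int = 0
    part_index: int = 0

    def __post_init__(self) -> None:
        check_label(self.label)
        if not (np.isfinite(self.lle) and np.isfinite(self.entropy)):
            raise ValueError("features must be finite")

    @property
    def xy(self) -> np.ndarray:
        return np.array([self.lle, self.entropy])


def features_to_arrays(features: list[FeatureVector]) -> tuple[np.ndarray, np.ndarray]:
    """Stack feature vectors into (X, y) with y as string labels."""
    X = np.array([[f.lle, f.entropy] for f in features], dtype=float)
    y = np.array([f.label for f in features])
    return X, y
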