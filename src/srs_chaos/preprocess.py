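"""Segment normalization and subdivision into fixed-length parts.

Each labelled segment is min-max normalized to [-0.5, 0.5] (per segment,
so that inter-part amplitude structure within a segment is preserved) and
then cut into consecutive non-overlapping 3200-sample parts; a trailing
remainder shorter than one part is discarded.
"""

from __future__ import annotations

import logging

import numpy as np

from .core import PART_LENGTH, AudioSegment, SegmentPart

logger = logging.getLogger(__name__)

__all__ = ["normalize_segment", "subdivide", "segments_to_parts"]


def normalize_segment(segment: AudioSegment) -> AudioSegment:
    """Affinely map a segment's amplitude range onto [-0.5, 0.5].

    The segment minimum maps to -0.5 and the maximum to +0.5.  A constant
    segment (zero range) maps to all zeros.  Idempotent up to floating
    point rounding.
    """
    x = segment.samples
    if x.size == 0:
        raise ValueError("cannot normalize an empty segment")
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        y = np.zeros_like(x)
    else:
        y = (x - lo) / (hi - lo) - 0.5
    return AudioSegment(samples=y, label=segment.label, subject_id=segment.subject_id)


def subdivide(
    segment: AudioSegment,
    part_length: int = PART_LENGTH,
    segment_index: int = 0,
) -> list[SegmentPart]:
    """Cut a normalized segment into consecutive non-overlapping parts.

    Returns floor(len/part_length) parts; the remainder is dropped.  A
    segment shorter than one part yields an empty list (with a warning).
    """
    if part_length < 2:
        raise ValueError("part_length must be >= 2")
    x = segment.samples
    n_parts = len(x) // part_length
    if n_parts == 0:
        logger.warning(
            "segment of %d samples is shorter than part_length=%d; no parts emitted",
            len(x),
            part_length,
        )
        return []
    parts = []
    for k in range(n_parts):
        window = x[k * part_length : (k + 1) * part_length]
        parts.append(
            SegmentPart(
                samples=window,
                label=segment.label,
                subject_id=segment.subject_id,
                part_index=k,
                segment_index=segment_index,
            )
        )
    return parts


def segments_to_parts(
    segments: list[AudioSegment], part_length: int = PART_LENGTH
) -> list[SegmentPart]:
    """Normalize every segment and concatenate the resulting parts."""
    parts: list[SegmentPart] = []
    for i, seg in enumerate(segments):
        parts.extend(subdivide(normalize_segment(seg), part_length, segment_index=i))
    return parts
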