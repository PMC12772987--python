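"""Standardized segmentation of airflow recordings.

The preprocessing chain is intentionally minimal: resample to a common 4 Hz,
cut into fixed-length 5/10/20-min segments, and z-score each segment. No
filtering or artifact removal is ever applied — noisy and artifact-bearing
segments are kept so the downstream regressor learns to handle them. The
``PIPELINE_STAGES`` registry enumerates the only transforms in the chain.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy.signal import resample_poly

from .simulate import AirflowRecord, EventAnnotation, RESPIRATORY_KINDS

__all__ = [
    "TARGET_FS",
    "SEGMENT_MINUTES",
    "PIPELINE_STAGES",
    "SegmentSet",
    "resample_to_4hz",
    "segment_signal",
    "standardize",
    "label_segments",
    "build_segment_set",
]

TARGET_FS = 4.0
SEGMENT_MINUTES = (5, 10, 20)

#: the complete transform chain; no filtering/denoising stage exists
PIPELINE_STAGES = ("resample_to_4hz", "segment_signal", "standardize")

_SD_GUARD = 1e-8


@dataclass
class SegmentSet:
    """Fixed-length standardized segments of one subject with event counts."""

    subject_id: str
    segment_minutes: int
    segments: np.ndarray  # (n_segments, L), z-scored
    labels: np.ndarray  # (n_segments,), apnea+hypopnea counts
    segment_start_times: np.ndarray  # seconds

    @property
    def n_segments(self) -> int:
        return self.segments.shape[0]

    @property
    def segment_length(self) -> int:
        return int(self.segment_minutes * 60 * TARGET_FS)


def resample_to_4hz(samples: np.ndarray, fs_in: float) -> np.ndarray:
    """Anti-aliased polyphase resampling to 4 Hz.

    The rational resampling factor approximates ``4/fs_in`` to within 1e-6
    relative; the output length is ``round(len(samples) * 4 / fs_in)``.
    Upsampling (``fs_in < 4``) is not supported.
    """
    samples = np.asarray(samples, dtype=float)
    if fs_in < TARGET_FS:
        raise ValueError(f"fs_in must be >= {TARGET_FS} Hz (got {fs_in}); upsampling unsupported")
    if not np.all(np.isfinite(samples)):
        raise ValueError("samples contain non-finite values")
    n_out = int(round(samples.size * TARGET_FS / fs_in))
    if fs_in == TARGET_FS:
        return samples.copy()
    frac = Fraction(TARGET_FS / fs_in).limit_denominator(1_000_000)
    out = resample_poly(samples, frac.numerator, frac.denominator)
    if out.size >= n_out:
        return out[:n_out]
    return np.pad(out, (0, n_out - out.size), mode="edge")


def segment_signal(
    samples: np.ndarray, segment_minutes: int
) -> tuple[np.ndarray, np.ndarray]:
    """Cut a 4 Hz signal into consecutive non-overlapping raw segments.

    Returns ``(segments, start_times)``; a trailing remainder shorter than
    one segment is dropped.
    """
    if segment_minutes not in SEGMENT_MINUTES:
        raise ValueError(f"segment_minutes must be one of {SEGMENT_MINUTES}")
    samples = np.asarray(samples, dtype=float)
    L = int(segment_minutes * 60 * TARGET_FS)
    n_seg = samples.size // L
    if n_seg == 0:
        raise ValueError(
            f"signal of {samples.size} samples is shorter than one "
            f"{segment_minutes}-min segment ({L} samples)"
        )
    segments = samples[: n_seg * L].reshape(n_seg, L)
    start_times = np.arange(n_seg) * (L / TARGET_FS)
    return segments, start_times


def standardize(segment: np.ndarray) -> np.ndarray:
    """Z-score one raw segment; a near-constant segment maps to all zeros."""
    segment = np.asarray(segment, dtype=float)
    if segment.size == 0:
        raise ValueError("segment is empty")
    sd = segment.std()
    if sd < _SD_GUARD:
        return np.zeros_like(segment)
    return (segment - segment.mean()) / sd


def label_segments(
    start_times: Sequence[float],
    segment_minutes: int,
    annotations: Sequence[EventAnnotation],
) -> np.ndarray:
    """Count apnea+hypopnea events per segment by event *onset*.

    An event belongs to the segment containing its onset, so each event is
    counted exactly once; artifact and wake annotations are never counted.
    """
    width = segment_minutes * 60.0
    onsets = np.array(
        [a.onset for a in annotations if a.kind in RESPIRATORY_KINDS], dtype=float
    )
    labels = np.zeros(len(start_times), dtype=int)
    for i, start in enumerate(start_times):
        labels[i] = int(np.sum((onsets >= start) & (onsets < start + width)))
    return labels


def build_segment_set(record: AirflowRecord, segment_minutes: int) -> SegmentSet:
    """Full chain for one recording: resample, segment, z-score, label."""
    x4 = resample_to_4hz(record.samples, record.fs)
    raw, starts = segment_signal(x4, segment_minutes)
    segments = np.stack([standardize(row) for row in raw])
    labels = label_segments(starts, segment_minutes, record.annotations)
    return SegmentSet(
        subject_id=record.subject_id,
        segment_minutes=segment_minutes,
        segments=segments,
        labels=labels,
        segment_start_times=starts,
    )
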