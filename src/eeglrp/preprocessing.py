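"""Signal conditioning: bandpass, downsample, common average reference,
fixed-length cropping and non-overlapping segmentation.

The canonical chain for raw clinical recordings is
``bandpass -> downsample -> common_average_reference -> crop -> segment``.
Artifact removal (ICA) is a pluggable no-op here: the pipeline accepts
already-clean data and the synthetic generator produces none.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .io import EEGRecording


@dataclass(frozen=True)
class SegmentSet:
    """Equal-length, non-overlapping, contiguous segments of one subject."""

    subject_id: str
    label: int | None
    segments: tuple[np.ndarray, ...]  # each (n_channels, segment_samples)
    segment_length: float  # seconds
    fs: float

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("segment set must contain at least one segment")
        shapes = {s.shape for s in self.segments}
        if len(shapes) != 1:
            raise ValueError(f"segments differ in shape: {shapes}")

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def n_channels(self) -> int:
        return self.segments[0].shape[0]

    @property
    def segment_samples(self) -> int:
        return self.segments[0].shape[1]

    def pick_channel_indices(self, idx) -> "SegmentSet":
        idx = np.asarray(idx, dtype=int)
        return replace(self, segments=tuple(s[idx] for s in self.segments))


def bandpass(rec: EEGRecording, low: float = 1.0, high: float = 55.0) -> EEGRecording:
    """Zero-phase 4th-order Butterworth bandpass."""
    nyquist = rec.fs / 2.0
    if not 0 < low < high:
        raise ValueError(f"need 0 < low < high, got ({low}, {high})")
    if high >= nyquist:
        raise ValueError(
            f"high edge {high} Hz must be below the Nyquist rate {nyquist} Hz"
        )
    sos = sps.butter(4, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    return replace(rec, signal=sps.sosfiltfilt(sos, rec.signal, axis=1))


def downsample(rec: EEGRecording, target: float = 200.0) -> EEGRecording:
    """Anti-aliased polyphase resampling to ``target`` Hz."""
    if target > rec.fs:
        raise ValueError(f"target {target} Hz exceeds current rate {rec.fs} Hz")
    if target == rec.fs:
        return rec
    ratio = Fraction(target / rec.fs).limit_denominator(1000)
    out = sps.resample_poly(rec.signal, ratio.numerator, ratio.denominator, axis=1)
    expected = int(np.floor(rec.n_samples * target / rec.fs))
    return replace(rec, fs=float(target), signal=out[:, :expected])


def common_average_reference(rec: EEGRecording) -> EEGRecording:
    """Subtract, at every sample, the mean over channels (CAR). Idempotent."""
    if rec.n_channels < 2:
        raise ValueError("common average reference needs at least 2 channels")
    return replace(rec, signal=rec.signal - rec.signal.mean(axis=0, keepdims=True))


def crop_to_common_length(rec: EEGRecording, length: float = 180.0) -> EEGRecording:
    """Keep the first ``length`` seconds."""
    n = int(round(length * rec.fs))
    if rec.n_samples < n:
        raise ValueError(
            f"subject {rec.subject_id}: recording is {rec.duration:.1f} s, "
            f"shorter than the requested {length} s crop"
        )
    return replace(rec, signal=rec.signal[:, :n])


def remove_artifacts(rec: EEGRecording) -> EEGRecording:
    """Artifact-removal stage (no-op).

    Clinical pipelines put ICA-based artifact rejection here; this package
    assumes artifact-free input and keeps the stage as an explicit
    pass-through so the chain's order is visible.
    """
    return rec


def segment(rec: EEGRecording, segment_length: float) -> SegmentSet:
    """Non-overlapping, contiguous segments from the recording start.

    The trailing remainder shorter than ``segment_length`` is discarded.
    Boundaries are half-open ``[start, end)`` in 0-based samples.
    """
    if segment_length <= 0:
        raise ValueError("segment_length must be positive")
    n_seg_samples = int(round(segment_length * rec.fs))
    n_segments = rec.n_samples // n_seg_samples
    if n_segments < 1:
        raise ValueError(
            f"subject {rec.subject_id}: recording shorter than one "
            f"{segment_length}-s segment"
        )
    segments = tuple(
        rec.signal[:, i * n_seg_samples : (i + 1) * n_seg_samples].copy()
        for i in range(n_segments)
    )
    return SegmentSet(
        subject_id=rec.subject_id,
        label=rec.label,
        segments=segments,
        segment_length=segment_length,
        fs=rec.fs,
    )


def preprocess(
    rec: EEGRecording,
    *,
    low: float = 1.0,
    high: float = 55.0,
    target_fs: float = 200.0,
    crop: float = 180.0,
) -> EEGRecording:
    """The full conditioning chain (without segmentation)."""
    rec = bandpass(rec, low, high)
    rec = remove_artifacts(rec)
    rec = downsample(rec, target_fs)
    rec = common_average_reference(rec)
    return crop_to_common_length(rec, crop)
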