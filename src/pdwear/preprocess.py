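"""Signal conditioning: regularize, downsample, high-pass filter, segment.

The pipeline order is fixed: cubic-spline interpolation onto the device's
nominal uniform grid, rational polyphase downsampling (with its built-in
anti-alias low-pass), zero-phase 0.5 Hz high-pass on the accelerometer
channels only (to remove the gravity/orientation component), then
segmentation into 5-s clips with 50% overlap.  Clips covering a window in
which the un-interpolated recording had fewer than 80% of the expected
samples are flagged invalid and excluded from modeling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, resample_poly, sosfiltfilt

from .synthdata import SensorRecording

__all__ = [
    "Clip",
    "UnusableRecordingError",
    "DataError",
    "regularize",
    "downsample",
    "highpass_accel",
    "segment",
    "preprocess_recording",
    "VALIDITY_FRACTION",
]

#: minimum fraction of expected raw samples for a clip to be usable
VALIDITY_FRACTION = 0.8

DEFAULT_WINDOW_S = 5.0
DEFAULT_OVERLAP = 0.5
DEFAULT_HIGHPASS_HZ = 0.5


class UnusableRecordingError(ValueError):
    """Recording too short or degenerate to preprocess."""


class DataError(ValueError):
    """Recording violates a structural invariant (e.g. non-monotone time)."""


@dataclass
class Clip:
    """One 5-s windowed segment of a preprocessed recording.

    ``raw_sample_count`` counts un-interpolated samples whose timestamps fall
    inside the window; the clip is valid iff that count reaches 80% of the
    samples the device should have produced at its native rate.
    Symptom scores are inherited unchanged from the parent recording.
    """

    device: str
    participant_id: str
    task_id: str
    repetition: int
    start_time: float
    accel: np.ndarray  # 3 x W
    gyro: np.ndarray | None  # 3 x W or None
    rate: float  # Hz after resampling
    raw_sample_count: int
    valid: bool
    scores: dict[str, int]

    @property
    def window_samples(self) -> int:
        return int(self.accel.shape[1])

    @property
    def clip_id(self) -> str:
        return (
            f"{self.device}:{self.participant_id}:{self.task_id}:"
            f"{self.repetition}:{self.start_time:.3f}"
        )


def regularize(recording: SensorRecording) -> SensorRecording:
    """Cubic-spline interpolate onto the nominal-rate uniform grid.

    The output grid spans ``[t0, tN]`` at ``nominal_rate`` — no
    extrapolation beyond the recorded span.  The original timestamps are
    retained as a sidecar for the clip validity rule.
    """
    t = np.asarray(recording.timestamps, float)
    if t.size < 4:
        raise UnusableRecordingError(
            f"need at least 4 samples for cubic-spline regularization, got {t.size}"
        )
    if np.any(np.diff(t) <= 0):
        raise DataError("timestamps must be strictly increasing")
    rate = recording.nominal_rate
    n_out = int(math.floor((t[-1] - t[0]) * rate)) + 1
    grid = t[0] + np.arange(n_out) / rate
    accel = CubicSpline(t, recording.accel, axis=1)(grid)
    gyro = None
    if recording.gyro is not None:
        gyro = CubicSpline(t, recording.gyro, axis=1)(grid)
    return replace(
        recording,
        timestamps=grid,
        accel=accel,
        gyro=gyro,
        raw_timestamps=t,
    )


def _rational_ratio(target: float, original: float) -> tuple[int, int]:
    frac = Fraction(target / original).limit_denominator(10_000)
    return frac.numerator, frac.denominator


def downsample(recording: SensorRecording, target_rate: float) -> SensorRecording:
    """Rational polyphase resampling to ``target_rate``.

    Uses an up/down factor pair from the rational ratio (62.5 -> 7.5 Hz is
    up 3 / down 25); the polyphase FIR includes the anti-alias low-pass at
    the new Nyquist frequency, so content above ``target_rate / 2`` is
    suppressed rather than aliased.
    """
    if target_rate > recording.nominal_rate:
        raise ValueError(
            f"target rate {target_rate} Hz above recording rate {recording.nominal_rate} Hz"
        )
    if target_rate == recording.nominal_rate:
        return replace(recording)
    up, down = _rational_ratio(target_rate, recording.nominal_rate)
    accel = resample_poly(recording.accel, up, down, axis=1)
    gyro = None
    if recording.gyro is not None:
        gyro = resample_poly(recording.gyro, up, down, axis=1)
    t0 = float(recording.timestamps[0])
    grid = t0 + np.arange(accel.shape[1]) / target_rate
    return replace(
        recording,
        timestamps=grid,
        accel=accel,
        gyro=gyro,
        nominal_rate=target_rate,
    )


def highpass_accel(
    recording: SensorRecording, cutoff: float = DEFAULT_HIGHPASS_HZ
) -> SensorRecording:
    """Zero-phase 4th-order Butterworth high-pass on accelerometer channels.

    Removes the orientation/gravity component (DC and drift below the
    cutoff).  Gyroscope channels pass through untouched.  Zero-phase
    (forward-backward) filtering preserves the alignment between clips and
    their labels.
    """
    rate = recording.nominal_rate
    if rate <= 2 * cutoff:
        raise ValueError(f"rate {rate} Hz too low for a {cutoff} Hz high-pass")
    sos = butter(4, cutoff, btype="highpass", fs=rate, output="sos")
    accel = sosfiltfilt(sos, recording.accel, axis=1)
    return replace(recording, accel=accel)


def segment(
    recording: SensorRecording,
    window_s: float = DEFAULT_WINDOW_S,
    overlap: float = DEFAULT_OVERLAP,
    scores: Mapping[str, int] | None = None,
) -> list[Clip]:
    """Cut a uniform recording into overlapping fixed-length clips.

    Windows hold ``floor(window_s * rate)`` samples with a hop of half a
    window.  A recording shorter than one window yields an empty list.  Each
    clip's ``raw_sample_count`` is computed from the sidecar of original
    timestamps; clips below the 80% coverage rule are flagged invalid.
    """
    rate = recording.nominal_rate
    w = int(math.floor(window_s * rate))
    hop = max(int(round(w * (1.0 - overlap))), 1)
    n = recording.n_samples
    if n < w:
        return []
    raw_t = recording.raw_timestamps
    if raw_t is None:
        # never regularized: the recording's own samples are the raw ones
        raw_t = recording.timestamps
    native_rate = recording.native_rate or rate
    expected_raw = window_s * native_rate
    clips: list[Clip] = []
    n_clips = (n - w) // hop + 1
    for k in range(n_clips):
        i0 = k * hop
        start = float(recording.timestamps[i0])
        raw_count = int(
            np.searchsorted(raw_t, start + window_s, side="left")
            - np.searchsorted(raw_t, start, side="left")
        )
        clips.append(
            Clip(
                device=recording.device,
                participant_id=recording.participant_id,
                task_id=recording.task_id,
                repetition=recording.repetition,
                start_time=start,
                accel=recording.accel[:, i0 : i0 + w].copy(),
                gyro=None if recording.gyro is None else recording.gyro[:, i0 : i0 + w].copy(),
                rate=rate,
                raw_sample_count=raw_count,
                valid=raw_count >= VALIDITY_FRACTION * expected_raw,
                scores=dict(scores or {}),
            )
        )
    return clips


def preprocess_recording(
    recording: SensorRecording,
    target_rate: float | None = None,
    cutoff: float = DEFAULT_HIGHPASS_HZ,
    window_s: float = DEFAULT_WINDOW_S,
    overlap: float = DEFAULT_OVERLAP,
    scores: Mapping[str, int] | None = None,
) -> list[Clip]:
    """Full conditioning chain: regularize -> downsample -> high-pass -> segment."""
    rec = regularize(recording)
    if target_rate is not None and target_rate < rec.nominal_rate:
        rec = downsample(rec, target_rate)
    rec = highpass_accel(rec, cutoff)
    return segment(rec, window_s=window_s, overlap=overlap, scores=scores)
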