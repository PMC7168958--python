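"""Glue from raw recordings to clip and feature tables."""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from . import features as _features
from .preprocess import Clip, preprocess_recording
from .synthdata import SensorRecording, SymptomAnnotation, annotation_index

__all__ = ["make_clips", "build_feature_table"]


def make_clips(
    recordings: Sequence[SensorRecording],
    annotations: Sequence[SymptomAnnotation],
    device: str,
    target_rate: float | None = None,
    window_s: float = 5.0,
    overlap: float = 0.5,
    cutoff: float = 0.5,
) -> list[Clip]:
    """Condition every recording of one device and pool the valid clips."""
    index = annotation_index(annotations)
    clips: list[Clip] = []
    for rec in recordings:
        if rec.device != device:
            continue
        scores = index.get((rec.participant_id, rec.task_id, rec.repetition), {})
        clips.extend(
            preprocess_recording(
                rec, target_rate=target_rate, cutoff=cutoff,
                window_s=window_s, overlap=overlap, scores=scores,
            )
        )
    return [c for c in clips if c.valid]


def build_feature_table(
    recordings: Sequence[SensorRecording],
    annotations: Sequence[SymptomAnnotation],
    device: str,
    target_rate: float | None = None,
    categories: Iterable[str] = _features.CATEGORIES,
    modalities: Iterable[str] | None = None,
    magnitude_only: bool = False,
) -> pd.DataFrame:
    """Preprocess one device's recordings and extract the feature matrix."""
    if modalities is None:
        modalities = _features.MODALITIES if device == "hand_sensor" else ("accel",)
    clips = make_clips(recordings, annotations, device, target_rate=target_rate)
    return _features.extract_feature_table(
        clips, categories=categories, modalities=modalities, magnitude_only=magnitude_only
    )
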