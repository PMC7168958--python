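"""Shared fixtures: small synthetic datasets and preprocessed clips."""

from __future__ import annotations

import numpy as np
import pytest

from pdwear.pipeline import build_feature_table, make_clips
from pdwear.synthdata import GeneratorConfig, default_tasks, generate_dataset


def small_config(seed: int = 11) -> GeneratorConfig:
    """Four participants, three tasks, two repetitions, short recordings.

    Symptom prevalence is boosted relative to the cohort defaults so that
    every participant is likely to contribute both classes — a convenience
    for exercising the modeling code paths on a tiny dataset.
    """
    by_id = {t.task_id: t for t in default_tasks()}
    return GeneratorConfig(
        n_participants=4,
        tasks=(by_id["walking"], by_id["pouring_water"], by_id["arms_extended"]),
        n_repetitions=2,
        duration_range=(15.0, 16.0),
        tremor_affected_prob=0.6,
        brady_affected_prob=0.8,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(small_config())


@pytest.fixture(scope="session")
def hand_clips(small_dataset):
    recordings, annotations = small_dataset
    return make_clips(recordings, annotations, "hand_sensor")


@pytest.fixture(scope="session")
def watch_clips(small_dataset):
    recordings, annotations = small_dataset
    return make_clips(recordings, annotations, "watch")


@pytest.fixture(scope="session")
def hand_table(small_dataset):
    recordings, annotations = small_dataset
    return build_feature_table(recordings, annotations, "hand_sensor")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
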