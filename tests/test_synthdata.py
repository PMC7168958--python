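"""Generator behavior: determinism, scoring rules, symptom signatures."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.signal import periodogram

from pdwear.synthdata import (
    ConfigError,
    GeneratorConfig,
    IdealMotion,
    ParticipantProfile,
    TaskSpec,
    apply_sensor_model,
    default_tasks,
    generate_annotations,
    generate_cohort,
    generate_dataset,
    score_task,
    synthesize_kinematics,
    G_MS2,
)

from conftest import small_config


def _profile(tremor=0.0, brady=0.0, response=(1.0, 0.9)):
    return ParticipantProfile("P01", tremor, brady, response)


def _postural_task(brady_scorable=False):
    return TaskSpec("hold", "postural_hold", 0.2, 0.4, brady_scorable=brady_scorable)


class TestCohort:
    def test_default_config_yields_requested_profiles(self):
        cfg = GeneratorConfig(seed=7)
        profiles = generate_cohort(cfg)
        assert len(profiles) == 13
        for p in profiles:
            assert 0.0 <= p.tremor_propensity < 4.0
            assert 0.0 <= p.brady_propensity < 4.0
            assert all(p.medication_response[0] >= m for m in p.medication_response[1:])

    def test_participant_count_follows_config(self):
        cfg = GeneratorConfig(n_participants=2)
        assert len(generate_cohort(cfg)) == 2

    def test_same_seed_reproduces_cohort(self):
        cfg = GeneratorConfig(seed=42)
        assert generate_cohort(cfg) == generate_cohort(cfg)

    @pytest.mark.parametrize(
        "field,value",
        [
            ("n_participants", 0),
            ("sample_drop_prob", 1.0),
            ("hand_rate", -1.0),
            ("duration_range", (30.0, 20.0)),
        ],
    )
    def test_invalid_config_names_field(self, field, value):
        cfg = GeneratorConfig(**{field: value})
        with pytest.raises(ConfigError, match=field.split("_")[0]):
            cfg.validate()

    def test_non_monotone_severity_map_rejected(self):
        cfg = GeneratorConfig(tremor_amp_by_score={0: 0.0, 1: 1.0, 2: 0.5})
        with pytest.raises(ConfigError, match="tremor_amp_by_score"):
            cfg.validate()


class TestScoring:
    def test_zero_propensity_scores_zero(self, rng):
        ann = score_task(_profile(), _postural_task(True), 1, "tremor", rng)
        assert ann.score == 0

    def test_bradykinesia_absent_on_non_scorable_task(self, rng):
        ann = score_task(_profile(brady=3.0), _postural_task(False), 1, "bradykinesia", rng)
        assert ann is None

    def test_score_is_rounded_scaled_propensity(self, rng):
        profile = _profile(tremor=3.2, response=(1.0,))
        ann = score_task(profile, _postural_task(True), 1, "tremor", rng, score_noise_sd=0.0)
        assert ann.score == 3

    def test_default_cohort_never_scores_four_and_is_mostly_zero(self):
        anns = generate_annotations(GeneratorConfig(seed=5))
        tremor = [a.score for a in anns if a.symptom == "tremor"]
        assert max(a.score for a in anns) <= 3
        zero_frac = np.mean(np.array(tremor) == 0)
        assert 0.6 <= zero_frac <= 0.85

    def test_brady_annotations_missing_only_for_non_scorable_tasks(self):
        cfg = GeneratorConfig(seed=5)
        anns = generate_annotations(cfg)
        scorable = {t.task_id for t in cfg.tasks if t.brady_scorable}
        brady_tasks = {a.task_id for a in anns if a.symptom == "bradykinesia"}
        assert brady_tasks == scorable


class TestKinematics:
    CFG = GeneratorConfig()

    def _motion(self, tremor=0, brady=0, task=None, seed=0, duration=20.0):
        task = task or _postural_task(True)
        rng = np.random.default_rng(seed)
        return synthesize_kinematics(
            _profile(tremor, brady), task,
            {"tremor": tremor, "bradykinesia": brady}, duration, rng, self.CFG,
        )

    @staticmethod
    def _band_power(motion, lo, hi):
        mag = np.linalg.norm(motion.accel, axis=0)
        f, p = periodogram(mag - mag.mean(), fs=motion.rate)
        return p[(f >= lo) & (f <= hi)].sum()

    def test_no_tremor_means_no_power_above_4hz(self):
        m = self._motion(tremor=0)
        # voluntary movement sits below 4 Hz; above it only the noise floor
        assert self._band_power(m, 4.0, 6.0) < 10 * self._band_power(m, 8.0, 10.0)

    def test_tremor_creates_dominant_4_to_6hz_peak(self):
        m = self._motion(tremor=3)
        mag = np.linalg.norm(m.accel, axis=0)
        f, p = periodogram(mag - mag.mean(), fs=m.rate)
        f, p = f[1:], p[1:]
        assert 4.0 <= f[np.argmax(p)] <= 6.0

    def test_bradykinesia_slows_peak_voluntary_speed(self):
        task = TaskSpec("pour", "gross_upper", 0.8, 1.8)
        slow = self._motion(brady=2, task=task, seed=3)
        normal = self._motion(brady=0, task=task, seed=3)
        # peak angular speed (the voluntary carrier) drops with the score
        peak = lambda m: np.abs(m.gyro).max()
        assert peak(slow) < peak(normal)

    def test_tremor_band_power_monotone_in_score(self):
        powers = []
        for score in (0, 1, 2, 3):
            per_seed = [
                self._band_power(self._motion(tremor=score, seed=s), 4.0, 6.0)
                for s in range(8)
            ]
            powers.append(np.mean(per_seed))
        assert all(a <= b for a, b in zip(powers, powers[1:]))

    def test_duration_outside_range_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            self._motion(duration=5.0)


class TestSensorModel:
    def test_no_jitter_no_drop_gives_uniform_grid(self):
        cfg = GeneratorConfig(timestamp_jitter_sd=0.0, sample_drop_prob=0.0)
        rng = np.random.default_rng(0)
        motion = synthesize_kinematics(
            _profile(), _postural_task(True), {}, 20.0, rng, cfg
        )
        rec = apply_sensor_model(motion, "hand_sensor", cfg, rng)
        dt = np.diff(rec.timestamps)
        assert np.allclose(dt, 1 / 62.5, atol=1e-12)
        assert rec.gyro is not None

    def test_drop_probability_thins_samples_binomially(self):
        cfg = GeneratorConfig(sample_drop_prob=0.1, duration_range=(15.0, 60.0))
        rng = np.random.default_rng(2)
        motion = synthesize_kinematics(_profile(), _postural_task(True), {}, 60.0, rng, cfg)
        rec = apply_sensor_model(motion, "hand_sensor", cfg, rng)
        n_total = int(60.0 * 62.5) + 1
        expected = 0.9 * n_total
        sd = np.sqrt(n_total * 0.9 * 0.1)
        assert abs(rec.n_samples - expected) < 3 * sd

    def test_accelerometer_clips_at_range(self):
        cfg = GeneratorConfig(noise_sd=0.0, timestamp_jitter_sd=0.0, sample_drop_prob=0.0)
        t = np.arange(0, 20.0, 1 / 200.0)
        motion = IdealMotion(t, np.full((3, t.size), 10.0 * G_MS2), np.zeros((3, t.size)), 200.0)
        rec = apply_sensor_model(motion, "hand_sensor", cfg, np.random.default_rng(0))
        assert np.allclose(rec.accel, 4.0)

    def test_watch_has_no_gyro_and_runs_at_50hz(self):
        cfg = GeneratorConfig(timestamp_jitter_sd=0.0, sample_drop_prob=0.0)
        rng = np.random.default_rng(0)
        motion = synthesize_kinematics(_profile(), _postural_task(True), {}, 20.0, rng, cfg)
        rec = apply_sensor_model(motion, "watch", cfg, rng)
        assert rec.gyro is None
        assert rec.nominal_rate == 50.0


class TestDataset:
    def test_recording_pair_counts(self):
        cfg = small_config()
        recordings, _ = generate_dataset(cfg)
        n = cfg.n_participants * len(cfg.tasks) * cfg.n_repetitions
        assert len(recordings) == 2 * n
        assert sum(r.device == "hand_sensor" for r in recordings) == n

    def test_single_cell_dataset(self):
        cfg = GeneratorConfig(
            n_participants=1, tasks=default_tasks()[:1], n_repetitions=1,
            duration_range=(15.0, 16.0),
        )
        recordings, _ = generate_dataset(cfg)
        assert len(recordings) == 2

    def test_dataset_reproducible_from_seed(self):
        cfg = small_config(seed=99)
        recs1, anns1 = generate_dataset(cfg)
        recs2, anns2 = generate_dataset(cfg)
        assert anns1 == anns2
        for a, b in zip(recs1, recs2):
            np.testing.assert_array_equal(a.timestamps, b.timestamps)
            np.testing.assert_array_equal(a.accel, b.accel)

    def test_zero_symptom_cohort_scores_all_zero(self):
        cfg = small_config()
        cfg.tremor_affected_prob = 0.0
        cfg.brady_affected_prob = 0.0
        cfg.score_noise_sd = 0.0
        anns = generate_annotations(cfg)
        assert all(a.score == 0 for a in anns)
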