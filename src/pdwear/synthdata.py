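"""Synthetic cohort of scored tremor/bradykinesia motor-task recordings.

Emulates a clinic visit protocol in which participants with Parkinson's
disease repeat a battery of standardized motor tasks while wearing a
skin-mounted hand sensor (tri-axial accelerometer + gyroscope, 62.5 Hz)
and a wrist smart watch (tri-axial accelerometer, ~50 Hz), and a clinician
scores tremor and bradykinesia severity on the 0-4 MDS-UPDRS-style scale.

The kinematic model is deliberately simple but carries the two clinically
relevant signatures:

* tremor — a 4-6 Hz sinusoid whose amplitude grows with the tremor score,
  slowly amplitude-modulated and distributed over the axes by a random
  orientation;
* bradykinesia — slowing of the voluntary task oscillation (frequency and
  amplitude scaled down with the score, with a within-recording amplitude
  decrement), expressed strongly in angular velocity and only weakly in
  linear acceleration.

Sensor imperfections (timestamp jitter, dropped samples, range clipping,
measurement noise, wrist attenuation) are applied by an explicit sensor
model so the preprocessing stage has real artifacts to correct.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ConfigError",
    "TaskSpec",
    "GeneratorConfig",
    "ParticipantProfile",
    "SymptomAnnotation",
    "SensorRecording",
    "IdealMotion",
    "default_tasks",
    "generate_cohort",
    "score_task",
    "synthesize_kinematics",
    "apply_sensor_model",
    "generate_dataset",
]

#: standard gravity, m/s^2 per G
G_MS2 = 9.80665

ARCHETYPES = ("gait", "fine_upper", "gross_upper", "clinical_assessment", "postural_hold")
SYMPTOMS = ("tremor", "bradykinesia")
DEVICES = ("hand_sensor", "watch")

#: baseline angular-velocity amplitude (deg/s) of the voluntary movement,
#: per task archetype.  Gross arm movements rotate the hand far more than
#: postural holds do.
GYRO_GAIN_BY_ARCHETYPE = {
    "gait": 40.0,
    "fine_upper": 25.0,
    "gross_upper": 60.0,
    "clinical_assessment": 50.0,
    "postural_hold": 8.0,
}

#: angular-velocity amplitude of the tremor component, deg/s per m/s^2 of
#: tremor acceleration amplitude (a hand oscillating about the wrist).
TREMOR_GYRO_GAIN = 15.0


class ConfigError(ValueError):
    """A :class:`GeneratorConfig` field violates its invariant."""


@dataclass(frozen=True)
class TaskSpec:
    """One standardized motor task of the assessment battery.

    Parameters
    ----------
    task_id : str
        Identifier, e.g. ``"pouring"``.
    archetype : str
        One of ``gait``, ``fine_upper``, ``gross_upper``,
        ``clinical_assessment``, ``postural_hold``.
    base_frequency : float
        Frequency (Hz) of the voluntary movement oscillation; typical human
        movement peaks in 0-5 Hz.
    base_amplitude : float
        Acceleration amplitude (m/s^2) of the voluntary movement at score 0.
    brady_scorable : bool
        Whether the task involves enough voluntary movement for a clinician
        to score bradykinesia.  Postural holds do not.
    """

    task_id: str
    archetype: str
    base_frequency: float
    base_amplitude: float
    brady_scorable: bool = True

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ConfigError(f"tasks: unknown archetype {self.archetype!r}")
        if not 0.0 <= self.base_frequency <= 5.0:
            raise ConfigError(
                f"tasks: base_frequency must be in [0, 5] Hz, got {self.base_frequency}"
            )
        if self.base_amplitude < 0:
            raise ConfigError("tasks: base_amplitude must be >= 0")


def default_tasks() -> tuple[TaskSpec, ...]:
    """The default 13-task battery.

    Mixes functional, fine and gross upper-extremity, and clinical-assessment
    tasks.  Three of the thirteen are holds with too little voluntary movement
    to score bradykinesia, which reproduces the gap between the number of
    tremor-scored and bradykinesia-scored clips.
    """
    return (
        TaskSpec("walking", "gait", 1.9, 2.5),
        TaskSpec("standing_posture", "postural_hold", 0.25, 0.4, brady_scorable=False),
        TaskSpec("sitting_rest", "postural_hold", 0.10, 0.3, brady_scorable=False),
        TaskSpec("arms_extended", "postural_hold", 0.20, 0.4, brady_scorable=False),
        TaskSpec("typing", "fine_upper", 3.0, 1.0),
        TaskSpec("writing", "fine_upper", 2.5, 0.9),
        TaskSpec("buttoning", "fine_upper", 2.0, 1.0),
        TaskSpec("drawing", "fine_upper", 1.5, 0.8),
        TaskSpec("pouring_water", "gross_upper", 0.8, 1.8),
        TaskSpec("drinking", "gross_upper", 0.7, 1.6),
        TaskSpec("folding_towels", "gross_upper", 0.9, 1.8),
        TaskSpec("finger_to_nose", "clinical_assessment", 1.2, 1.6),
        TaskSpec("alternating_hands", "clinical_assessment", 2.2, 1.8),
    )


def _default_tremor_amp() -> dict[int, float]:
    # m/s^2 amplitude of the tremor oscillation per clinical score;
    # score 0 is symptom-free by definition.
    return {0: 0.0, 1: 0.5, 2: 1.2, 3: 2.5, 4: 4.0}


def _default_brady_slowing() -> dict[int, float]:
    # multiplicative speed factor per clinical score; 1 = unimpaired.
    return {0: 1.0, 1: 0.85, 2: 0.70, 3: 0.55, 4: 0.40}


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the study conditions: 13 participants, 13 tasks x 7
    repetitions, hand sensor at 62.5 Hz (accel range +/-4 G, gyro range
    +/-1000 deg/s), watch accelerometer at 50 Hz, recordings 15-60 s,
    tremor in the 4-6 Hz band, and a severity distribution in which about
    three quarters of tremor-scored clips are score 0 and score 4 never
    occurs.
    """

    n_participants: int = 13
    tasks: tuple[TaskSpec, ...] = field(default_factory=default_tasks)
    n_repetitions: int = 7
    hand_rate: float = 62.5
    watch_rate: float = 50.0
    accel_range: float = 4.0  # G
    gyro_range: float = 1000.0  # deg/s
    tremor_band: tuple[float, float] = (4.0, 6.0)
    tremor_amp_by_score: Mapping[int, float] = field(default_factory=_default_tremor_amp)
    brady_slowing_by_score: Mapping[int, float] = field(default_factory=_default_brady_slowing)
    duration_range: tuple[float, float] = (15.0, 60.0)
    timestamp_jitter_sd: float = 0.002  # s
    sample_drop_prob: float = 0.02
    noise_sd: float = 0.01  # accelerometer measurement noise, G
    gyro_noise_sd: float = 1.0  # gyroscope measurement noise, deg/s
    seed: int = 0

    # medication response: multiplier on latent severity per repetition.
    # Repetition 1 is the OFF-medication state (maximal symptoms, ~12 h off
    # drug); 2-6 decline at 30-min intervals as one dose takes effect; 7 is
    # the ON-state second visit.  The OFF->ON swing is deep, which is what
    # gives each participant clips on both sides of the presence threshold.
    medication_response: tuple[float, ...] = (1.0, 0.85, 0.65, 0.45, 0.30, 0.25, 0.35)
    score_noise_sd: float = 0.35  # clinician scoring noise (free parameter)
    tremor_affected_prob: float = 0.30  # P(participant has appreciable tremor)
    brady_affected_prob: float = 0.60
    # exponents of the slowing multiplier applied to the voluntary amplitude:
    # angular velocity carries the full slowing signature, linear acceleration
    # only a weak one (wrist/hand accelerometry is empirically less sensitive
    # to slowness than gyroscopes).
    brady_accel_exponent: float = 0.35
    brady_gyro_exponent: float = 1.0
    brady_decrement: float = 0.12  # fractional amplitude decay per score over a recording
    # natural movement tempo varies between people and repetitions, so the
    # voluntary frequency is jittered per recording by a factor drawn from
    # this range; absolute frequency is therefore a confounded severity cue
    voluntary_freq_jitter: tuple[float, float] = (0.8, 1.25)
    watch_attenuation: float = 0.90  # wrist signal relative to hand
    dense_rate: float = 200.0  # Hz of the ideal continuous-time grid

    def validate(self) -> None:
        """Raise :class:`ConfigError` naming the offending field."""
        if self.n_participants < 1:
            raise ConfigError("n_participants must be >= 1")
        if self.n_repetitions < 1:
            raise ConfigError("n_repetitions must be >= 1")
        if not self.tasks:
            raise ConfigError("tasks must be non-empty")
        for rate_name in ("hand_rate", "watch_rate", "dense_rate"):
            if getattr(self, rate_name) <= 0:
                raise ConfigError(f"{rate_name} must be > 0")
        if not 0.0 <= self.sample_drop_prob < 1.0:
            raise ConfigError("sample_drop_prob must be in [0, 1)")
        if self.tremor_amp_by_score.get(0, None) != 0.0:
            raise ConfigError("tremor_amp_by_score must map score 0 to amplitude 0")
        if self.brady_slowing_by_score.get(0, None) != 1.0:
            raise ConfigError("brady_slowing_by_score must map score 0 to multiplier 1")
        for name, mapping, increasing in (
            ("tremor_amp_by_score", self.tremor_amp_by_score, True),
            ("brady_slowing_by_score", self.brady_slowing_by_score, False),
        ):
            scores = sorted(mapping)
            vals = [mapping[s] for s in scores]
            diffs = np.diff(vals)
            if increasing and np.any(diffs < 0):
                raise ConfigError(f"{name} must be non-decreasing in score")
            if not increasing and np.any(diffs > 0):
                raise ConfigError(f"{name} must be non-increasing in score")
        if any(m > 1.0 for m in self.brady_slowing_by_score.values()):
            raise ConfigError("brady_slowing_by_score multipliers must be <= 1")
        lo, hi = self.duration_range
        if not 0 < lo <= hi:
            raise ConfigError("duration_range must satisfy 0 < low <= high")
        if len(self.medication_response) < self.n_repetitions:
            raise ConfigError("medication_response must cover every repetition")
        if any(self.medication_response[0] < m for m in self.medication_response[1:]):
            raise ConfigError("medication_response must be maximal at repetition 1 (OFF state)")


@dataclass(frozen=True)
class ParticipantProfile:
    """Latent symptom severity of one synthetic participant.

    ``tremor_propensity`` and ``brady_propensity`` live on the same 0-4 scale
    as the clinical scores; the observed score for a repetition is the
    propensity scaled by the medication-response multiplier plus clinician
    noise, rounded and clamped.
    """

    participant_id: str
    tremor_propensity: float
    brady_propensity: float
    medication_response: tuple[float, ...]

    def response(self, repetition: int) -> float:
        return self.medication_response[repetition - 1]


@dataclass(frozen=True)
class SymptomAnnotation:
    """One clinician score for one participant/task/repetition."""

    symptom: str
    score: int
    participant_id: str
    task_id: str
    repetition: int

    def __post_init__(self) -> None:
        if self.score not in (0, 1, 2, 3, 4):
            raise ValueError(f"score must be an integer 0-4, got {self.score}")
        if self.symptom not in SYMPTOMS:
            raise ValueError(f"unknown symptom {self.symptom!r}")


@dataclass
class SensorRecording:
    """One device's multi-channel time series for one task repetition.

    ``accel`` is 3 x N in G; ``gyro`` is 3 x N in deg/s and present iff the
    device is the hand sensor.  ``timestamps`` are seconds, strictly
    increasing and possibly irregular.  ``nominal_rate`` is the rate of the
    current (possibly resampled) grid; ``native_rate`` is the device's
    as-worn rate and stays fixed through the pipeline.  ``raw_timestamps``
    is the sidecar of un-interpolated sample times used by the clip
    validity rule.
    """

    device: str
    participant_id: str
    task_id: str
    repetition: int
    timestamps: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray | None
    nominal_rate: float
    native_rate: float | None = None
    raw_timestamps: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.device not in DEVICES:
            raise ValueError(f"unknown device {self.device!r}")
        if (self.gyro is not None) != (self.device == "hand_sensor"):
            raise ValueError("gyro channels present iff device is hand_sensor")
        if self.accel.shape[0] != 3 or self.accel.shape[1] != self.timestamps.size:
            raise ValueError("accel must be 3 x N matching timestamps")
        if self.gyro is not None and self.gyro.shape != self.accel.shape:
            raise ValueError("gyro channels must match accel length")
        if self.native_rate is None:
            self.native_rate = self.nominal_rate

    @property
    def n_samples(self) -> int:
        return int(self.timestamps.size)

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])


@dataclass
class IdealMotion:
    """Noise-free hand motion on a dense uniform grid (accel m/s^2, gyro deg/s)."""

    timestamps: np.ndarray
    accel: np.ndarray  # 3 x M, m/s^2, includes gravity
    gyro: np.ndarray  # 3 x M, deg/s
    rate: float


# ---------------------------------------------------------------------------
# cohort and scoring


def _rng_for(config: GeneratorConfig, *stream: int) -> np.random.Generator:
    # independent, reproducible stream per (seed, purpose) key
    return np.random.default_rng([config.seed & 0x7FFFFFFF, *stream])


def generate_cohort(config: GeneratorConfig) -> list[ParticipantProfile]:
    """Draw participant latent-severity profiles.

    Propensities span a mild-to-moderate range (capped at 3.0) so that with
    the default scoring noise a score of 4 is never produced.  A minority of
    participants has appreciable tremor while a majority has appreciable
    bradykinesia, matching the observed clip-score imbalance (roughly three
    quarters of tremor-scored clips at score 0, under half for bradykinesia).
    """
    config.validate()
    rng = _rng_for(config, 0)
    profiles = []
    for i in range(config.n_participants):
        tremor = (
            rng.uniform(0.8, 2.75)
            if rng.random() < config.tremor_affected_prob
            else rng.uniform(0.0, 0.35)
        )
        brady = (
            rng.uniform(0.5, 2.4)
            if rng.random() < config.brady_affected_prob
            else rng.uniform(0.0, 0.35)
        )
        # small per-participant wobble on the ON-state response, never
        # exceeding the OFF-state multiplier
        base = np.asarray(config.medication_response[: config.n_repetitions], float)
        wobble = np.clip(base * rng.uniform(0.92, 1.06, base.size), None, base[0])
        wobble[0] = base[0]
        profiles.append(
            ParticipantProfile(
                participant_id=f"P{i + 1:02d}",
                tremor_propensity=float(tremor),
                brady_propensity=float(brady),
                medication_response=tuple(float(v) for v in wobble),
            )
        )
    return profiles


def score_task(
    profile: ParticipantProfile,
    task: TaskSpec,
    repetition: int,
    symptom: str,
    rng: np.random.Generator,
    score_noise_sd: float = 0.25,
) -> SymptomAnnotation | None:
    """Clinician-style 0-4 score for one task repetition, or ``None``.

    Bradykinesia is not scorable on tasks without enough voluntary movement,
    in which case no annotation is produced.  The score is
    ``clamp(round(propensity * medication_response(rep) + noise), 0, 4)``
    with the scoring noise truncated at +/-2 SD, so with the default noise
    and the cohort's propensity cap of 2.75 a score of 4 can never occur.
    """
    if symptom not in SYMPTOMS:
        raise ValueError(f"unknown symptom {symptom!r}")
    if symptom == "bradykinesia" and not task.brady_scorable:
        return None
    propensity = profile.tremor_propensity if symptom == "tremor" else profile.brady_propensity
    noise = float(np.clip(rng.normal(0.0, score_noise_sd), -2 * score_noise_sd, 2 * score_noise_sd))
    raw = propensity * profile.response(repetition) + noise
    score = int(np.clip(math.floor(raw + 0.5), 0, 4))
    return SymptomAnnotation(symptom, score, profile.participant_id, task.task_id, repetition)


# ---------------------------------------------------------------------------
# kinematics


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def synthesize_kinematics(
    profile: ParticipantProfile,
    task: TaskSpec,
    scores: Mapping[str, int],
    duration: float,
    rng: np.random.Generator,
    config: GeneratorConfig,
) -> IdealMotion:
    """Ideal continuous-time hand motion on a dense uniform grid.

    The linear acceleration is the sum of a slowly reorienting gravity
    projection, the voluntary task oscillation (slowed and damped by the
    bradykinesia score, with a within-recording amplitude decrement), the
    tremor oscillation (4-6 Hz, amplitude set by the tremor score, slow
    amplitude modulation, random spatial orientation), and white process
    noise.  Angular velocity is built from the same oscillatory phases so
    the gyroscope carries the slowing signature.
    """
    lo, hi = config.duration_range
    if not lo <= duration <= hi:
        raise ValueError(f"duration {duration} s outside configured range [{lo}, {hi}]")
    tremor_score = int(scores.get("tremor", 0))
    brady_score = int(scores.get("bradykinesia", 0))

    m = int(round(duration * config.dense_rate))
    t = np.arange(m) / config.dense_rate

    # gravity with slowly varying orientation (hand re-orients over ~20-50 s)
    theta0 = rng.uniform(0.1, 0.9)
    psi0 = rng.uniform(0.0, 2 * np.pi)
    f_orient = rng.uniform(0.02, 0.06)
    theta = theta0 + 0.08 * np.sin(2 * np.pi * f_orient * t + rng.uniform(0, 2 * np.pi))
    psi = psi0 + 0.06 * np.sin(2 * np.pi * 0.7 * f_orient * t + rng.uniform(0, 2 * np.pi))
    gravity = G_MS2 * np.vstack(
        [np.sin(theta) * np.cos(psi), np.sin(theta) * np.sin(psi), np.cos(theta)]
    )

    # voluntary movement, slowed by bradykinesia
    slow = float(config.brady_slowing_by_score.get(brady_score, min(config.brady_slowing_by_score.values())))
    tempo = rng.uniform(*config.voluntary_freq_jitter)
    f_vol = task.base_frequency * tempo * slow
    decay = np.clip(1.0 - config.brady_decrement * brady_score * (t / max(duration, 1e-9)), 0.2, None)
    phase_vol = 2 * np.pi * f_vol * t + rng.uniform(0, 2 * np.pi)
    amp_accel = task.base_amplitude * slow**config.brady_accel_exponent
    u_acc = _random_unit(rng)
    voluntary_accel = np.outer(u_acc, amp_accel * decay * np.sin(phase_vol))
    omega = GYRO_GAIN_BY_ARCHETYPE[task.archetype] * slow**config.brady_gyro_exponent
    u_gyr = _random_unit(rng)
    voluntary_gyro = np.outer(u_gyr, omega * decay * np.cos(phase_vol))

    # tremor
    f_trem = rng.uniform(*config.tremor_band)
    amp_trem = float(config.tremor_amp_by_score.get(tremor_score, max(config.tremor_amp_by_score.values())))
    modulation = 1.0 + 0.3 * np.sin(2 * np.pi * 0.25 * t + rng.uniform(0, 2 * np.pi))
    phase_trem = 2 * np.pi * f_trem * t + rng.uniform(0, 2 * np.pi)
    u_trem = _random_unit(rng)
    tremor_accel = np.outer(u_trem, amp_trem * modulation * np.sin(phase_trem))
    u_trem_g = _random_unit(rng)
    tremor_gyro = np.outer(u_trem_g, TREMOR_GYRO_GAIN * amp_trem * modulation * np.cos(phase_trem))

    accel = gravity + voluntary_accel + tremor_accel + rng.normal(0.0, 0.02, (3, m))
    gyro = voluntary_gyro + tremor_gyro + rng.normal(0.0, 0.2, (3, m))
    return IdealMotion(timestamps=t, accel=accel, gyro=gyro, rate=config.dense_rate)


# ---------------------------------------------------------------------------
# sensor model


def apply_sensor_model(
    ideal: IdealMotion,
    device: str,
    config: GeneratorConfig,
    rng: np.random.Generator,
    participant_id: str = "P00",
    task_id: str = "task",
    repetition: int = 1,
) -> SensorRecording:
    """Sample the ideal motion through an imperfect device.

    Applies timestamp jitter, independent per-sample dropout, additive
    measurement noise, and range clipping.  The watch sees the same motion
    slightly attenuated (wrist vs hand placement), with its own noise and no
    gyroscope.
    """
    if device not in DEVICES:
        raise ValueError(f"unknown device {device!r}")
    rate = config.hand_rate if device == "hand_sensor" else config.watch_rate
    t_end = float(ideal.timestamps[-1])
    n = int(math.floor(t_end * rate)) + 1
    base_t = np.arange(n) / rate
    if config.timestamp_jitter_sd > 0:
        jitter = rng.normal(0.0, config.timestamp_jitter_sd, n)
        # keep jitter below 40% of a sample period so timestamps stay
        # strictly increasing without re-sorting
        jitter = np.clip(jitter, -0.4 / rate, 0.4 / rate)
    else:
        jitter = np.zeros(n)
    t = np.clip(base_t + jitter, 0.0, t_end)
    t[0], t[-1] = base_t[0], base_t[-1]

    keep = rng.random(n) >= config.sample_drop_prob
    keep[0] = keep[-1] = True  # preserve the recorded span
    t = t[keep]

    accel_ms2 = np.vstack([np.interp(t, ideal.timestamps, ch) for ch in ideal.accel])
    accel_g = accel_ms2 / G_MS2
    if device == "watch":
        accel_g = config.watch_attenuation * accel_g
    accel_g = accel_g + rng.normal(0.0, config.noise_sd, accel_g.shape)
    accel_g = np.clip(accel_g, -config.accel_range, config.accel_range)

    gyro = None
    if device == "hand_sensor":
        gyro = np.vstack([np.interp(t, ideal.timestamps, ch) for ch in ideal.gyro])
        gyro = gyro + rng.normal(0.0, config.gyro_noise_sd, gyro.shape)
        gyro = np.clip(gyro, -config.gyro_range, config.gyro_range)

    return SensorRecording(
        device=device,
        participant_id=participant_id,
        task_id=task_id,
        repetition=repetition,
        timestamps=t,
        accel=accel_g,
        gyro=gyro,
        nominal_rate=rate,
        native_rate=rate,
    )


# ---------------------------------------------------------------------------
# dataset


def generate_annotations(config: GeneratorConfig) -> list[SymptomAnnotation]:
    """Clinician annotations only, without synthesizing any signals.

    Uses the same per-(participant, task, repetition) random streams as
    :func:`generate_dataset`, and the scoring draws come first in each
    stream, so the returned annotations are identical to the ones
    ``generate_dataset`` would produce for the same config.
    """
    config.validate()
    profiles = generate_cohort(config)
    annotations: list[SymptomAnnotation] = []
    for p_idx, profile in enumerate(profiles):
        for t_idx, task in enumerate(config.tasks):
            for rep in range(1, config.n_repetitions + 1):
                rng = _rng_for(config, 1, p_idx, t_idx, rep)
                for symptom in SYMPTOMS:
                    ann = score_task(profile, task, rep, symptom, rng, config.score_noise_sd)
                    if ann is not None:
                        annotations.append(ann)
    return annotations


def generate_dataset(
    config: GeneratorConfig,
) -> tuple[list[SensorRecording], list[SymptomAnnotation]]:
    """Generate the full cohort dataset.

    Returns one hand-sensor and one watch recording per participant x task x
    repetition, plus the clinician annotations (bradykinesia annotations are
    absent for tasks where it cannot be scored).  Fully reproducible from
    ``config.seed``.
    """
    config.validate()
    profiles = generate_cohort(config)
    recordings: list[SensorRecording] = []
    annotations: list[SymptomAnnotation] = []
    for p_idx, profile in enumerate(profiles):
        for t_idx, task in enumerate(config.tasks):
            for rep in range(1, config.n_repetitions + 1):
                rng = _rng_for(config, 1, p_idx, t_idx, rep)
                scores: dict[str, int] = {}
                for symptom in SYMPTOMS:
                    ann = score_task(profile, task, rep, symptom, rng, config.score_noise_sd)
                    if ann is not None:
                        annotations.append(ann)
                        scores[symptom] = ann.score
                duration = float(rng.uniform(*config.duration_range))
                ideal = synthesize_kinematics(profile, task, scores, duration, rng, config)
                for device in DEVICES:
                    recordings.append(
                        apply_sensor_model(
                            ideal,
                            device,
                            config,
                            rng,
                            participant_id=profile.participant_id,
                            task_id=task.task_id,
                            repetition=rep,
                        )
                    )
    return recordings, annotations


def annotation_index(
    annotations: Sequence[SymptomAnnotation],
) -> dict[tuple[str, str, int], dict[str, int]]:
    """Map (participant, task, repetition) -> {symptom: score}."""
    index: dict[tuple[str, str, int], dict[str, int]] = {}
    for ann in annotations:
        key = (ann.participant_id, ann.task_id, ann.repetition)
        index.setdefault(key, {})[ann.symptom] = ann.score
    return index
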