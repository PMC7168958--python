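"""Per-clip feature set: 74 features per sensor modality across 5 categories.

Categories (letter codes used throughout):

* ``T`` time domain — rms, range, mean, variance, skew, excess kurtosis;
* ``F`` frequency domain — dominant frequency, relative magnitude of the
  dominant bin, and spectral moments (mean/sd/skew/kurtosis of frequency
  under the normalized power spectral density);
* ``E`` sample entropy — SampEn(m=2, r=0.2*SD);
* ``C`` cross-correlation — peak and signed lag of the normalized
  cross-correlation of each axis pair (tri-axial only);
* ``D`` derivative — moments of the forward-differenced signal.

Each category is computed on the three axes and on the per-sample Euclidean
magnitude (except C, which is inherently pairwise), giving per modality
57 tri-axial + 17 magnitude = 74 features, or 148 with both accelerometer
and gyroscope.  Feature names encode modality, source, category, and
statistic, e.g. ``accel_x_T_rms`` or ``gyro_mag_F_psd_mean``.

Moment conventions are uniform across categories: population moments,
excess kurtosis, and zero skew/kurtosis for constant (zero-variance)
signals.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import periodogram

from .preprocess import Clip

__all__ = [
    "FeatureVector",
    "MissingModalityError",
    "CATEGORIES",
    "MODALITIES",
    "feature_names",
    "magnitude",
    "time_features",
    "frequency_features",
    "sample_entropy",
    "correlation_features",
    "derivative_features",
    "extract_features",
    "extract_feature_table",
    "time_feature_sets",
]

CATEGORIES = ("T", "F", "E", "C", "D")
MODALITIES = ("accel", "gyro")
AXES = ("x", "y", "z")
PAIRS = ("xy", "xz", "yz")
TIME_STATS = ("rms", "range", "mean", "variance", "skew", "kurtosis")
FREQ_STATS = ("dom_freq", "rel_mag", "psd_mean", "psd_sd", "psd_skew", "psd_kurtosis")
DERIV_STATS = ("mean", "sd", "skew", "kurtosis")

SAMPEN_M = 2
SAMPEN_R_FACTOR = 0.2


class MissingModalityError(KeyError):
    """A requested sensor modality is absent from the clip (e.g. watch gyro)."""


@dataclass
class FeatureVector:
    """Ordered named feature values for one clip."""

    clip_id: str
    values: dict[str, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.values)

    def as_array(self) -> np.ndarray:
        return np.fromiter(self.values.values(), dtype=float, count=len(self.values))


def feature_names(
    categories: Iterable[str] = CATEGORIES,
    modalities: Iterable[str] = MODALITIES,
    magnitude_only: bool = False,
) -> list[str]:
    """Deterministic feature-name ordering for the requested selection.

    ``magnitude_only`` keeps only magnitude-based features, except the six
    cross-correlation features per modality, which have no magnitude
    counterpart and are retained as-is.
    """
    cats = [c for c in CATEGORIES if c in set(categories)]
    mods = [m for m in MODALITIES if m in set(modalities)]
    sources = ("mag",) if magnitude_only else (*AXES, "mag")
    names: list[str] = []
    for mod in mods:
        for cat in cats:
            if cat == "T":
                names += [f"{mod}_{s}_T_{st}" for s in sources for st in TIME_STATS]
            elif cat == "F":
                names += [f"{mod}_{s}_F_{st}" for s in sources for st in FREQ_STATS]
            elif cat == "E":
                names += [f"{mod}_{s}_E_sampen" for s in sources]
            elif cat == "C":
                names += [f"{mod}_{p}_C_{st}" for p in PAIRS for st in ("peak", "lag")]
            elif cat == "D":
                names += [f"{mod}_{s}_D_{st}" for s in sources for st in DERIV_STATS]
    return names


# ---------------------------------------------------------------------------
# elementary statistics


def _pop_moments(v: np.ndarray) -> tuple[float, float, float, float]:
    """(mean, variance, skew, excess kurtosis), population convention.

    Zero-variance input yields skew 0 and kurtosis 0.
    """
    v = np.asarray(v, float)
    mean = float(v.mean())
    d = v - mean
    var = float(np.mean(d * d))
    # a numerically-constant signal (e.g. the exact difference of a ramp)
    # leaves rounding noise of order eps * |mean| in the deviations; its
    # higher moments are meaningless, so apply the degenerate convention
    if var <= (1e-12 * max(abs(mean), 1.0e-300)) ** 2 or var == 0.0:
        return mean, var, 0.0, 0.0
    m3 = float(np.mean(d**3))
    m4 = float(np.mean(d**4))
    return mean, var, m3 / var**1.5, m4 / var**2 - 3.0


def magnitude(triaxial: np.ndarray) -> np.ndarray:
    """Per-sample Euclidean norm of a 3 x W signal."""
    triaxial = np.asarray(triaxial, float)
    if triaxial.ndim != 2 or triaxial.shape[0] != 3:
        raise ValueError("expected a 3 x W array")
    return np.sqrt(np.sum(triaxial * triaxial, axis=0))


def time_features(signal: np.ndarray) -> tuple[float, ...]:
    """(rms, range, mean, variance, skew, kurtosis)."""
    signal = np.asarray(signal, float)
    if signal.size < 2:
        raise ValueError("time features need at least 2 samples")
    mean, var, skew, kurt = _pop_moments(signal)
    rms = float(np.sqrt(np.mean(signal * signal)))
    rng = float(np.ptp(signal))
    return rms, rng, mean, var, skew, kurt


def frequency_features(signal: np.ndarray, rate: float) -> tuple[float, ...]:
    """(dominant_freq, relative_magnitude, psd_mean, psd_sd, psd_skew, psd_kurtosis).

    The PSD is a Hann-windowed full-clip periodogram of the mean-removed
    signal; the 0 Hz bin is excluded.  ``relative_magnitude`` is the power
    in the dominant bin divided by the total power.  The moment features
    treat the normalized PSD as a probability mass over frequency bins, so
    ``psd_mean`` is the spectral centroid.  An all-zero signal returns all
    zeros by convention.
    """
    signal = np.asarray(signal, float)
    if signal.size < 8:
        raise ValueError("frequency features need at least 8 samples")
    if rate <= 0:
        raise ValueError("rate must be positive")
    x = signal - signal.mean()
    if not np.any(x):
        return 0.0, 0.0, 0.0, 0.0, 0.0, 0.0
    f, p = periodogram(x, fs=rate, window="hann", detrend=False)
    f, p = f[1:], p[1:]
    total = p.sum()
    if total <= 0:
        return 0.0, 0.0, 0.0, 0.0, 0.0, 0.0
    k = int(np.argmax(p))
    q = p / total
    mu = float(np.dot(f, q))
    d = f - mu
    var = float(np.dot(d * d, q))
    if var > 0:
        sd = var**0.5
        skew = float(np.dot(d**3, q)) / var**1.5
        kurt = float(np.dot(d**4, q)) / var**2 - 3.0
    else:
        sd, skew, kurt = 0.0, 0.0, 0.0
    return float(f[k]), float(p[k] / total), mu, sd, skew, kurt


def sample_entropy(
    signal: np.ndarray, m: int = SAMPEN_M, r: float | None = None
) -> float:
    """Sample entropy SampEn(m, r) with Chebyshev template matching.

    ``r`` defaults to 0.2 x SD of the clip.  Counts pairs of distinct
    templates (self-matches excluded, each unordered pair once) of length
    ``m`` (B) and ``m + 1`` (A) within tolerance ``r``, using the same
    ``n - m`` template offsets for both lengths, and returns ``-ln(A / B)``.
    A constant signal returns 0 (every pair matches at both lengths).  When
    A or B is zero the entropy is undefined; the documented cap
    ``ln(nt * (nt - 1))`` (the largest value resolvable from ``nt``
    templates) is returned instead.
    """
    x = np.asarray(signal, float)
    n = x.size
    if n <= m + 1:
        raise ValueError(f"need more than m + 1 = {m + 1} samples, got {n}")
    if r is None:
        r = SAMPEN_R_FACTOR * float(x.std())
    nt = n - m
    if r <= 0:
        # zero tolerance: only exactly-repeating templates match; constant
        # signals match everywhere, giving A/B = 1
        if np.all(x == x[0]):
            return 0.0
    cap = float(np.log(nt * (nt - 1))) if nt > 1 else 0.0
    # pairwise distances between scalar samples, reused for both template
    # lengths via shifted maxima; the matrices are symmetric with a zero
    # diagonal, so unordered pair counts are (total - diagonal) / 2
    d0 = np.abs(x[:, None] - x[None, :])
    dm = d0[:nt, :nt]
    for k in range(1, m):
        dm = np.maximum(dm, d0[k : k + nt, k : k + nt])
    b = (int(np.count_nonzero(dm <= r)) - nt) // 2
    dm1 = np.maximum(dm, d0[m : m + nt, m : m + nt])
    a = (int(np.count_nonzero(dm1 <= r)) - nt) // 2
    if b == 0 or a == 0:
        return cap
    return float(-np.log(a / b))


def correlation_features(triaxial: np.ndarray, rate: float) -> tuple[float, ...]:
    """Peak and signed lag (s) of normalized cross-correlation per axis pair.

    Axis signals are mean-removed and the cross-correlation over all lags is
    normalized by the product of the axis energies, so identical axes give a
    peak of exactly 1 at lag 0.  Ties are broken toward the smallest \\|lag\\|
    (then toward the negative lag).  A zero-variance axis yields peak 0,
    lag 0 by convention.  Order: (peak_xy, lag_xy, peak_xz, lag_xz,
    peak_yz, lag_yz).
    """
    triaxial = np.asarray(triaxial, float)
    if triaxial.ndim != 2 or triaxial.shape[0] != 3:
        raise ValueError("expected a 3 x W array")
    w = triaxial.shape[1]
    if w < 2:
        raise ValueError("correlation features need at least 2 samples")
    centered = triaxial - triaxial.mean(axis=1, keepdims=True)
    energies = np.sqrt(np.sum(centered * centered, axis=1))
    lags = np.arange(-(w - 1), w)
    out: list[float] = []
    for i, j in ((0, 1), (0, 2), (1, 2)):
        if energies[i] == 0.0 or energies[j] == 0.0:
            out += [0.0, 0.0]
            continue
        c = np.correlate(centered[i], centered[j], mode="full") / (energies[i] * energies[j])
        peak = float(c.max())
        ties = lags[c >= peak - 1e-12]
        lag = int(ties[np.lexsort((ties, np.abs(ties)))[0]])
        out += [peak, lag / rate]
    return tuple(out)


def derivative_features(signal: np.ndarray, rate: float) -> tuple[float, ...]:
    """(mean, sd, skew, kurtosis) of the forward-difference derivative."""
    signal = np.asarray(signal, float)
    if signal.size < 3:
        raise ValueError("derivative features need at least 3 samples")
    d = np.diff(signal) * rate
    mean, var, skew, kurt = _pop_moments(d)
    return mean, float(np.sqrt(var)), skew, kurt


# ---------------------------------------------------------------------------
# per-clip assembly


def _sources(sig: np.ndarray, mag: np.ndarray, magnitude_only: bool):
    if magnitude_only:
        return (("mag", mag),)
    return (("x", sig[0]), ("y", sig[1]), ("z", sig[2]), ("mag", mag))


def _extract_into(
    values: dict[str, float],
    mod: str,
    sig: np.ndarray,
    rate: float,
    cats: Sequence[str],
    magnitude_only: bool,
) -> None:
    mag = magnitude(sig)  # shared preliminary across categories
    srcs = _sources(sig, mag, magnitude_only)
    for cat in cats:
        if cat == "T":
            for s, v in srcs:
                for st, val in zip(TIME_STATS, time_features(v)):
                    values[f"{mod}_{s}_T_{st}"] = val
        elif cat == "F":
            for s, v in srcs:
                for st, val in zip(FREQ_STATS, frequency_features(v, rate)):
                    values[f"{mod}_{s}_F_{st}"] = val
        elif cat == "E":
            for s, v in srcs:
                values[f"{mod}_{s}_E_sampen"] = sample_entropy(v)
        elif cat == "C":
            vals = correlation_features(sig, rate)
            for k, p in enumerate(PAIRS):
                values[f"{mod}_{p}_C_peak"] = vals[2 * k]
                values[f"{mod}_{p}_C_lag"] = vals[2 * k + 1]
        elif cat == "D":
            for s, v in srcs:
                for st, val in zip(DERIV_STATS, derivative_features(v, rate)):
                    values[f"{mod}_{s}_D_{st}"] = val


def extract_features(
    clip: Clip,
    categories: Iterable[str] = CATEGORIES,
    modalities: Iterable[str] = MODALITIES,
    magnitude_only: bool = False,
) -> FeatureVector:
    """Assemble the named feature vector for one clip.

    With all categories and both modalities this yields 148 features; one
    modality yields 74; ``magnitude_only`` with one modality yields 23
    (17 magnitude features plus the 6 retained tri-axial correlation
    features).
    """
    cats = [c for c in CATEGORIES if c in set(categories)]
    mods = [m for m in MODALITIES if m in set(modalities)]
    fv = FeatureVector(clip_id=clip.clip_id)
    for mod in mods:
        sig = clip.accel if mod == "accel" else clip.gyro
        if sig is None:
            raise MissingModalityError(
                f"clip from device {clip.device!r} has no {mod} channels"
            )
        _extract_into(fv.values, mod, np.asarray(sig, float), clip.rate, cats, magnitude_only)
    return fv


def extract_feature_table(
    clips: Sequence[Clip],
    categories: Iterable[str] = CATEGORIES,
    modalities: Iterable[str] = MODALITIES,
    magnitude_only: bool = False,
):
    """Feature matrix over valid clips as a pandas DataFrame.

    One row per valid clip: provenance columns (``clip_id``, ``device``,
    ``participant``, ``task``, ``repetition``, ``start_time``), score
    columns (``tremor_score``, ``brady_score`` — the latter NaN where
    bradykinesia was not scored), then the feature columns in registry
    order.
    """
    import pandas as pd

    names = feature_names(categories, modalities, magnitude_only)
    rows = []
    for clip in clips:
        if not clip.valid:
            continue
        fv = extract_features(clip, categories, modalities, magnitude_only)
        row = {
            "clip_id": clip.clip_id,
            "device": clip.device,
            "participant": clip.participant_id,
            "task": clip.task_id,
            "repetition": clip.repetition,
            "start_time": clip.start_time,
            "tremor_score": clip.scores.get("tremor", np.nan),
            "brady_score": clip.scores.get("bradykinesia", np.nan),
        }
        row.update(fv.values)
        rows.append(row)
    meta = [
        "clip_id",
        "device",
        "participant",
        "task",
        "repetition",
        "start_time",
        "tremor_score",
        "brady_score",
    ]
    return pd.DataFrame(rows, columns=meta + names)


def time_feature_sets(
    clips: Sequence[Clip],
    categories: Iterable[str],
    repeats: int = 5,
    modalities: Iterable[str] = ("accel",),
    magnitude_only: bool = False,
) -> float:
    """Median wall-clock time (ms) to extract a category combination.

    Times the extraction of the requested categories over the fixed clip
    batch, ``repeats`` times, and returns the median in milliseconds.
    Preliminaries shared between categories (the signal magnitude) are
    charged once per combination.  The empty combination costs 0 ms.
    """
    cats = [c for c in CATEGORIES if c in set(categories)]
    if not cats or not clips:
        return 0.0
    mods = list(modalities)
    times = []
    for _ in range(max(repeats, 1)):
        t0 = time.perf_counter()
        for clip in clips:
            values: dict[str, float] = {}
            for mod in mods:
                sig = clip.accel if mod == "accel" else clip.gyro
                if sig is None:
                    raise MissingModalityError(mod)
                _extract_into(values, mod, np.asarray(sig, float), clip.rate, cats, magnitude_only)
        times.append((time.perf_counter() - t0) * 1000.0)
    return float(np.median(times))
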