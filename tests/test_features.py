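"""Feature definitions: exact counts, hand-computed values, naive oracles."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pdwear.features import (
    CATEGORIES,
    MissingModalityError,
    correlation_features,
    derivative_features,
    extract_features,
    feature_names,
    frequency_features,
    magnitude,
    sample_entropy,
    time_features,
    time_feature_sets,
)


# ---------------------------------------------------------------------------
# naive reference implementations (kept deliberately independent of the
# vectorized production code)


def brute_sample_entropy(x, m=2, r=None):
    x = np.asarray(x, float)
    n = x.size
    if r is None:
        r = 0.2 * x.std()
    nt = n - m
    if r <= 0 and np.all(x == x[0]):
        return 0.0
    a = b = 0
    for i in range(nt):
        for j in range(i + 1, nt):
            dm = max(abs(x[i + k] - x[j + k]) for k in range(m))
            if dm <= r:
                b += 1
                if max(dm, abs(x[i + m] - x[j + m])) <= r:
                    a += 1
    cap = math.log(nt * (nt - 1))
    if a == 0 or b == 0:
        return cap
    return -math.log(a / b)


def brute_xcorr(a, b, rate):
    a = np.asarray(a, float) - np.mean(a)
    b = np.asarray(b, float) - np.mean(b)
    ea = math.sqrt(np.sum(a * a))
    eb = math.sqrt(np.sum(b * b))
    if ea == 0 or eb == 0:
        return 0.0, 0.0
    w = a.size
    best = (-np.inf, 0)
    for lag in range(-(w - 1), w):
        s = 0.0
        for n in range(w):
            k = n - lag
            if 0 <= k < w:
                s += a[n] * b[k]
        c = s / (ea * eb)
        if c > best[0] + 1e-12 or (
            abs(c - best[0]) <= 1e-12
            and (abs(lag), lag) < (abs(best[1]), best[1])
        ):
            best = (c, lag)
    return best[0], best[1] / rate


class TestCounts:
    def test_category_counts_per_source(self):
        per_cat_tri = {"T": 18, "F": 18, "E": 3, "C": 6, "D": 12}
        per_cat_mag = {"T": 6, "F": 6, "E": 1, "C": 0, "D": 4}
        for cat in CATEGORIES:
            names = feature_names([cat], ["accel"])
            tri = [n for n in names if n.split("_")[1] in ("x", "y", "z", "xy", "xz", "yz")]
            mag = [n for n in names if n.split("_")[1] == "mag"]
            assert len(tri) == per_cat_tri[cat], cat
            assert len(mag) == per_cat_mag[cat], cat

    def test_totals(self):
        assert len(feature_names(modalities=["accel"])) == 74
        assert len(feature_names()) == 148
        assert len(feature_names(modalities=["accel"], magnitude_only=True)) == 23

    def test_extracted_counts_match_registry(self, hand_clips):
        clip = hand_clips[0]
        assert len(extract_features(clip)) == 148
        assert len(extract_features(clip, modalities=["accel"])) == 74
        assert len(extract_features(clip, modalities=["accel"], magnitude_only=True)) == 23
        assert list(extract_features(clip).values) == feature_names()

    def test_gyro_requested_on_watch_clip(self, watch_clips):
        with pytest.raises(MissingModalityError):
            extract_features(watch_clips[0], modalities=["gyro"])

    def test_all_features_finite_on_dataset(self, hand_table):
        values = hand_table[feature_names()].to_numpy(float)
        assert np.all(np.isfinite(values))


class TestMagnitude:
    def test_three_four_zero_gives_five(self):
        tri = np.tile([[3.0], [4.0], [0.0]], (1, 10))
        np.testing.assert_allclose(magnitude(tri), 5.0)

    def test_single_axis_gives_absolute_value(self):
        tri = np.vstack([-2.0 * np.ones(5), np.zeros(5), np.zeros(5)])
        np.testing.assert_allclose(magnitude(tri), 2.0)

    def test_elementwise_identity(self, rng):
        tri = rng.normal(size=(3, 50))
        np.testing.assert_allclose(
            magnitude(tri) ** 2, (tri**2).sum(axis=0), rtol=1e-12
        )


class TestTimeFeatures:
    def test_hand_computed_moments(self):
        rms, rng_, mean, var, skew, kurt = time_features([1, 2, 3, 4])
        assert mean == 2.5
        assert rng_ == 3.0
        assert rms == pytest.approx(math.sqrt(7.5))
        assert var == 1.25
        assert skew == 0.0
        assert kurt == pytest.approx(-1.36)

    def test_constant_signal_conventions(self):
        rms, rng_, mean, var, skew, kurt = time_features([-3.0] * 10)
        assert (rms, rng_, mean, var, skew, kurt) == (3.0, 0.0, -3.0, 0.0, 0.0, 0.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=64))
    def test_rms_squared_is_mean_squared_plus_variance(self, xs):
        rms, _, mean, var, _, _ = time_features(xs)
        assert rms**2 == pytest.approx(mean**2 + var, abs=1e-6 * max(1.0, rms**2))


class TestFrequencyFeatures:
    def test_pure_tone_dominant_bin(self):
        rate, n = 62.5, 312
        t = np.arange(n) / rate
        x = np.sin(2 * np.pi * 5.0 * t)
        dom, rel, *_ = frequency_features(x, rate)
        assert dom == pytest.approx(5.0, abs=rate / n + 1e-9)
        # the Hann taper spreads an on-bin tone over three bins with power
        # weights 1/4, 1/16, 1/16, so the dominant bin holds at most 2/3 of
        # the total; just off-bin it stays close to that bound
        assert rel > 0.6

    def test_white_noise_centroid_near_quarter_rate(self, rng):
        rate = 62.5
        centroids = [
            frequency_features(rng.normal(size=2048), rate)[2] for _ in range(5)
        ]
        assert np.mean(centroids) == pytest.approx(rate / 4, rel=0.1)

    def test_two_equal_tones_centroid_at_midpoint(self):
        rate, n = 62.5, 4096
        t = np.arange(n) / rate
        x = np.sin(2 * np.pi * 2.0 * t) + np.sin(2 * np.pi * 6.0 * t)
        assert frequency_features(x, rate)[2] == pytest.approx(4.0, abs=0.1)

    def test_zero_signal_convention(self):
        assert frequency_features(np.zeros(64), 62.5) == (0.0,) * 6


class TestSampleEntropy:
    def test_constant_signal_is_zero(self):
        assert sample_entropy(np.full(50, 2.5)) == 0.0

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(25):
            w = int(rng.integers(20, 120))
            x = rng.normal(size=w)
            assert sample_entropy(x) == pytest.approx(brute_sample_entropy(x), abs=1e-12)

    def test_gaussian_noise_band(self, rng):
        vals = [sample_entropy(rng.normal(size=312)) for _ in range(5)]
        assert all(1.5 < v < 3.0 for v in vals)

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError):
            sample_entropy(np.ones(3), m=2)


class TestCorrelationFeatures:
    RATE = 62.5

    def test_identical_axes_peak_one_lag_zero(self, rng):
        x = rng.normal(size=64)
        tri = np.vstack([x, x, rng.normal(size=64)])
        vals = correlation_features(tri, self.RATE)
        assert vals[0] == pytest.approx(1.0)
        assert vals[1] == 0.0

    def test_shifted_tone_recovers_lag(self):
        n, shift = 128, 10
        t = np.arange(n + shift)
        x = np.sin(2 * np.pi * 0.05 * t)
        tri = np.vstack([x[shift:], x[:n], np.random.default_rng(0).normal(size=n)])
        vals = correlation_features(tri, self.RATE)
        assert abs(vals[1]) == pytest.approx(shift / self.RATE)

    def test_zero_variance_axis_convention(self):
        tri = np.vstack([np.ones(16), np.arange(16.0), np.arange(16.0)])
        vals = correlation_features(tri, self.RATE)
        assert vals[0] == 0.0 and vals[1] == 0.0  # xy involves the flat axis

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(10):
            tri = rng.normal(size=(3, int(rng.integers(10, 60))))
            vals = correlation_features(tri, self.RATE)
            for k, (i, j) in enumerate(((0, 1), (0, 2), (1, 2))):
                peak, lag = brute_xcorr(tri[i], tri[j], self.RATE)
                assert vals[2 * k] == pytest.approx(peak, abs=1e-9)
                assert vals[2 * k + 1] == pytest.approx(lag, abs=1e-12)


class TestDerivativeFeatures:
    def test_linear_ramp(self):
        rate = 62.5
        t = np.arange(100) / rate
        mean, sd, skew, kurt = derivative_features(3.0 * t, rate)
        assert mean == pytest.approx(3.0)
        assert sd == pytest.approx(0.0, abs=1e-9)
        assert skew == 0.0 and kurt == 0.0

    def test_constant_signal(self):
        mean, sd, *_ = derivative_features(np.full(10, 7.0), 50.0)
        assert mean == 0.0 and sd == 0.0

    def test_matches_explicit_difference(self, rng):
        rate = 50.0
        x = rng.normal(size=80)
        d = np.diff(x) * rate
        mean, sd, skew, kurt = derivative_features(x, rate)
        assert mean == pytest.approx(d.mean())
        assert sd == pytest.approx(d.std())


class TestTremorDiscriminability:
    """The dominant-frequency feature separates tremor from movement.

    Checked on per-axis spectra: the Euclidean magnitude of a zero-mean
    oscillation is full-wave rectified, which doubles the carrier frequency,
    and score-0 clips of low-amplitude holds are noise-dominated — so the
    clean statements live on the axis features, per task type.
    """

    def test_axis_dominant_freq_tracks_tremor_band(self, hand_table):
        ax_cols = [f"accel_{a}_F_dom_freq" for a in "xyz"]
        hold = hand_table[hand_table.task == "arms_extended"]
        tremor_clips = hold[hold.tremor_score >= 2]
        assert len(tremor_clips) > 0
        assert 4.0 <= tremor_clips[ax_cols].to_numpy().mean() <= 6.0

    def test_movement_without_tremor_peaks_below_band(self, hand_table):
        ax_cols = [f"accel_{a}_F_dom_freq" for a in "xyz"]
        moving = hand_table[hand_table.task.isin(["walking", "pouring_water"])]
        quiet = moving[moving.tremor_score == 0]
        assert len(quiet) > 0
        assert quiet[ax_cols].to_numpy().mean() < 4.0


class TestTiming:
    def test_empty_combination_costs_nothing(self, hand_clips):
        assert time_feature_sets(hand_clips[:5], []) == 0.0

    def test_entropy_slowest_single_category(self, hand_clips):
        batch = hand_clips[:10]
        times = {c: time_feature_sets(batch, [c], repeats=3) for c in CATEGORIES}
        assert times["E"] == max(times.values())
        assert times["E"] > times["C"]

    def test_shared_preliminaries_make_timing_subadditive(self, hand_clips):
        batch = hand_clips[:10]
        t_tf = time_feature_sets(batch, ["T", "F"], repeats=5)
        t_t = time_feature_sets(batch, ["T"], repeats=5)
        t_f = time_feature_sets(batch, ["F"], repeats=5)
        assert t_tf <= 1.2 * (t_t + t_f)
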