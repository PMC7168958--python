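"""Sensitivity analyses over sensor sets, sampling rates, and feature sets.

Each experiment evaluates LOPO random-forest models under several conditions
on identical clip sets per fold (a paired design), then applies a one-way
repeated-measures ANOVA over folds x conditions and, when significant,
paired post-hoc t-tests with a Holm-Bonferroni family-wise correction at
alpha = 0.05.

The feature-set analysis additionally ranks all 31 non-empty category
combinations by average computation time and discards every combination
that does not outperform all cheaper ones — keeping only the Pareto
frontier of computation cost vs mean AUROC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist
from scipy.stats import t as t_dist

from . import features as _features
from .modeling import FoldResult, ModelConfig, evaluate_lopo
from .pipeline import build_feature_table, make_clips
from .synthdata import SensorRecording, SymptomAnnotation

__all__ = [
    "ALPHA",
    "SAMPLING_RATES",
    "FEATURE_ANALYSIS_RATE",
    "PairwiseTest",
    "ComparisonResult",
    "ParetoEntry",
    "rm_anova",
    "paired_t",
    "holm_bonferroni",
    "pareto_filter",
    "all_category_subsets",
    "sensor_set_experiment",
    "sampling_rate_experiment",
    "feature_set_experiment",
]

ALPHA = 0.05

#: candidate rates (Hz) for the sampling-rate analysis; the watch list
#: starts at its native 50 Hz
SAMPLING_RATES = (62.5, 50.0, 40.0, 30.0, 20.0, 10.0, 7.5, 5.0)

#: rate at which the feature-set analysis is run
FEATURE_ANALYSIS_RATE = 30.0


@dataclass
class PairwiseTest:
    pair: tuple[str, str]
    tail: str
    t: float
    raw_p: float
    adjusted_p: float = float("nan")
    significant: bool = False


@dataclass
class ComparisonResult:
    """Per-fold AUROC matrix across conditions plus the statistical tests."""

    factor: str
    conditions: list[str]
    fold_ids: list[str]
    auroc_matrix: np.ndarray  # folds x conditions
    anova_F: float
    anova_p: float
    pairwise: list[PairwiseTest] = field(default_factory=list)

    def condition_means(self) -> dict[str, float]:
        return {
            c: float(self.auroc_matrix[:, k].mean()) for k, c in enumerate(self.conditions)
        }

    def to_dict(self) -> dict:
        return {
            "factor": self.factor,
            "conditions": self.conditions,
            "fold_ids": self.fold_ids,
            "auroc_matrix": self.auroc_matrix.tolist(),
            "condition_means": self.condition_means(),
            "anova_F": self.anova_F,
            "anova_p": self.anova_p,
            "pairwise": [
                {
                    "pair": list(pw.pair),
                    "tail": pw.tail,
                    "t": pw.t,
                    "raw_p": pw.raw_p,
                    "adjusted_p": pw.adjusted_p,
                    "significant": pw.significant,
                }
                for pw in self.pairwise
            ],
        }


@dataclass
class ParetoEntry:
    """One feature-category combination on the cost/performance plane."""

    feature_categories: str  # e.g. "CEFT", letters sorted
    mean_time_ms: float
    mean_auroc: float
    retained: bool = False


# ---------------------------------------------------------------------------
# statistical machinery


def rm_anova(auroc_matrix: np.ndarray) -> tuple[float, float]:
    """One-way repeated-measures ANOVA over a folds x conditions matrix.

    Folds (left-out participants) are the subjects.  The F statistic is
    ``MS_condition / MS_(subject x condition)`` with degrees of freedom
    ``(k - 1, (n - 1)(k - 1))``; no sphericity correction is applied.
    Identical condition columns give F = 0, p = 1.
    """
    m = np.asarray(auroc_matrix, float)
    if m.ndim != 2 or m.shape[1] < 2 or m.shape[0] < 3:
        raise ValueError("need a complete matrix with >= 3 folds and >= 2 conditions")
    if np.any(~np.isfinite(m)):
        raise ValueError("matrix must be complete (finite)")
    n, k = m.shape
    grand = m.mean()
    ss_cond = n * float(np.sum((m.mean(axis=0) - grand) ** 2))
    ss_subj = k * float(np.sum((m.mean(axis=1) - grand) ** 2))
    ss_tot = float(np.sum((m - grand) ** 2))
    ss_err = max(ss_tot - ss_cond - ss_subj, 0.0)
    # snap rounding-noise sums of squares (identical columns leave SS of
    # order eps^2 relative to the total) to exact zero
    tol = 1e-24 * max(ss_tot, 1.0)
    ss_cond = 0.0 if ss_cond <= tol else ss_cond
    ss_err = 0.0 if ss_err <= tol else ss_err
    df1, df2 = k - 1, (n - 1) * (k - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    if ms_err == 0.0:
        if ms_cond == 0.0:
            return 0.0, 1.0
        return float("inf"), 0.0
    f_stat = ms_cond / ms_err
    return float(f_stat), float(f_dist.sf(f_stat, df1, df2))


def paired_t(
    a: Sequence[float] | np.ndarray,
    b: Sequence[float] | np.ndarray,
    tail: str = "greater",
) -> tuple[float, float]:
    """Paired t-test on ``a - b``.

    ``tail="greater"`` tests the one-sided alternative mean(a - b) > 0 with
    p = P(T_df >= t); ``tail="two_sided"`` doubles the corresponding tail.
    Zero-variance differences have no t distribution: all-zero differences
    return the neutral sentinel (t = 0, p = 0.5 one-tailed / 1.0 two-tailed)
    and constant nonzero differences return t = +/-inf with p 0 or 1
    accordingly.
    """
    if tail not in ("greater", "two_sided"):
        raise ValueError(f"unknown tail {tail!r}")
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need equal-length samples of size >= 3")
    d = a - b
    sd = d.std(ddof=1)
    n = d.size
    if sd <= 1e-12 * max(abs(float(d.mean())), np.abs(d).max(initial=0.0)):
        sd = 0.0
    if sd == 0.0:
        if d[0] == 0.0:
            return 0.0, 0.5 if tail == "greater" else 1.0
        t_stat = float(np.inf) if d[0] > 0 else float(-np.inf)
        if tail == "greater":
            return t_stat, 0.0 if d[0] > 0 else 1.0
        return t_stat, 0.0
    t_stat = float(d.mean() / (sd / np.sqrt(n)))
    if tail == "greater":
        p = float(t_dist.sf(t_stat, n - 1))
    else:
        p = float(2.0 * t_dist.sf(abs(t_stat), n - 1))
    return t_stat, p


def holm_bonferroni(
    raw_p: Sequence[float], alpha: float = ALPHA
) -> tuple[list[float], list[bool]]:
    """Holm's step-down multiple-testing correction.

    Adjusted p-values are the running maximum of ``(m - i) * p_(i)`` over
    the ascending order statistics, capped at 1; a hypothesis is rejected
    iff its adjusted p is <= alpha.
    """
    p = np.asarray(raw_p, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 0.0
    for i, idx in enumerate(order):
        running = max(running, (m - i) * p[idx])
        adjusted[idx] = min(running, 1.0)
    reject = adjusted <= alpha
    return adjusted.tolist(), reject.tolist()


def pareto_filter(entries: Sequence[ParetoEntry]) -> list[ParetoEntry]:
    """Flag the cost/performance frontier.

    Entries are ordered by computation time (ties broken by the lexicographic
    category label, a stable perturbation); an entry is retained iff its
    AUROC strictly exceeds the AUROC of every lower-time entry, at full
    floating precision.  Retained entries therefore increase strictly in
    both time and AUROC.
    """
    ordered = sorted(entries, key=lambda e: (e.mean_time_ms, e.feature_categories))
    best = -np.inf
    out = []
    for e in ordered:
        retained = e.mean_auroc > best
        best = max(best, e.mean_auroc)
        out.append(
            ParetoEntry(e.feature_categories, e.mean_time_ms, e.mean_auroc, retained)
        )
    return out


def all_category_subsets() -> list[str]:
    """The 31 non-empty feature-category combinations, as sorted letter labels."""
    cats = sorted(_features.CATEGORIES)
    subsets = []
    for mask in range(1, 1 << len(cats)):
        subsets.append("".join(c for i, c in enumerate(cats) if mask >> i & 1))
    return subsets


# ---------------------------------------------------------------------------
# experiment drivers


def _fold_auroc_map(
    table: pd.DataFrame, feature_cols: Sequence[str], config: ModelConfig
) -> dict[str, float]:
    return {
        r.left_out_participant: r.auroc
        for r in evaluate_lopo(table, feature_cols, config)
        if r.evaluable
    }


def _assemble(
    factor: str,
    condition_maps: dict[str, dict[str, float]],
    alpha: float = ALPHA,
) -> tuple[ComparisonResult, list[str]]:
    """Build the complete folds x conditions matrix over common folds."""
    conditions = list(condition_maps)
    common = sorted(set.intersection(*(set(m) for m in condition_maps.values())))
    if len(common) < 3:
        raise ValueError("fewer than 3 folds evaluable under every condition")
    matrix = np.array(
        [[condition_maps[c][p] for c in conditions] for p in common], float
    )
    f_stat, p_val = rm_anova(matrix)
    return (
        ComparisonResult(
            factor=factor,
            conditions=conditions,
            fold_ids=common,
            auroc_matrix=matrix,
            anova_F=f_stat,
            anova_p=p_val,
        ),
        common,
    )


def _run_posthoc(
    result: ComparisonResult,
    pairs: Sequence[tuple[str, str, str]],
    alpha: float = ALPHA,
) -> None:
    """Attach Holm-corrected paired t-tests for the listed (a, b, tail) pairs."""
    cols = {c: result.auroc_matrix[:, k] for k, c in enumerate(result.conditions)}
    tests = []
    for a, b, tail in pairs:
        t_stat, p_raw = paired_t(cols[a], cols[b], tail)
        tests.append(PairwiseTest(pair=(a, b), tail=tail, t=t_stat, raw_p=p_raw))
    adjusted, reject = holm_bonferroni([t.raw_p for t in tests], alpha)
    for t, adj, rej in zip(tests, adjusted, reject):
        t.adjusted_p = adj
        t.significant = bool(rej)
    result.pairwise = tests


def sensor_set_experiment(
    recordings: Sequence[SensorRecording],
    annotations: Sequence[SymptomAnnotation],
    symptom: str,
    mode: str,
    target_rate: float | None = None,
    n_trees: int = 50,
    seed: int = 0,
    alpha: float = ALPHA,
) -> ComparisonResult:
    """Compare Combo / Accel / Gyro (hand sensor) and Watch conditions.

    The hand-sensor conditions share identical clips and differ only in the
    feature columns used; the watch condition uses the watch's own clips,
    paired with the hand conditions at the fold (participant) level.
    Post-hoc tests (run only when the ANOVA is significant) are the three
    one-tailed Combo-benefit comparisons plus the two-tailed Accel vs Watch
    hardware/placement comparison.
    """
    hand = build_feature_table(recordings, annotations, "hand_sensor", target_rate)
    watch = build_feature_table(recordings, annotations, "watch", target_rate)
    if hand.empty or watch.empty:
        raise ValueError("dataset must contain both hand_sensor and watch recordings")

    def cfg() -> ModelConfig:
        return ModelConfig(symptom=symptom, mode=mode, n_trees=n_trees, seed=seed)

    maps = {
        "Combo": _fold_auroc_map(hand, _features.feature_names(modalities=("accel", "gyro")), cfg()),
        "Accel": _fold_auroc_map(hand, _features.feature_names(modalities=("accel",)), cfg()),
        "Gyro": _fold_auroc_map(hand, _features.feature_names(modalities=("gyro",)), cfg()),
        "Watch": _fold_auroc_map(watch, _features.feature_names(modalities=("accel",)), cfg()),
    }
    result, _ = _assemble("sensor_set", maps, alpha)
    if result.anova_p < alpha:
        _run_posthoc(
            result,
            [
                ("Combo", "Accel", "greater"),
                ("Combo", "Gyro", "greater"),
                ("Combo", "Watch", "greater"),
                ("Accel", "Watch", "two_sided"),
            ],
            alpha,
        )
    return result


def preferred_modalities(symptom: str, device: str) -> tuple[str, ...]:
    """Sensor set carried into the rate and feature analyses.

    Accelerometer alone suffices for tremor; bradykinesia uses the combined
    accelerometer + gyroscope set.  The watch only has an accelerometer.
    """
    if device == "watch" or symptom == "tremor":
        return ("accel",)
    return ("accel", "gyro")


def sampling_rate_experiment(
    recordings: Sequence[SensorRecording],
    annotations: Sequence[SymptomAnnotation],
    symptom: str,
    mode: str,
    rates: Sequence[float] = SAMPLING_RATES,
    device: str = "hand_sensor",
    n_trees: int = 50,
    seed: int = 0,
    alpha: float = ALPHA,
) -> ComparisonResult:
    """Effect of downsampling on LOPO performance.

    Every candidate rate at or below the device's native rate is evaluated
    with the symptom's preferred sensor set; post-hoc one-tailed tests
    (original rate > lower rate), Holm-corrected, run when the ANOVA is
    significant.
    """
    native = max(r.native_rate for r in recordings if r.device == device)
    usable_rates = [r for r in rates if r <= native]
    modalities = preferred_modalities(symptom, device)
    cols = _features.feature_names(modalities=modalities)
    maps: dict[str, dict[str, float]] = {}
    for rate in usable_rates:
        table = build_feature_table(
            recordings, annotations, device,
            target_rate=None if rate == native else rate,
            modalities=modalities,
        )
        maps[f"{rate:g}"] = _fold_auroc_map(
            table,
            cols,
            ModelConfig(symptom=symptom, mode=mode, n_trees=n_trees, seed=seed,
                        modalities=modalities, sampling_rate=rate),
        )
    result, _ = _assemble("sampling_rate", maps, alpha)
    if result.anova_p < alpha:
        original = f"{usable_rates[0]:g}"
        pairs = [(original, f"{r:g}", "greater") for r in usable_rates[1:]]
        _run_posthoc(result, pairs, alpha)
    return result


def feature_set_experiment(
    recordings: Sequence[SensorRecording],
    annotations: Sequence[SymptomAnnotation],
    symptom: str,
    mode: str,
    magnitude_only: bool = False,
    target_rate: float = FEATURE_ANALYSIS_RATE,
    device: str = "hand_sensor",
    n_trees: int = 50,
    seed: int = 0,
    timing_repeats: int = 3,
    timing_batch: int = 40,
    alpha: float = ALPHA,
) -> tuple[list[ParetoEntry], ComparisonResult]:
    """Computation-cost vs performance trade-off over all category subsets.

    All 31 non-empty combinations of the 5 feature categories are timed on a
    fixed clip batch and scored by LOPO mean AUROC on data downsampled to
    ``target_rate``.  Combinations not on the cost/performance Pareto
    frontier are discarded; the retained sets enter a repeated-measures
    ANOVA, followed (if significant) by one-tailed tests of the
    highest-computation-time retained set against each other retained set.
    """
    modalities = preferred_modalities(symptom, device)
    clips = make_clips(recordings, annotations, device, target_rate=target_rate)
    table = _features.extract_feature_table(
        clips, modalities=modalities, magnitude_only=magnitude_only
    )
    batch = clips[: min(timing_batch, len(clips))]
    subset_labels = all_category_subsets()
    fold_maps: dict[str, dict[str, float]] = {}
    entries: list[ParetoEntry] = []
    for label in subset_labels:
        cats = tuple(label)
        cols = _features.feature_names(cats, modalities, magnitude_only)
        fold_maps[label] = _fold_auroc_map(
            table,
            cols,
            ModelConfig(symptom=symptom, mode=mode, n_trees=n_trees, seed=seed,
                        categories=cats, modalities=modalities,
                        magnitude_only=magnitude_only, sampling_rate=target_rate),
        )
        t_ms = _features.time_feature_sets(
            batch, cats, repeats=timing_repeats, modalities=modalities,
            magnitude_only=magnitude_only,
        )
        mean_auroc = float(np.mean(list(fold_maps[label].values())))
        entries.append(ParetoEntry(label, t_ms, mean_auroc))
    filtered = pareto_filter(entries)
    retained = [e.feature_categories for e in filtered if e.retained]
    result, _ = _assemble(
        "feature_set", {label: fold_maps[label] for label in retained}, alpha
    )
    if result.anova_p < alpha and len(retained) >= 2:
        slowest = max(
            (e for e in filtered if e.retained), key=lambda e: e.mean_time_ms
        ).feature_categories
        pairs = [(slowest, other, "greater") for other in retained if other != slowest]
        _run_posthoc(result, pairs, alpha)
    return filtered, result
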