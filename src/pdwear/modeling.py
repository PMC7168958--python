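"""Random-forest symptom classifiers under leave-one-participant-out CV.

Binary models classify symptom presence (clinical score >= 1); multiclass
models predict the 0-4 score.  Performance is the area under the ROC curve
(AUROC): the probability that a random positive clip is ranked above a
random negative one, ties counted one half.  Multiclass performance is the
prevalence-weighted average of one-vs-rest AUROCs over the classes present
in the left-out participant's data.

All cross-validation is leave-one-participant-out (LOPO): every clip of a
participant — including the 50%-overlapping windows — stays on one side of
each fold, so no subject's data ever leaks between training and testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier

from . import features as _features

__all__ = [
    "ModelConfig",
    "FoldResult",
    "make_labels",
    "lopo_folds",
    "binary_auroc",
    "multiclass_auroc",
    "fit_and_score",
    "evaluate_lopo",
    "summarize_folds",
]

logger = logging.getLogger(__name__)

DEFAULT_N_TREES = 50


@dataclass
class ModelConfig:
    """One classifier configuration.

    ``categories``/``modalities``/``magnitude_only`` select the feature
    columns; ``sampling_rate`` records the preprocessing rate the features
    were computed at (metadata only).
    """

    symptom: str = "tremor"
    mode: str = "binary"
    n_trees: int = DEFAULT_N_TREES
    seed: int = 0
    categories: tuple[str, ...] = _features.CATEGORIES
    modalities: tuple[str, ...] = _features.MODALITIES
    magnitude_only: bool = False
    sampling_rate: float | None = None

    def __post_init__(self) -> None:
        if self.symptom not in ("tremor", "bradykinesia"):
            raise ValueError(f"unknown symptom {self.symptom!r}")
        if self.mode not in ("binary", "multiclass"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass
class FoldResult:
    """Per-left-out-participant evaluation of one model configuration."""

    left_out_participant: str
    auroc: float
    per_class_auroc: dict[int, float] = field(default_factory=dict)
    class_weights: dict[int, float] = field(default_factory=dict)
    n_test: int = 0
    evaluable: bool = True


def make_labels(scores: Sequence[float] | np.ndarray, mode: str) -> np.ndarray:
    """Clip labels from clinical scores.

    Binary: symptom present (1) iff the clinician scored 1-4, absent (0)
    for score 0.  Multiclass: the 0-4 score itself.
    """
    scores = np.asarray(scores, float)
    if np.any(np.isnan(scores)):
        raise ValueError("labels requested for clips without a score")
    if mode == "binary":
        return (scores >= 1).astype(int)
    if mode == "multiclass":
        return scores.astype(int)
    raise ValueError(f"unknown mode {mode!r}")


def lopo_folds(participants: Sequence[str] | np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    """Leave-one-participant-out folds over clip-aligned participant ids.

    Returns one ``(train_idx, test_idx)`` pair per participant, in sorted
    participant order.  Train and test participant sets are disjoint and the
    test sets partition all clips.
    """
    participants = np.asarray(participants)
    unique = np.unique(participants)
    if unique.size < 2:
        raise ValueError("LOPO cross-validation needs at least 2 participants")
    folds = []
    for p in unique:
        test = np.flatnonzero(participants == p)
        train = np.flatnonzero(participants != p)
        folds.append((train, test))
    return folds


def binary_auroc(scores: Sequence[float] | np.ndarray, labels: Sequence[int] | np.ndarray) -> float:
    """Pairwise concordance probability (trapezoidal ROC area).

    ``P(score_pos > score_neg) + 0.5 * P(score_pos == score_neg)`` over all
    positive-negative pairs, computed via midranks.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("binary AUROC needs both classes present")
    ranks = rankdata(scores)  # midranks handle ties as half-concordant
    pos_rank_sum = float(ranks[labels == 1].sum())
    return (pos_rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def multiclass_auroc(
    proba: np.ndarray,
    classes: Sequence[int],
    labels: Sequence[int] | np.ndarray,
) -> tuple[float, dict[int, float], dict[int, float]]:
    """Prevalence-weighted one-vs-rest AUROC.

    ``proba`` is an (n, k) class-probability matrix with columns ordered as
    ``classes``.  For every class present in ``labels`` the one-vs-rest
    binary AUROC is computed from that class's probability column; classes
    absent from the test labels are skipped, and the weights are the test
    prevalences renormalized over the present classes.
    """
    proba = np.asarray(proba, float)
    labels = np.asarray(labels, int)
    classes = list(classes)
    present = np.unique(labels)
    if present.size < 2:
        raise ValueError("multiclass AUROC needs at least 2 classes in the labels")
    per_class: dict[int, float] = {}
    weights: dict[int, float] = {}
    for c in present:
        col = (
            proba[:, classes.index(c)]
            if c in classes
            else np.zeros(labels.size)  # class never seen in training
        )
        per_class[int(c)] = binary_auroc(col, (labels == c).astype(int))
        weights[int(c)] = float(np.mean(labels == c))
    total = sum(weights.values())
    weights = {c: w / total for c, w in weights.items()}
    weighted = float(sum(weights[c] * per_class[c] for c in per_class))
    return weighted, per_class, weights


def fit_and_score(
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    test_y: np.ndarray,
    config: ModelConfig,
    left_out: str = "",
) -> FoldResult:
    """Train one random forest and score the held-out participant.

    The forest has ``config.n_trees`` trees and a fixed seed, so repeated
    runs give identical fold AUROCs.  A binary fold whose test set contains
    a single class cannot be scored; it is returned with
    ``evaluable=False`` and a logged warning, and callers exclude it.
    """
    train_y = np.asarray(train_y, int)
    test_y = np.asarray(test_y, int)
    if np.unique(train_y).size < 2:
        raise ValueError("training data contains a single class")
    if np.unique(test_y).size < 2:
        logger.warning(
            "fold %s has a single test class; marked unevaluable", left_out or "<unnamed>"
        )
        return FoldResult(left_out, float("nan"), n_test=int(test_y.size), evaluable=False)
    model = RandomForestClassifier(
        n_estimators=config.n_trees, random_state=config.seed, n_jobs=1
    )
    model.fit(np.asarray(train_X, float), train_y)
    proba = model.predict_proba(np.asarray(test_X, float))
    classes = [int(c) for c in model.classes_]
    if config.mode == "binary":
        auroc = binary_auroc(proba[:, classes.index(1)], test_y)
        return FoldResult(left_out, auroc, n_test=int(test_y.size))
    weighted, per_class, weights = multiclass_auroc(proba, classes, test_y)
    return FoldResult(
        left_out, weighted, per_class_auroc=per_class, class_weights=weights,
        n_test=int(test_y.size),
    )


def evaluate_lopo(
    table: pd.DataFrame,
    feature_cols: Sequence[str],
    config: ModelConfig,
) -> list[FoldResult]:
    """LOPO evaluation of one configuration over a feature table.

    ``table`` is an :func:`pdwear.features.extract_feature_table` frame.
    Clips without a score for the requested symptom (bradykinesia on
    non-scorable tasks) are excluded before folding.
    """
    score_col = "tremor_score" if config.symptom == "tremor" else "brady_score"
    usable = table[~table[score_col].isna()].reset_index(drop=True)
    labels = make_labels(usable[score_col].to_numpy(), config.mode)
    X = usable[list(feature_cols)].to_numpy(float)
    participants = usable["participant"].to_numpy()
    results = []
    for train, test in lopo_folds(participants):
        results.append(
            fit_and_score(
                X[train], labels[train], X[test], labels[test], config,
                left_out=str(participants[test][0]),
            )
        )
    return results


def summarize_folds(results: Iterable[FoldResult]) -> dict:
    """Mean AUROC and 95% t-interval across evaluable folds."""
    from scipy.stats import t as t_dist

    vals = np.array([r.auroc for r in results if r.evaluable], float)
    n = vals.size
    mean = float(vals.mean()) if n else float("nan")
    if n >= 2:
        half = float(t_dist.ppf(0.975, n - 1) * vals.std(ddof=1) / np.sqrt(n))
    else:
        half = float("nan")
    return {
        "n_folds": int(n),
        "mean_auroc": mean,
        "ci95_low": mean - half,
        "ci95_high": mean + half,
    }
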