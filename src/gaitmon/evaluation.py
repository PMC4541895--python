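"""Cross-validation, feature-count sweeps and trial summary statistics.

The evaluation protocol mirrors the study design: six-fold cross-validation
with each activity's sample block split into six contiguous parts (no
shuffling), pooled accuracy across folds, a sweep of the retained component
count from 5 to 37, per-activity recognition percentages over a trial, and
Avg (+/- SD) summary rows using the population (1/n) standard deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .gnb import ACTIVITIES
from .pipeline import ActivityClassifier

__all__ = [
    "CVResult",
    "six_fold_cv",
    "accuracy_feature_sweep",
    "recognition_percentages",
    "TrialSummary",
    "trial_summary",
]


@dataclass(frozen=True)
class CVResult:
    """Pooled cross-validation outcome."""

    accuracy_pct: float
    fold_accuracies: tuple[float, ...]
    n_test: int


def _fold_indices(
    labels: np.ndarray, n_folds: int, classes: Sequence[str]
) -> list[np.ndarray]:
    """Deterministic contiguous per-class fold blocks.

    Each class's samples (in dataset order) are cut into ``n_folds`` equal
    contiguous blocks; block i of every class forms test fold i.  Classes
    whose size is not divisible by the fold count are truncated to the
    largest multiple, with a warning.
    """
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for cls_name in classes:
        idx = np.flatnonzero(labels == cls_name)
        usable = (len(idx) // n_folds) * n_folds
        if usable == 0:
            raise ValueError(f"class {cls_name!r} too small for {n_folds} folds")
        if usable < len(idx):
            warnings.warn(
                f"class {cls_name!r}: truncating {len(idx)} to {usable} samples "
                f"for {n_folds} folds",
                stacklevel=3,
            )
            idx = idx[:usable]
        for i, block in enumerate(np.split(idx, n_folds)):
            folds[i].extend(block.tolist())
    return [np.asarray(sorted(f)) for f in folds]


def six_fold_cv(
    X: np.ndarray,
    labels: np.ndarray,
    n_components: int = 22,
    n_folds: int = 6,
    classes: Sequence[str] = ACTIVITIES,
    standardize: bool = True,
) -> CVResult:
    """Cross-validated pooled accuracy of the full classifier pipeline.

    The standardizer, PCA and GNB are refitted on the training five-sixths
    of every fold; accuracy is pooled correct/total over all held-out
    samples, in percent.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if not 1 <= n_components <= X.shape[1]:
        raise ValueError(f"component count must be in [1, {X.shape[1]}]")
    folds = _fold_indices(labels, n_folds, classes)
    correct, total, fold_accs = 0, 0, []
    for test_idx in folds:
        mask = np.ones(len(labels), dtype=bool)
        mask[test_idx] = False
        clf = ActivityClassifier(
            n_components=n_components, standardize=standardize
        ).fit(X[mask], labels[mask], classes=tuple(classes))
        pred = clf.predict(X[test_idx])
        hits = int(np.sum(pred == labels[test_idx]))
        fold_accs.append(100.0 * hits / len(test_idx))
        correct += hits
        total += len(test_idx)
    return CVResult(100.0 * correct / total, tuple(fold_accs), total)


def accuracy_feature_sweep(
    X: np.ndarray,
    labels: np.ndarray,
    components: Iterable[int] = range(5, 38),
    n_folds: int = 6,
    classes: Sequence[str] = ACTIVITIES,
) -> pd.DataFrame:
    """Cross-validated accuracy for each retained-component count.

    The default sweep covers 5 to 37 components inclusive; the PCA is refit
    per count.  Returns a table with columns ``n_components`` and
    ``accuracy_pct``.
    """
    components = list(components)
    if any(i < 1 or i > X.shape[1] for i in components):
        raise ValueError(f"component counts must lie in [1, {X.shape[1]}]")
    rows = [
        {
            "n_components": i,
            "accuracy_pct": six_fold_cv(
                X, labels, n_components=i, n_folds=n_folds, classes=classes
            ).accuracy_pct,
        }
        for i in components
    ]
    return pd.DataFrame(rows)


def recognition_percentages(
    predictions: Sequence[str],
    timestamps: Sequence[float] | None = None,
    activities: Sequence[str] = ACTIVITIES,
) -> dict[str, float]:
    """Share of a trial's duration each activity was recognized, in percent.

    Every sample is weighted by the interval to the next sample (the last
    sample by the median interval); with uniform sampling this reduces to
    the fraction of samples.  The returned percentages sum to 100.
    """
    predictions = np.asarray(predictions, dtype=object)
    n = len(predictions)
    if n == 0:
        raise ValueError("empty prediction sequence")
    if timestamps is None:
        weights = np.ones(n)
    else:
        ts = np.asarray(timestamps, dtype=float)
        if len(ts) != n:
            raise ValueError("timestamps and predictions differ in length")
        gaps = np.diff(ts)
        if np.any(gaps <= 0):
            raise ValueError("timestamps must be strictly increasing")
        tail = np.median(gaps) if len(gaps) else 1.0
        weights = np.concatenate([gaps, [tail]])
    total = weights.sum()
    if total <= 0:
        raise ValueError("trial has zero duration")
    out = {}
    for act in activities:
        out[act] = 100.0 * float(weights[predictions == act].sum()) / total
    return out


@dataclass(frozen=True)
class TrialSummary:
    """Per-trial values with their mean and population standard deviation."""

    values: tuple[float, ...]
    mean: float
    sd: float

    def rounded(self, decimals: int = 0) -> tuple[float, float]:
        """Mean and SD rounded for display (0 decimals for ms, 2 for %)."""
        if decimals == 0:
            return float(round(self.mean)), float(round(self.sd))
        return round(self.mean, decimals), round(self.sd, decimals)


def trial_summary(per_trial_values: Iterable[float]) -> TrialSummary:
    """Summarize per-trial values as mean and population (1/n) SD."""
    values = tuple(float(v) for v in per_trial_values)
    if not values:
        raise ValueError("no per-trial values")
    arr = np.asarray(values)
    return TrialSummary(values, float(arr.mean()), float(arr.std(ddof=0)))
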