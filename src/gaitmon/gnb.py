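"""Gaussian naive Bayes discrimination of foot-movement patterns.

Each projected feature is modelled within each class as an independent
Gaussian whose mean and variance are the maximum-likelihood (1/n) estimates
from that class's training samples.  Class priors are taken as equal, so the
evidence term cancels and prediction reduces to the argmax over classes of
the summed per-feature log-densities

    sum_i [ -ln(sigma_ik sqrt(2 pi)) - 1/2 ((y_i - mu_ik)/sigma_ik)^2 ].

All probability arithmetic is done in the log domain; the reported
posteriors are a max-subtracted softmax of the class log-scores, which
reinstates the evidence normalization exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["ACTIVITIES", "GNBModel", "fit_gnb", "class_log_score"]

#: Fixed activity ordering; class index = position in this tuple, and ties in
#: the posterior resolve to the lowest index.
ACTIVITIES = (
    "walking_forward",
    "walking_backwards",
    "lateral_left",
    "lateral_right",
    "turning_left",
    "turning_right",
    "sitting_down",
    "standing_up",
)

#: Floor on estimated standard deviations (standardized-feature units); keeps
#: a within-class constant feature (e.g. a frozen phase-sequence code) from
#: producing an infinite density.
SIGMA_FLOOR = 1e-9


@dataclass(frozen=True)
class GNBModel:
    """Per-class Gaussian parameters over the selected features."""

    classes: tuple[str, ...]
    means: np.ndarray  # (K, I)
    sigmas: np.ndarray  # (K, I), floored at sigma_floor
    sigma_floor: float = SIGMA_FLOOR

    @property
    def n_features(self) -> int:
        return self.means.shape[1]

    def log_scores(self, Y: np.ndarray) -> np.ndarray:
        """Class log-scores for sample(s); shape (n, K)."""
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        if not np.all(np.isfinite(Y)):
            raise ValueError("non-finite feature value in input")
        if Y.shape[1] != self.n_features:
            raise ValueError(f"expected {self.n_features} features, got {Y.shape[1]}")
        z = (Y[:, None, :] - self.means[None, :, :]) / self.sigmas[None, :, :]
        const = -np.log(self.sigmas * np.sqrt(2.0 * np.pi)).sum(axis=1)
        return const[None, :] - 0.5 * (z**2).sum(axis=2)

    def predict(self, Y: np.ndarray) -> np.ndarray:
        """Most probable class label per sample (lowest index wins ties)."""
        scores = self.log_scores(Y)
        return np.asarray(self.classes, dtype=object)[np.argmax(scores, axis=1)]

    def posteriors(self, Y: np.ndarray) -> np.ndarray:
        """Normalized class posteriors per sample under equal priors."""
        scores = self.log_scores(Y)
        scores = scores - scores.max(axis=1, keepdims=True)
        p = np.exp(scores)
        return p / p.sum(axis=1, keepdims=True)

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "means": self.means.tolist(),
            "sigmas": self.sigmas.tolist(),
            "sigma_floor": self.sigma_floor,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "GNBModel":
        return cls(
            classes=tuple(doc["classes"]),
            means=np.asarray(doc["means"], dtype=float),
            sigmas=np.asarray(doc["sigmas"], dtype=float),
            sigma_floor=float(doc.get("sigma_floor", SIGMA_FLOOR)),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GNBModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def class_log_score(y: np.ndarray, mean: np.ndarray, sigma: np.ndarray) -> float:
    """Log-score of one sample under one class's Gaussian parameters."""
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite feature value in input")
    z = (y - mean) / sigma
    return float(np.sum(-np.log(sigma * np.sqrt(2.0 * np.pi)) - 0.5 * z**2))


def fit_gnb(
    Y: np.ndarray,
    labels: np.ndarray,
    classes: tuple[str, ...] = ACTIVITIES,
    sigma_floor: float = SIGMA_FLOOR,
    ddof: int = 0,
) -> GNBModel:
    """Fit per-class Gaussian parameters by maximum likelihood.

    ``ddof=0`` gives the 1/n (MLE) variance; ``ddof=1`` switches to the
    unbiased 1/(n-1) convention.  Every class in ``classes`` must contribute
    at least two samples.
    """
    Y = np.asarray(Y, dtype=float)
    labels = np.asarray(labels)
    K, I = len(classes), Y.shape[1]
    means = np.empty((K, I))
    sigmas = np.empty((K, I))
    for k, cls_name in enumerate(classes):
        block = Y[labels == cls_name]
        if block.shape[0] < 2:
            raise ValueError(f"class {cls_name!r} has fewer than 2 training samples")
        means[k] = block.mean(axis=0)
        sigmas[k] = np.maximum(block.std(axis=0, ddof=ddof), sigma_floor)
    return GNBModel(classes=tuple(classes), means=means, sigmas=sigmas,
                    sigma_floor=sigma_floor)
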