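"""End-to-end activity classifier: standardize -> PCA -> Gaussian naive Bayes."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .gnb import ACTIVITIES, GNBModel, fit_gnb
from .pca import PCAModel, Standardizer, fit_pca

__all__ = ["ActivityClassifier"]


@dataclass
class ActivityClassifier:
    """Walking-forward discriminator over 37-feature vectors.

    Features are z-scored with training statistics, projected onto the top
    ``n_components`` scatter-matrix eigenvectors, and classified with a
    Gaussian naive Bayes model under equal priors.
    """

    n_components: int = 22
    standardize: bool = True
    center: bool = True
    ddof: int = 0
    scaler: Standardizer | None = None
    pca: PCAModel | None = None
    gnb: GNBModel | None = None

    def fit(self, X: np.ndarray, labels: np.ndarray,
            classes: tuple[str, ...] = ACTIVITIES) -> "ActivityClassifier":
        X = np.asarray(X, dtype=float)
        if self.standardize:
            self.scaler = Standardizer.fit(X)
            X = self.scaler.transform(X)
        self.pca = fit_pca(X, self.n_components, center=self.center)
        Y = self.pca.project(X)
        self.gnb = fit_gnb(Y, labels, classes=classes, ddof=self.ddof)
        return self

    def _project(self, X: np.ndarray) -> np.ndarray:
        if self.pca is None or self.gnb is None:
            raise RuntimeError("classifier is not fitted")
        X = np.asarray(X, dtype=float)
        if self.scaler is not None:
            X = self.scaler.transform(X)
        return self.pca.project(X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        Y = self._project(X)
        return self.gnb.predict(Y)

    def posteriors(self, X: np.ndarray) -> np.ndarray:
        Y = self._project(X)
        return self.gnb.posteriors(Y)

    def save(self, path: str | Path) -> None:
        doc = {
            "n_components": self.n_components,
            "standardize": self.standardize,
            "center": self.center,
            "ddof": self.ddof,
            "scaler": None
            if self.scaler is None
            else {"mean": self.scaler.mean.tolist(),
                  "scale": self.scaler.scale.tolist()},
            "pca": self.pca.to_dict(),
            "gnb": self.gnb.to_dict(),
        }
        Path(path).write_text(json.dumps(doc) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "ActivityClassifier":
        doc = json.loads(Path(path).read_text())
        clf = cls(
            n_components=doc["n_components"],
            standardize=doc["standardize"],
            center=doc["center"],
            ddof=doc["ddof"],
        )
        if doc["scaler"] is not None:
            clf.scaler = Standardizer(
                np.asarray(doc["scaler"]["mean"], dtype=float),
                np.asarray(doc["scaler"]["scale"], dtype=float),
            )
        clf.pca = PCAModel.from_dict(doc["pca"])
        clf.gnb = GNBModel.from_dict(doc["gnb"])
        return clf
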