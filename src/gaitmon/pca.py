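"""Principal component analysis via the scatter matrix.

The projection basis is obtained exactly as the classifier pipeline defines
it: the per-feature mean vector ``m`` over all samples (class labels
ignored), the scatter matrix ``S = sum_j (x_j - m)(x_j - m)^T`` (n times the
population covariance), and the eigenvectors of ``S`` with the largest
eigenvalues, concatenated column-wise into the 37 x I transformation matrix
``W``.  Samples are projected as ``y = W^T (x - m)``; a ``center=False``
switch restores the uncentered form ``y = W^T x``, which shifts every class
by the same constant and is therefore equivalent for the downstream
Gaussian classifier.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Standardizer",
    "PCAModel",
    "mean_vector",
    "scatter_matrix",
    "principal_axes",
    "projection_matrix",
    "fit_pca",
]

#: Eigenvalues of the PSD scatter matrix more negative than this are an error;
#: anything in (-tol, 0) is numerical noise and is clipped to zero.
EIGENVALUE_TOLERANCE = 1e-10


@dataclass(frozen=True)
class Standardizer:
    """Per-feature z-scoring with training-set statistics.

    Raw feature scales differ by orders of magnitude (normalized pressures
    vs. phase-sequence codes in the thousands), so features are standardized
    before the scatter matrix is formed.  A constant feature gets unit scale
    so it maps to exactly zero instead of dividing by zero.
    """

    mean: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale = np.where(scale == 0.0, 1.0, scale)
        return cls(mean, scale)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.scale


def mean_vector(X: np.ndarray) -> np.ndarray:
    """Arithmetic mean per feature over all samples."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("dataset must be a non-empty 2-D array")
    return X.mean(axis=0)


def scatter_matrix(X: np.ndarray, m: np.ndarray | None = None) -> np.ndarray:
    """Scatter matrix ``sum_j (x_j - m)(x_j - m)^T`` (symmetric PSD)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("scatter matrix needs at least 2 samples")
    if m is None:
        m = mean_vector(X)
    D = X - np.asarray(m, dtype=float)
    return D.T @ D


def principal_axes(S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenpairs of a symmetric matrix, sorted by eigenvalue descending.

    Returns ``(eigenvalues, eigenvectors)`` with eigenvectors as columns.
    The sort is stable so eigenvalue ties keep their original axis order;
    each eigenvector's sign is fixed so its largest-magnitude component is
    positive.  Tiny negative eigenvalues (round-off on a PSD input) are
    clipped to zero.
    """
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1] or not np.allclose(S, S.T):
        raise ValueError("scatter matrix must be square and symmetric")
    eigvals, eigvecs = np.linalg.eigh(S)
    order = np.argsort(-eigvals, kind="stable")
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    if np.any(eigvals < -EIGENVALUE_TOLERANCE * max(1.0, abs(eigvals[0]))):
        raise ValueError("scatter matrix has significantly negative eigenvalues")
    eigvals = np.clip(eigvals, 0.0, None)
    flip = np.sign(eigvecs[np.argmax(np.abs(eigvecs), axis=0), np.arange(S.shape[0])])
    flip = np.where(flip == 0, 1.0, flip)
    return eigvals, eigvecs * flip


def projection_matrix(eigvecs: np.ndarray, n_components: int) -> np.ndarray:
    """Transformation matrix W: the top-I eigenvectors as columns."""
    d = eigvecs.shape[0]
    if not 1 <= n_components <= d:
        raise ValueError(f"component count must be in [1, {d}], got {n_components}")
    return eigvecs[:, :n_components].copy()


@dataclass(frozen=True)
class PCAModel:
    """Fitted projection: mean, eigenvalues, transformation matrix W."""

    mean: np.ndarray
    eigenvalues: np.ndarray
    components: np.ndarray  # (d, I) matrix W, columns unit-norm
    center: bool = True

    @property
    def n_components(self) -> int:
        return self.components.shape[1]

    def project(self, X: np.ndarray) -> np.ndarray:
        """Project sample(s) onto the retained axes: ``y = W^T (x - m)``."""
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        if X.shape[-1] != self.components.shape[0]:
            raise ValueError(
                f"expected {self.components.shape[0]} features, got {X.shape[-1]}"
            )
        if self.center:
            X = X - self.mean
        Y = X @ self.components
        return Y if not single else Y

    def to_dict(self) -> dict:
        return {
            "mean": self.mean.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "components": self.components.tolist(),
            "center": self.center,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "PCAModel":
        return cls(
            mean=np.asarray(doc["mean"], dtype=float),
            eigenvalues=np.asarray(doc["eigenvalues"], dtype=float),
            components=np.asarray(doc["components"], dtype=float),
            center=bool(doc.get("center", True)),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PCAModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_pca(X: np.ndarray, n_components: int = 22, center: bool = True) -> PCAModel:
    """Fit the scatter-matrix PCA and retain the top ``n_components`` axes."""
    m = mean_vector(X)
    S = scatter_matrix(X, m)
    eigvals, eigvecs = principal_axes(S)
    W = projection_matrix(eigvecs, n_components)
    return PCAModel(mean=m, eigenvalues=eigvals, components=W, center=center)
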