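"""Classical-scaling (RKHS-style) embedding of a pairwise NCD matrix.

Classical multidimensional scaling turns a symmetric dissimilarity matrix D
into point coordinates whose Euclidean geometry reproduces D as well as a
Euclidean configuration can: square D entrywise, double-center

    B = -1/2 * J D^2 J,      J = I - (1/n) 11',

eigendecompose B, and scale the eigenvectors of the k largest nonnegative
eigenvalues by sqrt(eigenvalue).  When D is exactly Euclidean this recovers
the original configuration up to rigid motion; NCD matrices are only
approximately Euclidean, so negative eigenvalues appear and their total
magnitude is reported as a diagnostic rather than silently discarded.

The embedding dimension is chosen as the number of ground-truth classes
(capped at n-1), following spectral-learning practice: with K distinct
conditions in the corpus the K principal dimensions carry the class structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .compression import DistanceMatrix

__all__ = ["EmbeddingSpace", "ClassicalScalingEmbedding", "embed", "choose_dimension"]


@dataclass
class EmbeddingSpace:
    """N points x k coordinates with the retained eigenvalues and inertia bookkeeping."""

    coordinates: np.ndarray  # (n, k)
    eigenvalues: np.ndarray  # (k,), nonnegative, descending
    total_inertia: float  # sum of |eigenvalue| over all n
    dropped_mass: float  # |eigenvalue| mass not retained (incl. negative part)
    ids: list[str]

    @property
    def retained_inertia(self) -> float:
        return float(self.eigenvalues.sum())


class ClassicalScalingEmbedding(BaseEstimator, TransformerMixin):
    """Classical MDS on a precomputed dissimilarity matrix, scikit-learn style.

    Parameters
    ----------
    n_components : int
        Number of embedding dimensions k, 1 <= k <= n-1.
    center : bool
        Double-center the squared dissimilarities (default).  ``False``
        eigendecomposes the raw dissimilarity matrix instead — kept for
        comparison only; it lacks the distance-preservation property.

    Attributes
    ----------
    embedding_ : ndarray of shape (n, k)
        Coordinates; eigenvectors scaled by sqrt(eigenvalue), signs fixed so
        each column's largest-magnitude loading is positive.
    eigenvalues_ : ndarray of shape (k,)
        Retained nonnegative eigenvalues, descending.
    dropped_mass_ : float
        Total absolute eigenvalue mass not retained, including the negative
        eigenvalues produced by non-Euclidean dissimilarities.
    total_inertia_ : float
        Sum of absolute eigenvalues of the centered matrix.
    """

    def __init__(self, n_components: int = 2, center: bool = True):
        self.n_components = n_components
        self.center = center

    def fit(self, X, y=None):
        D = np.asarray(X, dtype=float)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValueError("X must be a square dissimilarity matrix")
        n = D.shape[0]
        if not np.allclose(D, D.T, atol=1e-10):
            raise ValueError("dissimilarity matrix must be symmetric")
        k = int(self.n_components)
        if not 1 <= k <= n - 1:
            raise ValueError(f"n_components must be in [1, {n - 1}], got {k}")
        if self.center:
            J = np.eye(n) - np.full((n, n), 1.0 / n)
            B = -0.5 * J @ (D**2) @ J
        else:
            B = D
        B = 0.5 * (B + B.T)  # guard symmetry against roundoff
        w, V = np.linalg.eigh(B)
        order = np.argsort(w)[::-1]
        w, V = w[order], V[:, order]
        pos = np.clip(w[:k], 0.0, None)
        coords = V[:, :k] * np.sqrt(pos)
        # reproducible sign: largest-magnitude loading of each axis positive
        for j in range(k):
            col = coords[:, j]
            if col.any() and col[np.argmax(np.abs(col))] < 0:
                coords[:, j] = -col
        self.embedding_ = coords
        self.eigenvalues_ = pos
        self.total_inertia_ = float(np.abs(w).sum())
        self.dropped_mass_ = float(np.abs(w).sum() - pos.sum())
        self.n_features_in_ = n
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X, y).embedding_

    def transform(self, X):
        # classical scaling has no out-of-sample rule; only the fitted corpus
        X = np.asarray(X, dtype=float)
        if X.shape != (self.n_features_in_, self.n_features_in_):
            raise ValueError("transform only supports the matrix the model was fit on")
        return self.embedding_


def embed(D: DistanceMatrix | np.ndarray, k: int, center: bool = True) -> EmbeddingSpace:
    """Embed a pairwise distance matrix in k dimensions by classical scaling."""
    if isinstance(D, DistanceMatrix):
        ids, values = D.ids, D.values
    else:
        values = np.asarray(D, dtype=float)
        ids = [f"point{i}" for i in range(values.shape[0])]
    model = ClassicalScalingEmbedding(n_components=k, center=center).fit(values)
    return EmbeddingSpace(
        coordinates=model.embedding_,
        eigenvalues=model.eigenvalues_,
        total_inertia=model.total_inertia_,
        dropped_mass=model.dropped_mass_,
        ids=list(ids),
    )


def choose_dimension(labels, n_points: int | None = None) -> int:
    """Embedding dimension = number of distinct class labels, capped at n-1."""
    labels = list(labels)
    if not labels:
        raise ValueError("labels must be non-empty")
    k = len(set(labels))
    n = n_points if n_points is not None else len(labels)
    return max(1, min(k, n - 1))
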