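"""PCA of Procrustes residuals and Euclidean distances in PC space.

The PCA is an eigendecomposition of the covariance of the residual vectors
(no variable rescaling), computed through the SVD of the centered residual
matrix.  All PCs up to the rank bound min(n-1, p) are kept, so variance
fractions sum to one and Euclidean distances over all PC scores equal
distances between the centered residual vectors exactly (orthogonal
projection identity).  Eigenvector sign is fixed by making each loading's
largest-magnitude element positive, so scores are reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import squareform, pdist

__all__ = ["PCAResult", "DistanceMatrix", "pca", "pc_distance_matrix"]


@dataclass
class PCAResult:
    eigenvalues: np.ndarray        # descending, variance units
    variance_fraction: np.ndarray  # per-PC fraction of total variance
    scores: np.ndarray             # (n, r) coordinates on all retained PCs
    loadings: np.ndarray           # (r, p) orthonormal axis vectors (rows)
    labels: list[str]
    mean: np.ndarray               # (p,) center of the residual vectors

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown configuration label {label!r}") from None


def pca(residuals: np.ndarray, labels: Sequence[str]) -> PCAResult:
    """PCA of per-configuration residual vectors (rows)."""
    X = np.asarray(residuals, float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 configurations")
    labels = [str(l) for l in labels]
    if len(labels) != X.shape[0]:
        raise ValueError("labels must match rows of the residual matrix")
    n, p = X.shape
    mean = X.mean(axis=0)
    Xc = X - mean
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    r = min(n - 1, p)
    U, S, Vt = U[:, :r], S[:r], Vt[:r]
    # deterministic sign: largest-|element| of each loading made positive
    for j in range(r):
        row = Vt[j]
        if row[int(np.argmax(np.abs(row)))] < 0:
            Vt[j] = -row
            U[:, j] = -U[:, j]
    eigenvalues = S**2 / (n - 1)
    total = float(eigenvalues.sum())
    if total <= 0.0:
        raise ValueError("zero total variance: all residual vectors identical")
    return PCAResult(
        eigenvalues=eigenvalues,
        variance_fraction=eigenvalues / total,
        scores=U * S,
        loadings=Vt,
        labels=labels,
        mean=mean,
    )


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        D = np.asarray(self.values, float)
        self.labels = [str(l) for l in self.labels]
        if D.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if np.any(np.abs(D - D.T) > 1e-12 * max(1.0, float(np.abs(D).max()))):
            raise ValueError("distance matrix is not symmetric")
        if np.any(D < 0.0):
            raise ValueError("distance matrix has negative entries")
        D = 0.5 * (D + D.T)
        np.fill_diagonal(D, 0.0)
        self.values = D

    @property
    def n(self) -> int:
        return len(self.labels)


def pc_distance_matrix(result: PCAResult, subset: Sequence[str] | None = None) -> DistanceMatrix:
    """Pairwise Euclidean distance over ALL PC scores for selected labels."""
    if subset is None:
        labels = list(result.labels)
    else:
        labels = [str(l) for l in subset]
        if not labels:
            raise ValueError("empty subset")
    idx = [result.index_of(l) for l in labels]
    pts = result.scores[idx]
    D = squareform(pdist(pts))
    return DistanceMatrix(labels=labels, values=D)
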