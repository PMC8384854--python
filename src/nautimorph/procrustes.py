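"""Generalized Procrustes analysis (full Procrustes, proper rotations only).

Each configuration is centered and scaled to unit centroid size, then
iteratively rotated onto the running consensus (the renormalized mean shape)
until the consensus stabilizes.  Reflections are excluded: nautilid conchs
have a fixed chirality, and mirroring a suture would fabricate shape
similarity.  After convergence the whole aligned set is rotated into a
canonical frame (consensus principal axes, deterministic sign rule), which
makes downstream PC scores reproducible bit-for-bit no matter how the inputs
were oriented, positioned, or scaled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import LandmarkConfiguration, centroid_size

__all__ = ["ProcrustesResult", "orthogonal_align", "gpa", "procrustes_distance"]


def orthogonal_align(source: np.ndarray, target: np.ndarray):
    """Proper rotation R (det +1) minimizing ||source @ R - target||^2.

    Both arrays are expected centered; the standard singular-value
    construction is used, with the smallest singular direction flipped when
    the unconstrained optimum would be a reflection.

    Returns
    -------
    (R, fitted) : ((d, d) array, (k, d) array)
    """
    X = np.asarray(source, float)
    Y = np.asarray(target, float)
    if X.shape != Y.shape:
        raise ValueError("source and target must have identical shape")
    U, _, Vt = np.linalg.svd(X.T @ Y)
    sign = np.sign(np.linalg.det(U @ Vt))
    D = np.ones(X.shape[1])
    D[-1] = sign
    R = (U * D) @ Vt
    return R, X @ R


@dataclass
class ProcrustesResult:
    """GPA output: aligned configurations, consensus, residual vectors."""

    aligned: list[LandmarkConfiguration]
    consensus: np.ndarray
    residuals: np.ndarray  # (n, k*d), aligned minus mean of aligned, flattened
    labels: list[str]
    iterations: int
    converged: bool


def _canonical_rotation(consensus: np.ndarray) -> np.ndarray:
    """Proper rotation taking the consensus onto its principal axes.

    Column signs are fixed so the largest-magnitude loading of each axis is
    positive; if the resulting basis is improper, the last (smallest-variance)
    axis is flipped back.  Deterministic for configurations with distinct
    principal variances.
    """
    d = consensus.shape[1]
    U, _, Vt = np.linalg.svd(consensus, full_matrices=False)
    V = Vt.T
    for j in range(d):
        col = U[:, j]
        if col[int(np.argmax(np.abs(col)))] < 0:
            V[:, j] = -V[:, j]
    if np.linalg.det(V) < 0:
        V[:, -1] = -V[:, -1]
    return V


def gpa(configs, max_iter: int = 200, tol: float = 1e-10) -> ProcrustesResult:
    """Generalized Procrustes alignment of >= 2 same-layout configurations."""
    configs = list(configs)
    if len(configs) < 2:
        raise ValueError("GPA needs at least 2 configurations")
    shapes = {(c.k, c.ndim) for c in configs}
    if len(shapes) != 1:
        raise ValueError(f"mixed landmark layouts in GPA input: {sorted(shapes)}")
    mats = []
    for c in configs:
        size = centroid_size(c.coords)
        if size <= 0.0:
            raise ValueError(f"configuration {c.label!r} has zero centroid size")
        mats.append((c.coords - c.coords.mean(axis=0)) / size)
    X = np.stack(mats)  # (n, k, d)

    consensus = X[0].copy()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for i in range(X.shape[0]):
            _, X[i] = orthogonal_align(X[i], consensus)
        mean = X.mean(axis=0)
        mean = mean - mean.mean(axis=0)
        new_consensus = mean / centroid_size(mean)
        delta = float(np.linalg.norm(new_consensus - consensus))
        consensus = new_consensus
        if delta < tol:
            converged = True
            break

    V = _canonical_rotation(consensus)
    X = X @ V
    consensus = consensus @ V
    mean = X.mean(axis=0)
    residuals = (X - mean).reshape(X.shape[0], -1)
    aligned = [
        LandmarkConfiguration(coords=X[i], label=configs[i].label) for i in range(X.shape[0])
    ]
    return ProcrustesResult(
        aligned=aligned,
        consensus=consensus,
        residuals=residuals,
        labels=[c.label for c in configs],
        iterations=it,
        converged=converged,
    )


def procrustes_distance(a: LandmarkConfiguration, b: LandmarkConfiguration) -> float:
    """Full Procrustes distance between two configurations (root summed
    squared difference after centering, unit scaling, and optimal proper
    rotation of `a` onto `b`)."""
    A = (a.coords - a.coords.mean(axis=0)) / centroid_size(a.coords)
    Bm = (b.coords - b.coords.mean(axis=0)) / centroid_size(b.coords)
    _, fitted = orthogonal_align(A, Bm)
    return float(np.linalg.norm(fitted - Bm))
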