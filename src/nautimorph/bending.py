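"""Thin-plate-spline bending energy and sliding semi-landmarks.

The bending-energy matrix of a reference configuration is the Schur
complement of the affine block in the bordered TPS system: with kernel matrix
K (U(r) = r^2 log r in 2D, U(r) = -r in 3D, U(0) = 0) and affine basis
P = [1 | X], the energy matrix is

    B = Q2 (Q2' K Q2)^-1 Q2'

where Q2 is an orthonormal basis of the null space of P'.  B is symmetric
positive-semidefinite, annihilates affine terms exactly (B P = 0 by
construction), and x' B x summed over coordinate columns of a target x is the
bending energy of the TPS warp taking the reference onto the target.

Semi-landmarks are slid along each specimen's own curve so as to minimize
bending energy relative to the reference: at each iteration the optimal
sliding magnitudes along the local unit tangents solve a linear system
(the energy is quadratic in the slide), the landmarks are displaced,
re-projected onto the curve, and the step is backtracked if projection
increased the energy — so energy is non-increasing across iterations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .geometry import Curve, LandmarkConfiguration, arc_length, project_to_curve, tangent_at

__all__ = [
    "BendingEnergyModel",
    "bending_energy_matrix",
    "bending_energy",
    "slide_semilandmarks",
]


def tps_kernel(r: np.ndarray, ndim: int) -> np.ndarray:
    """TPS radial kernel: r^2 log r in 2D, -r in 3D (U(0) = 0).

    The signs make the resulting energy matrix positive-semidefinite.
    """
    r = np.asarray(r, dtype=float)
    if ndim == 2:
        out = np.zeros_like(r)
        mask = r > 0.0
        out[mask] = r[mask] ** 2 * np.log(r[mask])
        return out
    if ndim == 3:
        return -r
    raise ValueError("kernel defined for d in {2, 3}")


@dataclass
class BendingEnergyModel:
    """Bending-energy matrix of a reference configuration."""

    reference: LandmarkConfiguration
    energy_matrix: np.ndarray
    kernel_dim: int


def bending_energy_matrix(reference: LandmarkConfiguration) -> BendingEnergyModel:
    """Build the k x k bending-energy matrix of `reference`.

    Raises if two reference landmarks coincide (singular TPS system) or the
    configuration is affinely degenerate (all collinear / coplanar).
    """
    X = reference.coords
    k, d = X.shape
    if k <= d + 1:
        raise ValueError(f"need more than d+1={d + 1} landmarks, got {k}")
    r = cdist(X, X)
    off = r + np.eye(k)
    if np.any(off == 0.0):
        i, j = np.argwhere((r == 0.0) & ~np.eye(k, dtype=bool))[0]
        raise np.linalg.LinAlgError(
            f"duplicate landmarks {i} and {j} in reference {reference.label!r}"
        )
    K = tps_kernel(r, d)
    P = np.hstack([np.ones((k, 1)), X])
    # affine-degeneracy check via rank of P
    if np.linalg.matrix_rank(P) < d + 1:
        raise np.linalg.LinAlgError(
            f"reference {reference.label!r} is affinely degenerate (collinear/coplanar)"
        )
    Q, _ = np.linalg.qr(P, mode="complete")
    Q2 = Q[:, d + 1 :]
    M = Q2.T @ K @ Q2
    B = Q2 @ np.linalg.solve(M, Q2.T)
    B = 0.5 * (B + B.T)
    model = BendingEnergyModel(reference=reference, energy_matrix=B, kernel_dim=d)
    return model


def bending_energy(model: BendingEnergyModel, target: LandmarkConfiguration | np.ndarray) -> float:
    """Bending energy of `target` relative to the model's reference.

    Sum over coordinate dimensions of x_c' B x_c.  Nonnegative; zero exactly
    when the target is an affine transform of the reference.
    """
    Y = target.coords if isinstance(target, LandmarkConfiguration) else np.asarray(target, float)
    B = model.energy_matrix
    if Y.shape != model.reference.coords.shape:
        raise ValueError(
            f"target shape {Y.shape} does not match reference {model.reference.coords.shape}"
        )
    e = float(np.einsum("ic,ij,jc->", Y, B, Y))
    if e < -1e-10 * max(1.0, float(np.sum(Y * Y))):
        raise np.linalg.LinAlgError(f"negative bending energy {e}")
    return max(e, 0.0)


def _slide_once(
    coords: np.ndarray,
    curve: Curve,
    B: np.ndarray,
    free: np.ndarray,
    positions: np.ndarray,
    max_step: float,
) -> np.ndarray:
    """Sliding magnitudes along tangents for the free landmarks.

    Solves the quadratic minimization for the optimal slide, then caps each
    magnitude at `max_step` (half the mean landmark spacing): the energy is
    nearly flat along whole-curve reparametrizations of smooth outlines, so
    an uncapped step can travel far along that valley on the strength of
    noise; the cap keeps the linearization local and the correspondence
    anchored to the equidistant start.
    """
    k, d = coords.shape
    tangents = np.zeros_like(coords)
    for i in np.where(free)[0]:
        tangents[i] = tangent_at(curve, positions[i])
    # energy E(t) = sum_c (x_c + t*u_c)' B (x_c + t*u_c); grad -> A t = -g
    A = np.zeros((k, k))
    g = np.zeros(k)
    for c in range(d):
        u = tangents[:, c]
        A += np.outer(u, u) * B
        g += u * (B @ coords[:, c])
    idx = np.where(free)[0]
    Aff = A[np.ix_(idx, idx)]
    # tiny Tikhonov ridge guards rank deficiency (e.g. parallel tangents)
    ridge = 1e-12 * max(1.0, float(np.trace(Aff)) / max(len(idx), 1))
    t = np.zeros(k)
    t[idx] = np.linalg.solve(Aff + ridge * np.eye(len(idx)), -g[idx])
    t = np.clip(t, -max_step, max_step)
    return t[:, None] * tangents


def slide_semilandmarks(
    configs: Sequence[LandmarkConfiguration],
    curves: Sequence[Curve],
    model: BendingEnergyModel,
    max_iter: int = 10,
    tol: float = 1e-8,
    fixed_indices: Iterable[int] = (0,),
    max_curve_distance: float | None = None,
    collect_traces: bool = False,
):
    """Slide semi-landmarks along their curves to minimize bending energy.

    Each configuration is slid along its own curve against the model's
    reference.  Landmarks listed in `fixed_indices` never move (and need not
    lie on the curve).  Sliding landmarks farther than `max_curve_distance`
    (default: 1e-3 of the curve length) from their curve are rejected as
    input errors.  Bending energy is non-increasing across iterations.

    Returns the list of slid configurations; with ``collect_traces=True``
    returns ``(configs, traces)`` where each trace is the per-iteration
    bending-energy sequence of one configuration.
    """
    if len(configs) != len(curves):
        raise ValueError("configs and curves must match one-to-one")
    out: list[LandmarkConfiguration] = []
    k = model.reference.k
    fixed = np.zeros(k, dtype=bool)
    fixed[list(fixed_indices)] = True
    free = ~fixed
    B = model.energy_matrix

    traces: list[list[float]] = []
    for cfg, curve in zip(configs, curves):
        if cfg.k != k or cfg.ndim != model.reference.ndim:
            raise ValueError(f"config {cfg.label!r} does not match the reference layout")
        L = arc_length(curve)
        limit = 1e-3 * L if max_curve_distance is None else max_curve_distance
        coords = cfg.coords.copy()
        positions = np.zeros(k)
        for i in np.where(free)[0]:
            proj, s, dist = project_to_curve(coords[i], curve)
            if dist > limit:
                raise ValueError(
                    f"landmark {i} of {cfg.label!r} is {dist:.3g} mm from its curve "
                    f"(limit {limit:.3g})"
                )
            coords[i] = proj
            positions[i] = s
        energy = bending_energy(model, coords)
        trace = [energy]
        max_step = 0.5 * L / k
        for _ in range(max_iter):
            step = _slide_once(coords, curve, B, free, positions, max_step)
            lam = 1.0
            accepted = None
            while lam >= 1.0 / 64.0:
                trial = coords + lam * step
                trial_pos = positions.copy()
                for i in np.where(free)[0]:
                    proj, s, _ = project_to_curve(trial[i], curve)
                    trial[i] = proj
                    trial_pos[i] = s
                trial_energy = bending_energy(model, trial)
                if trial_energy <= energy:
                    accepted = (trial, trial_pos, trial_energy)
                    break
                lam *= 0.5
            if accepted is None:
                break
            new_coords, new_pos, new_energy = accepted
            gain = energy - new_energy
            coords, positions, energy = new_coords, new_pos, new_energy
            trace.append(energy)
            if gain < tol * max(energy, 1e-300):
                break
        out.append(LandmarkConfiguration(coords=coords, label=cfg.label))
        traces.append(trace)
    if collect_traces:
        return out, traces
    return out
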