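"""Polyline curves, equidistant landmark resampling, centroid size, projection.

Curves are piecewise-linear: digitized suture lines and whorl cross-sections
arrive as densely sampled point sequences (>= 500 points from the generator),
so polyline arc length is accurate to second order in the sampling step and no
spline dialect needs to be fixed.  Closed curves store each vertex once; the
closing segment from the last vertex back to the first is implicit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Curve",
    "LandmarkConfiguration",
    "arc_length",
    "resample_equidistant",
    "centroid_size",
    "project_to_curve",
]


@dataclass
class Curve:
    """An ordered polyline in 2 or 3 dimensions (coordinates in mm).

    Parameters
    ----------
    points : (n, d) array
        Vertex coordinates, d in {2, 3}, n >= 3.  For closed curves the first
        vertex must not be repeated at the end.
    closed : bool
        Whether the closing segment last->first is part of the curve.
    label : str
        Provenance (specimen and chamber/section index).
    """

    points: np.ndarray
    closed: bool = True
    label: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] not in (2, 3):
            raise ValueError(f"curve {self.label!r}: points must be (n, 2) or (n, 3)")
        if pts.shape[0] < 3:
            raise ValueError(f"curve {self.label!r}: need at least 3 points")
        seg = np.diff(pts, axis=0)
        if np.any(np.all(seg == 0.0, axis=1)):
            raise ValueError(f"curve {self.label!r}: consecutive duplicate points")
        if self.closed and np.all(pts[0] == pts[-1]):
            raise ValueError(
                f"curve {self.label!r}: closed curve must not repeat its first point"
            )
        self.points = pts

    @property
    def ndim(self) -> int:
        return self.points.shape[1]

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def vertices_with_closure(self) -> np.ndarray:
        """Vertices with the first point appended when the curve is closed."""
        if self.closed:
            return np.vstack([self.points, self.points[:1]])
        return self.points

    def cumulative_arclength(self) -> np.ndarray:
        """Arc-length position of each vertex (closing vertex included if closed)."""
        verts = self.vertices_with_closure()
        seg = np.linalg.norm(np.diff(verts, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])


@dataclass
class LandmarkConfiguration:
    """An ordered set of k landmarks in d dimensions (mm)."""

    coords: np.ndarray
    label: str = ""
    centroid_size: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] not in (2, 3):
            raise ValueError(f"config {self.label!r}: coords must be (k, 2) or (k, 3)")
        self.coords = coords
        if self.centroid_size is None:
            self.centroid_size = centroid_size(coords)

    @property
    def k(self) -> int:
        return self.coords.shape[0]

    @property
    def ndim(self) -> int:
        return self.coords.shape[1]


def arc_length(curve: Curve) -> float:
    """Total polyline length in mm, including the closing segment if closed."""
    return float(curve.cumulative_arclength()[-1])


def centroid_size(config) -> float:
    """Square root of summed squared landmark distances from their centroid.

    Accepts a LandmarkConfiguration or a bare (k, d) array.  Translation- and
    rotation-invariant; scaling coordinates by c scales the result by |c|.
    """
    coords = config.coords if isinstance(config, LandmarkConfiguration) else np.asarray(config, float)
    centered = coords - coords.mean(axis=0)
    return float(np.sqrt(np.sum(centered**2)))


def _start_offset(curve: Curve, start_rule) -> float:
    """Arc-length position of the starting landmark under `start_rule`.

    ``"vertex0"`` starts at the first vertex.  ``"ventral"`` starts at the
    vertex farthest from the coiling axis: for 3D curves the axis is the z
    axis (distance hypot(x, y)); for 2D whorl sections the first coordinate is
    the radial distance from the axis in the section plane.  Ties are broken
    by the smallest vertex index.  A callable receives the vertex array and
    returns the starting vertex index.
    """
    if start_rule == "vertex0":
        return 0.0
    if start_rule == "ventral":
        pts = curve.points
        if curve.ndim == 3:
            radial = np.hypot(pts[:, 0], pts[:, 1])
        else:
            radial = pts[:, 0]
        idx = int(np.argmax(radial))  # argmax returns the first maximum: smallest index
    elif callable(start_rule):
        idx = int(start_rule(curve.points))
    else:
        raise ValueError(f"unknown start_rule {start_rule!r}")
    return float(curve.cumulative_arclength()[idx])


def _interp_on_curve(curve: Curve, positions: np.ndarray) -> np.ndarray:
    """Points at given arc-length positions (wrapped into [0, L) if closed)."""
    s = curve.cumulative_arclength()
    total = s[-1]
    verts = curve.vertices_with_closure()
    pos = np.asarray(positions, dtype=float)
    if curve.closed:
        pos = np.mod(pos, total)
    else:
        pos = np.clip(pos, 0.0, total)
    out = np.empty((pos.size, curve.ndim))
    for j in range(curve.ndim):
        out[:, j] = np.interp(pos, s, verts[:, j])
    return out


def resample_equidistant(curve: Curve, k: int, start_rule="ventral") -> LandmarkConfiguration:
    """Place k landmarks at equal arc-length intervals along the curve.

    For a closed curve the landmarks sit at arc-length positions
    s0 + i*L/k (i = 0..k-1) from the starting point resolved by `start_rule`;
    for an open curve at i*L/(k-1) from the first vertex.  Ordering follows
    the curve's own orientation.
    """
    if k < 3:
        raise ValueError("need k >= 3 landmarks")
    total = arc_length(curve)
    min_seg = np.min(np.linalg.norm(np.diff(curve.vertices_with_closure(), axis=0), axis=1))
    if total / k < min_seg * 1e-9:
        raise ValueError(f"k={k} exceeds representable resolution of curve {curve.label!r}")
    if curve.closed:
        s0 = _start_offset(curve, start_rule)
        positions = s0 + np.arange(k) * total / k
    else:
        positions = np.arange(k) * total / (k - 1)
    coords = _interp_on_curve(curve, positions)
    return LandmarkConfiguration(coords=coords, label=curve.label)


def project_to_curve(point, curve: Curve):
    """Closest point on the polyline and its arc-length coordinate.

    Returns
    -------
    (nearest, s, dist) : ((d,) array, float, float)
        The closest point, its arc-length position along the curve, and the
        Euclidean distance from `point` to it.
    """
    p = np.asarray(point, dtype=float)
    verts = curve.vertices_with_closure()
    a = verts[:-1]
    b = verts[1:]
    ab = b - a
    seg_len2 = np.sum(ab**2, axis=1)
    t = np.clip(np.sum((p - a) * ab, axis=1) / seg_len2, 0.0, 1.0)
    candidates = a + t[:, None] * ab
    d2 = np.sum((candidates - p) ** 2, axis=1)
    i = int(np.argmin(d2))
    s = curve.cumulative_arclength()
    pos = float(s[i] + t[i] * np.sqrt(seg_len2[i]))
    if curve.closed:
        pos = float(np.mod(pos, s[-1]))
    return candidates[i], pos, float(np.sqrt(d2[i]))


def tangent_at(curve: Curve, s_pos: float, delta: float | None = None) -> np.ndarray:
    """Unit tangent of the curve at arc-length position `s_pos`.

    Estimated by central differencing points at s ± delta (delta defaults to
    L/2000), which is robust at polyline vertices.
    """
    total = arc_length(curve)
    if delta is None:
        delta = total / 2000.0
    if curve.closed:
        pts = _interp_on_curve(curve, np.array([s_pos - delta, s_pos + delta]))
    else:
        lo = max(0.0, s_pos - delta)
        hi = min(total, s_pos + delta)
        pts = _interp_on_curve(curve, np.array([lo, hi]))
    vec = pts[1] - pts[0]
    norm = np.linalg.norm(vec)
    if norm == 0.0:
        raise ValueError("degenerate tangent")
    return vec / norm
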