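"""Curve arc length, equidistant resampling, centroid size, projection."""

import numpy as np
import pytest

from nautimorph import (
    Curve,
    LandmarkConfiguration,
    arc_length,
    centroid_size,
    project_to_curve,
    resample_equidistant,
)
from conftest import circle_curve


def unit_square(closed=True):
    pts = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
    return Curve(points=pts, closed=closed, label="square")


class TestCurveValidation:
    def test_too_few_points(self):
        with pytest.raises(ValueError, match="3 points"):
            Curve(points=[[0, 0], [1, 1]], closed=False)

    def test_consecutive_duplicates_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            Curve(points=[[0, 0], [0, 0], [1, 1]], closed=False)

    def test_closed_curve_must_not_repeat_first_point(self):
        pts = [[0, 0], [1, 0], [1, 1], [0, 0]]
        with pytest.raises(ValueError, match="repeat"):
            Curve(points=pts, closed=True)


class TestArcLength:
    def test_unit_square(self):
        assert arc_length(unit_square()) == pytest.approx(4.0, abs=1e-12)

    def test_open_square_excludes_closing_segment(self):
        assert arc_length(unit_square(closed=False)) == pytest.approx(3.0, abs=1e-12)

    def test_regular_polygon_approaches_circumference(self):
        c = circle_curve(n=360)
        assert arc_length(c) == pytest.approx(2 * np.pi, rel=1e-4)

    def test_helix_closed_form(self):
        # one turn of a radius-1, pitch-1 helix: length sqrt((2*pi)^2 + 1)
        t = np.linspace(0.0, 2 * np.pi, 1000)
        pts = np.column_stack([np.cos(t), np.sin(t), t / (2 * np.pi)])
        helix = Curve(points=pts, closed=False, label="helix")
        assert arc_length(helix) == pytest.approx(np.sqrt((2 * np.pi) ** 2 + 1), rel=1e-4)


class TestResampleEquidistant:
    def test_circle_quarters_from_ventral_start(self):
        cfg = resample_equidistant(circle_curve(n=3600), k=4, start_rule="ventral")
        angles = np.degrees(np.arctan2(cfg.coords[:, 1], cfg.coords[:, 0])) % 360
        assert np.allclose(angles, [0.0, 90.0, 180.0, 270.0], atol=0.2)

    def test_square_k8_gap_half(self):
        cfg = resample_equidistant(unit_square(), k=8, start_rule="vertex0")
        closed = np.vstack([cfg.coords, cfg.coords[:1]])
        gaps = np.linalg.norm(np.diff(closed, axis=0), axis=1)
        assert np.allclose(gaps, 0.5, atol=1e-12)

    def test_identity_when_vertices_already_equidistant(self):
        t = np.linspace(0.0, 2 * np.pi, 12, endpoint=False)
        pts = np.column_stack([np.cos(t), np.sin(t)])
        c = Curve(points=pts, closed=True, label="12gon")
        cfg = resample_equidistant(c, k=12, start_rule="vertex0")
        assert np.allclose(cfg.coords, pts, atol=1e-9)

    @pytest.mark.parametrize("k", [5, 20, 40])
    def test_gap_uniformity_on_irregular_curve(self, rng, k):
        t = np.linspace(0.0, 2 * np.pi, 800, endpoint=False)
        r = 1.0 + 0.3 * np.cos(2 * t) + 0.1 * np.sin(3 * t)
        c = Curve(points=np.column_stack([r * np.cos(t), r * np.sin(t)]), closed=True)
        cfg = resample_equidistant(c, k=k, start_rule="ventral")
        L = arc_length(c)
        pos = np.array([project_to_curve(p, c)[1] for p in cfg.coords])
        gaps = np.diff(np.concatenate([pos, [pos[0] + L]])) % L
        assert np.allclose(gaps, L / k, atol=1e-6 * L)

    def test_equivariance_under_rigid_motion(self, rng):
        t = np.linspace(0.0, 2 * np.pi, 600, endpoint=False)
        r = 1.0 + 0.2 * np.cos(3 * t)
        pts = np.column_stack([r * np.cos(t), r * np.sin(t)])
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        shift = np.array([2.5, -1.0])
        a = resample_equidistant(Curve(points=pts, closed=True), k=20, start_rule="vertex0")
        b = resample_equidistant(Curve(points=pts @ R.T + shift, closed=True), k=20,
                                 start_rule="vertex0")
        assert np.allclose(a.coords @ R.T + shift, b.coords, atol=1e-9)

    def test_k_too_small(self):
        with pytest.raises(ValueError):
            resample_equidistant(unit_square(), k=2)


class TestCentroidSize:
    def test_unit_square_corners(self):
        assert centroid_size(unit_square().points) == pytest.approx(np.sqrt(2.0), abs=1e-12)

    def test_scale_homogeneity(self, rng):
        X = rng.normal(size=(20, 3))
        assert centroid_size(3.0 * X) == pytest.approx(3.0 * centroid_size(X), rel=1e-12)

    def test_rigid_invariance(self, rng):
        X = rng.normal(size=(15, 2))
        theta = 1.1
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        assert centroid_size(X @ R.T + 5.0) == pytest.approx(centroid_size(X), rel=1e-12)

    def test_coincident_points_give_zero(self):
        assert centroid_size(np.ones((20, 2))) == 0.0


class TestProjectToCurve:
    def test_point_on_curve_projects_to_itself(self):
        sq = unit_square()
        nearest, s, dist = project_to_curve([0.5, 0.0], sq)
        assert dist == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(nearest, [0.5, 0.0])
        assert s == pytest.approx(0.5, abs=1e-12)

    def test_point_above_circle(self):
        c = circle_curve(n=3600)
        nearest, _, dist = project_to_curve([0.0, 2.0], c)
        assert np.allclose(nearest, [0.0, 1.0], atol=1e-3)
        assert dist == pytest.approx(1.0, abs=1e-3)

    def test_matches_brute_force_over_segments(self, rng):
        t = np.linspace(0.0, 2 * np.pi, 300, endpoint=False)
        r = 1.0 + 0.25 * np.sin(4 * t)
        c = Curve(points=np.column_stack([r * np.cos(t), r * np.sin(t)]), closed=True)
        verts = c.vertices_with_closure()
        for p in rng.normal(scale=1.5, size=(25, 2)):
            _, _, dist = project_to_curve(p, c)
            brute = np.inf
            for a, b in zip(verts[:-1], verts[1:]):
                ab = b - a
                tt = np.clip(np.dot(p - a, ab) / np.dot(ab, ab), 0.0, 1.0)
                brute = min(brute, np.linalg.norm(a + tt * ab - p))
            assert dist == pytest.approx(brute, abs=1e-12)


def test_landmark_configuration_computes_centroid_size():
    cfg = LandmarkConfiguration(coords=unit_square().points, label="sq")
    assert cfg.centroid_size == pytest.approx(np.sqrt(2.0))
    assert cfg.k == 4 and cfg.ndim == 2
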