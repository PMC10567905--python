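"""Landmark ordering, curve resampling and marginal ROI extraction."""

import numpy as np
import pytest

from crownfit.errors import ContentError, GeometryError, OrderingError
from crownfit.margin import (
    LandmarkSet,
    MarginCurve,
    extract_above_margin,
    extract_margin_roi,
    order_landmarks,
    points_to_polyline_distance,
    read_landmarks,
    resample_curve,
    write_landmarks,
)

from conftest import open_cylinder


def circle_points(n, radius, rng=None, z=0.0):
    angles = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = np.column_stack([radius * np.cos(angles),
                           radius * np.sin(angles),
                           np.full(n, z)])
    if rng is not None:
        pts = pts[rng.permutation(n)]
    return pts


def cycles_equal(a: np.ndarray, b: np.ndarray) -> bool:
    """Same closed cycle up to rotation and traversal direction."""
    n = len(a)
    if len(b) != n:
        return False
    for direction in (1, -1):
        bb = b[::direction]
        for shift in range(n):
            if np.allclose(a, np.roll(bb, shift, axis=0), atol=1e-12):
                return True
    return False


class TestOrderLandmarks:
    def test_circle_recovers_angular_order(self):
        rng = np.random.default_rng(3)
        pts = circle_points(50, 5.0, rng)
        curve = order_landmarks(LandmarkSet(pts, label="abutment"))
        assert curve.arc_length == pytest.approx(2 * np.pi * 5.0, rel=0.01)
        # ordered cycle must visit the angular positions consecutively
        ref = order_landmarks(LandmarkSet(circle_points(50, 5.0)))
        assert cycles_equal(ref.points, curve.points)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(11)
        base = circle_points(30, 4.0) + rng.normal(scale=0.05, size=(30, 3))
        c1 = order_landmarks(LandmarkSet(base))
        c2 = order_landmarks(LandmarkSet(base[rng.permutation(30)]))
        assert cycles_equal(c1.points, c2.points)

    def test_square_perimeter(self):
        pts = np.array([[0.0, 0, 0], [2, 0, 0], [2, 2, 0], [0, 2, 0]])
        curve = order_landmarks(LandmarkSet(pts[[2, 0, 3, 1]]))
        assert curve.arc_length == pytest.approx(8.0)

    def test_collinear_rejected(self):
        pts = np.column_stack([np.linspace(0, 1, 10), np.zeros(10), np.zeros(10)])
        with pytest.raises(OrderingError):
            order_landmarks(LandmarkSet(pts))

    def test_non_ring_rejected(self):
        # filled disk of points: radius SD / mean far above the ring limit
        rng = np.random.default_rng(5)
        r = np.sqrt(rng.uniform(0, 1, 200)) * 5
        r[:100] *= 0.01  # heavy mass at the centre
        ang = rng.uniform(0, 2 * np.pi, 200)
        pts = np.column_stack([r * np.cos(ang), r * np.sin(ang), np.zeros(200)])
        with pytest.raises(OrderingError):
            order_landmarks(LandmarkSet(pts))


class TestResample:
    def test_square_uniform_spacing(self):
        curve = MarginCurve(np.array([[0.0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]]))
        out = resample_curve(curve, 8)
        seg = np.diff(out.points, axis=0, append=out.points[:1])
        np.testing.assert_allclose(np.linalg.norm(seg, axis=1), 0.5, atol=1e-12)

    def test_idempotent_on_uniform_curve(self):
        curve = MarginCurve(circle_points(40, 3.0))
        out = resample_curve(curve, 40)
        np.testing.assert_allclose(out.points, curve.points, atol=1e-9)

    def test_arc_length_preserved_on_uniform_curve(self):
        # when every original vertex is itself a sample (uniform curve, count
        # a multiple) the resampled polyline retraces the original exactly
        curve = MarginCurve(circle_points(40, 6.0))
        for n in (40, 120, 200):
            out = resample_curve(curve, n)
            assert out.arc_length == pytest.approx(curve.arc_length, rel=1e-9)

    def test_arc_length_nearly_preserved_when_densified(self):
        # generic curves: resampling cuts corners, so the length can only
        # shrink, and by no more than the chordal error
        rng = np.random.default_rng(8)
        pts = circle_points(25, 6.0) + rng.normal(scale=0.2, size=(25, 3))
        curve = MarginCurve(pts)
        for n in (123, 500):
            out = resample_curve(curve, n)
            assert out.arc_length <= curve.arc_length + 1e-12
            assert out.arc_length == pytest.approx(curve.arc_length, rel=0.01)

    def test_densified_points_near_true_circle(self):
        curve = MarginCurve(circle_points(50, 5.0))
        out = resample_curve(curve, 500)
        radii = np.linalg.norm(out.points[:, :2], axis=1)
        # every resampled point lies between the chord and the circle
        chord_sagitta = 5.0 * (1 - np.cos(np.pi / 50))
        assert (radii <= 5.0 + 1e-9).all()
        assert (radii >= 5.0 - chord_sagitta - 1e-9).all()


class TestPolylineDistance:
    def test_point_to_segment_not_vertex(self):
        # the midpoint of a long edge is distance 1 from the polyline even
        # though both endpoints are much farther
        curve = MarginCurve(np.array([[-5.0, 0, 0], [5, 0, 0], [0, 8, 0]]))
        d, cp = points_to_polyline_distance(np.array([[0.0, -1.0, 0.0]]), curve)
        assert d[0] == pytest.approx(1.0, abs=1e-12)
        assert cp[0] == pytest.approx([0.0, 0.0, 0.0])


class TestMarginROI:
    def test_cylinder_band_area(self):
        mesh = open_cylinder(4.0, 5.0, n_theta=160, n_z=51)  # 0.1 mm rings
        rim = MarginCurve(mesh.vertices[:160])
        roi = extract_margin_roi(mesh, rim, band_height=0.5)
        area = roi.face_areas().sum()
        assert area == pytest.approx(2 * np.pi * 4.0 * 0.5, rel=0.05)

    def test_band_larger_than_mesh_keeps_everything(self, abutment):
        roi = extract_margin_roi(abutment.mesh, abutment.margin, band_height=100.0)
        assert roi.n_faces == abutment.mesh.n_faces

    def test_zero_band_touching_faces(self):
        mesh = open_cylinder(4.0, 5.0, n_theta=64, n_z=11)
        rim = MarginCurve(mesh.vertices[:64])
        roi = extract_margin_roi(mesh, rim, band_height=0.0)
        assert roi.n_faces > 0
        # every kept face touches the rim ring
        d, _ = points_to_polyline_distance(roi.vertices, rim)
        assert (d[roi.faces].min(axis=1) < 1e-9).all()

    def test_monotone_in_band_height(self, abutment):
        areas = []
        for band in (0.3, 0.6, 1.2):
            roi = extract_margin_roi(abutment.mesh, abutment.margin, band)
            areas.append(roi.n_faces)
        assert areas[0] < areas[1] < areas[2]

    def test_far_curve_rejected(self, abutment):
        far = MarginCurve(abutment.margin.points + np.array([0, 0, -3.0]))
        with pytest.raises(GeometryError):
            extract_margin_roi(abutment.mesh, far, 0.5)


class TestAboveMargin:
    def test_heights_respected(self, abutment):
        sub, idx = extract_above_margin(abutment.mesh, abutment.margin, 0.6)
        assert sub.n_faces == len(idx)
        assert (sub.vertices[:, 2] >= 0.6 - 1e-9).all()

    def test_band_criterion_any(self, abutment):
        band, _ = extract_above_margin(abutment.mesh, abutment.margin,
                                       0.3, 0.5, criterion="any")
        assert band.n_faces > 0
        strict, _ = extract_above_margin(abutment.mesh, abutment.margin,
                                         0.0, 10.0)
        assert band.n_faces <= strict.n_faces


class TestLandmarkIO:
    def test_round_trip(self, tmp_path):
        pts = circle_points(12, 2.0)
        path = tmp_path / "lm.xyz"
        write_landmarks(pts, path, header="test landmarks")
        back = read_landmarks(path, label="abutment")
        np.testing.assert_allclose(back.points, pts, atol=1e-9)
        assert back.label == "abutment"

    def test_malformed_line(self, tmp_path):
        path = tmp_path / "bad.xyz"
        path.write_text("1 2 3\n4 5\n")
        with pytest.raises(ContentError):
            read_landmarks(path)
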