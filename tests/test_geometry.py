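"""Closed periodic B-spline contour geometry."""

import numpy as np
import pytest
from scipy.interpolate import BSpline

from lumenfit.geometry import (
    ContourSpline,
    DegenerateContourWarning,
    basis,
    control_points,
    evaluate_contour,
    point_in_contour,
    points_in_polygon,
    polygon_area,
    rasterize_polygon,
    load_polygon_csv,
    load_spline_json,
    save_polygon_csv,
    save_spline_json,
)

KNOTS = np.arange(20.0)


class TestBasis:
    def test_degree_zero_is_span_indicator(self):
        assert basis(4, 0, 4.5, KNOTS) == 1.0
        assert basis(4, 0, 4.0, KNOTS) == 1.0  # left-closed
        assert basis(4, 0, 5.0, KNOTS) == 0.0  # right-open
        assert basis(4, 0, 3.9, KNOTS) == 0.0

    @pytest.mark.parametrize("t", [3.5, 7.0, 9.99, 12.25])
    def test_cubic_partition_of_unity(self, t):
        total = sum(basis(i, 3, t, KNOTS) for i in range(KNOTS.size - 4))
        assert abs(total - 1.0) < 1e-9

    def test_cubic_values_at_interior_knot(self):
        # at a knot of a uniform cubic spline the three supporting bases
        # take the classical 1/6, 2/3, 1/6 values
        vals = [basis(i, 3, 7.0, KNOTS) for i in range(4, 7)]
        assert vals == pytest.approx([1 / 6, 2 / 3, 1 / 6])

    def test_agrees_with_scipy_basis_element(self, rng):
        for i in (2, 5, 9):
            ref = BSpline.basis_element(KNOTS[i:i + 5], extrapolate=False)
            for t in rng.uniform(KNOTS[i], KNOTS[i + 4], 20):
                assert basis(i, 3, t, KNOTS) == pytest.approx(float(ref(t)), abs=1e-12)

    def test_rejects_short_knots_and_bad_degree(self):
        with pytest.raises(ValueError):
            basis(8, 3, 5.0, np.arange(10.0))
        with pytest.raises(ValueError):
            basis(0, 0, 0.5, np.array([1.0, 0.0]))


class TestControlPoints:
    def test_angles_for_eight_directions(self):
        cp = control_points(np.full(8, 1.0), R=1.0, delta_s=1.0)
        angles = np.degrees(np.arctan2(cp[:, 1], cp[:, 0]))
        assert angles[1] == pytest.approx(45.0)
        assert angles[2] == pytest.approx(90.0)

    def test_direct_substitution(self):
        cp = control_points(np.array([0.5, 0.3, 0.3, 0.3]), R=10.0, delta_s=0.45)
        assert cp[0] == pytest.approx([2.25, 0.0])

    def test_negative_distance_flips_to_opposite_ray(self):
        d = np.full(10, 0.4)
        d[6] = -0.08
        cp = control_points(d, R=11.0, delta_s=1.0)
        # ray 6 points at 216 deg (= +144 deg in image-display coordinates,
        # where y runs downward); the negative distance flips it by 180 deg,
        # i.e. to -36 deg on a display
        angle = np.degrees(np.arctan2(-cp[6, 1], cp[6, 0]))
        assert angle == pytest.approx(-36.0)
        positive = control_points(np.full(10, 0.4), R=11.0, delta_s=1.0)
        assert np.allclose(cp[6], -0.08 / 0.4 * positive[6])


class TestEvaluateContour:
    def test_equal_distances_give_near_circle(self, round_spline):
        poly = evaluate_contour(round_spline, 400)
        radii = np.linalg.norm(poly, axis=1)
        assert (radii.max() - radii.min()) / radii.mean() < 0.005

    def test_closure(self, random_splines):
        for spline in random_splines[:5]:
            poly = evaluate_contour(spline, 157)
            assert np.linalg.norm(poly[0] - poly[-1]) < 1e-9

    def test_cyclic_rotation_equivariance(self, rng):
        d = rng.uniform(0.2, 0.8, 10)
        base = evaluate_contour(ContourSpline(d=d), 101)[:-1]
        rolled = evaluate_contour(ContourSpline(d=np.roll(d, 1)), 101)[:-1]
        theta = 2 * np.pi / 10
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        # rotating the plane by one control step and shifting the parameter
        # start by one knot span must reproduce the same polygon
        expected = base @ rot.T
        assert np.allclose(np.roll(rolled, -10, axis=0), expected, atol=1e-9)

    def test_scaling_linearity(self, rng):
        d = rng.uniform(0.1, 1.0, 10)
        p1 = evaluate_contour(ContourSpline(d=d), 200)
        p2 = evaluate_contour(ContourSpline(d=2.5 * d), 200)
        assert np.allclose(p2, 2.5 * p1, atol=1e-9)

    def test_c2_continuity_across_knots(self, rng):
        # discrete second differences on a dense sampling must not spike at
        # the knots, unlike for a curve with only C1 joins
        d = rng.uniform(0.2, 0.9, 10)
        poly = evaluate_contour(ContourSpline(d=d), 5001)[:-1]
        second = np.diff(poly, 2, axis=0)
        jumps = np.linalg.norm(np.diff(second, axis=0), axis=1)
        # third-difference magnitude is O(h^3) everywhere for a C2 curve
        assert jumps.max() < 50.0 * np.median(jumps + 1e-30)

    def test_degenerate_contour_warns(self):
        spline = ContourSpline(d=np.zeros(10))
        with pytest.warns(DegenerateContourWarning):
            poly = evaluate_contour(spline, 50)
        assert np.allclose(poly, 0.0)

    def test_coarse_vs_dense_area(self, random_splines):
        for spline in random_splines[:8]:
            coarse = polygon_area(evaluate_contour(spline, 100))
            dense = polygon_area(evaluate_contour(spline, 10_000))
            assert abs(coarse - dense) / dense < 0.005


class TestPolygonOps:
    def test_unit_square_area(self):
        square = np.array([[0, 0], [1, 0], [1, 1], [0, 1.0]])
        assert polygon_area(square) == pytest.approx(1.0)
        assert polygon_area(square[::-1]) == pytest.approx(1.0)

    def test_regular_polygon_closed_form(self):
        n, r = 100, 2.3
        th = 2 * np.pi * np.arange(n) / n
        poly = r * np.stack([np.cos(th), np.sin(th)], axis=1)
        expected = 0.5 * n * r**2 * np.sin(2 * np.pi / n)
        assert polygon_area(poly) == pytest.approx(expected, rel=1e-12)

    def test_membership_basics(self, round_spline):
        poly = evaluate_contour(round_spline, 200)
        assert point_in_contour(poly, [0.0, 0.0])
        assert not point_in_contour(poly, [50.0, 0.0])
        assert point_in_contour(poly, poly[17])  # boundary counts as inside

    def test_membership_against_dense_raster_oracle(self, rng):
        hits = total = 0
        for _ in range(20):
            spline = ContourSpline(d=rng.uniform(0.1, 0.6, 10))
            poly = evaluate_contour(spline, 300)
            pts = rng.uniform(-7, 7, size=(50, 2))
            fast = points_in_polygon(poly, pts)
            # brute-force oracle: even-odd via matplotlib's path machinery
            from matplotlib.path import Path

            ref = Path(poly).contains_points(pts)
            hits += int(np.sum(fast == ref))
            total += pts.shape[0]
        assert hits / total >= 0.999

    def test_scanline_raster_matches_pointwise_test(self, rng):
        spline = ContourSpline(d=rng.uniform(0.2, 0.7, 10))
        poly = evaluate_contour(spline, 300)
        xs = np.linspace(-7, 7, 40)
        ys = np.linspace(-7, 7, 37)
        mask = rasterize_polygon(poly, xs, ys)
        X, Y = np.meshgrid(xs, ys)
        ref = points_in_polygon(poly, np.stack([X.ravel(), Y.ravel()], 1))
        assert np.array_equal(mask.ravel().astype(bool), ref)


class TestIO:
    def test_spline_json_roundtrip(self, tmp_path, round_spline):
        path = tmp_path / "spline.json"
        save_spline_json(path, round_spline)
        loaded = load_spline_json(path)
        assert np.allclose(loaded.d, round_spline.d)
        assert loaded.R == round_spline.R
        assert loaded.delta_s == round_spline.delta_s

    def test_polygon_csv_roundtrip(self, tmp_path, round_spline):
        poly = evaluate_contour(round_spline, 50)
        path = tmp_path / "poly.csv"
        save_polygon_csv(path, poly)
        assert np.allclose(load_polygon_csv(path), poly, atol=1e-8)
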