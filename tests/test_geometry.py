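"""Geometry: polygon measures, containment, and the radial profile."""

import math

import numpy as np
import pytest

from breastsym import (
    InvalidGeometryError,
    Point,
    Polygon,
    point_in_polygon,
    polygon_area,
    polygon_perimeter,
    radial_profile,
)

UNIT_SQUARE = Polygon([(0, 0), (1, 0), (1, 1), (0, 1)])
TRIANGLE_345 = Polygon([(0, 0), (4, 0), (0, 3)])


def regular_ngon(n: int, r: float, cx: float = 0.0, cy: float = 0.0) -> Polygon:
    t = 2 * np.pi * np.arange(n) / n
    return Polygon(np.column_stack([cx + r * np.cos(t), cy + r * np.sin(t)]))


def star_polygon(rng: np.random.Generator, n: int = 12) -> Polygon:
    """Random star-shaped simple polygon around the origin."""
    t = 2 * np.pi * np.arange(n) / n
    r = rng.uniform(2.0, 10.0, size=n)
    return Polygon(np.column_stack([r * np.cos(t), r * np.sin(t)]))


class TestPolygonMeasures:
    @pytest.mark.parametrize(
        "poly, area, perim",
        [(UNIT_SQUARE, 1.0, 4.0), (TRIANGLE_345, 6.0, 12.0)],
        ids=["unit-square", "3-4-5-triangle"],
    )
    def test_closed_forms(self, poly, area, perim):
        assert polygon_area(poly) == pytest.approx(area, abs=1e-12)
        assert polygon_perimeter(poly) == pytest.approx(perim, abs=1e-12)

    def test_winding_independent(self):
        rev = Polygon(UNIT_SQUARE.vertices[::-1])
        assert polygon_area(rev) == polygon_area(UNIT_SQUARE)

    def test_monte_carlo_area_oracle(self):
        """Area of a random simple 12-gon agrees with a 10^6-sample
        point-in-polygon Monte-Carlo estimate to 1%."""
        rng = np.random.default_rng(42)
        poly = star_polygon(rng)
        v = poly.vertices
        lo, hi = v.min(axis=0), v.max(axis=0)
        pts = rng.uniform(lo, hi, size=(1_000_000, 2))
        inside = _winding_inside(pts, v)
        mc_area = inside.mean() * np.prod(hi - lo)
        assert polygon_area(poly) == pytest.approx(mc_area, rel=0.01)

    def test_circle_perimeter_limit(self):
        poly = regular_ngon(360, 10.0)
        assert polygon_perimeter(poly) == pytest.approx(2 * np.pi * 10.0, rel=1e-3)

    @pytest.mark.parametrize(
        "vertices",
        [
            [(0, 0), (1, 1)],                      # too few
            [(0, 0), (0, 0), (1, 1), (0, 1)],      # repeated consecutive vertex
            [(0, 0), (1, 0), (2, 0)],              # collinear: zero area
            [(0, 0), (1, 1), (1, 0), (0, 1)],      # bow-tie self-intersection
        ],
        ids=["too-few", "repeat", "collinear", "bowtie"],
    )
    def test_invalid_polygons_rejected(self, vertices):
        with pytest.raises(InvalidGeometryError):
            Polygon(vertices)


def _winding_inside(pts: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Independent winding-number interiority oracle (vectorised)."""
    w = np.zeros(len(pts))
    n = len(v)
    for i in range(n):
        p, q = v[i], v[(i + 1) % n]
        cross = (q[0] - p[0]) * (pts[:, 1] - p[1]) - (pts[:, 0] - p[0]) * (q[1] - p[1])
        up = (p[1] <= pts[:, 1]) & (q[1] > pts[:, 1])
        dn = (p[1] > pts[:, 1]) & (q[1] <= pts[:, 1])
        w += np.where(up & (cross > 0), 1, 0) + np.where(dn & (cross < 0), -1, 0)
    return w != 0


class TestContainment:
    def test_interior_and_exterior(self):
        assert point_in_polygon(Point(0.5, 0.5), UNIT_SQUARE)
        assert not point_in_polygon(Point(2, 2), UNIT_SQUARE)

    def test_boundary_is_outside(self):
        assert not point_in_polygon(Point(0.0, 0.5), UNIT_SQUARE)

    def test_against_winding_number_oracle(self):
        rng = np.random.default_rng(3)
        poly = star_polygon(rng)
        pts = rng.uniform(-11, 11, size=(1000, 2))
        expect = _winding_inside(pts, poly.vertices)
        got = np.array([point_in_polygon(Point(*p), poly) for p in pts])
        assert np.array_equal(got, expect)


class TestRadialProfile:
    def test_circle_all_radii_equal(self):
        poly = regular_ngon(720, 5.0)
        prof = radial_profile(Point(0, 0), poly, n=24)
        assert len(prof) == 24
        assert np.allclose(prof.distances, 5.0, atol=0.01)
        assert np.allclose(prof.angles_deg, 15.0 * np.arange(24))

    def test_ellipse_closed_form(self):
        """2:1 ellipse: 5 px at 12 o'clock, 10 px at 3 o'clock, and the polar
        radius formula everywhere in between."""
        a, b = 10.0, 5.0
        t = 2 * np.pi * np.arange(720) / 720
        poly = Polygon(np.column_stack([a * np.cos(t), b * np.sin(t)]))
        prof = radial_profile(Point(0, 0), poly, n=24, clockwise=True)
        assert prof.distances[0] == pytest.approx(b, abs=0.01)   # 12 o'clock (up)
        assert prof.distances[6] == pytest.approx(a, abs=0.01)   # 3 o'clock (right)
        # closed-form polar radius along each cast direction
        ang = 2 * np.pi * np.arange(24) / 24
        dx, dy = np.sin(ang), -np.cos(ang)
        expect = a * b / np.hypot(b * dx, a * dy)
        assert np.allclose(prof.distances, expect, atol=0.01)

    def test_central_symmetry_opposite_cuts(self):
        """A centrally symmetric polygon has distances[i] == distances[i+12]."""
        rng = np.random.default_rng(11)
        t = 2 * np.pi * np.arange(40) / 40
        r = np.concatenate([rng.uniform(4, 9, 20)] * 2)  # r(t) = r(t + pi)
        poly = Polygon(np.column_stack([r * np.cos(t), r * np.sin(t)]))
        prof = radial_profile(Point(0, 0), poly, n=24)
        assert np.allclose(prof.distances, np.roll(prof.distances, 12), atol=1e-9)

    def test_mirror_duality(self):
        """Flipping the scene about a vertical axis and reversing orientation
        reproduces the profile."""
        rng = np.random.default_rng(5)
        poly = star_polygon(rng)
        center = Point(0.3, -0.2)
        orig = radial_profile(center, poly, n=24, clockwise=True)
        mirrored = radial_profile(
            center.mirrored_x(7.0), poly.mirrored_x(7.0), n=24, clockwise=False
        )
        assert np.allclose(orig.distances, mirrored.distances, atol=1e-9)

    def test_nearest_intersection_on_nonconvex_border(self):
        """On a non-star geometry the ray takes the nearest crossing."""
        # U-shaped polygon; a ray cast rightward from inside one arm crosses
        # the boundary three times (x = 3, 7, 10) and must stop at the first.
        poly = Polygon(
            [(0, 0), (10, 0), (10, 10), (7, 10), (7, 3), (3, 3), (3, 10), (0, 10)]
        )
        prof = radial_profile(Point(1.5, 5.0), poly, n=4, clockwise=True)
        assert prof.distances[1] == pytest.approx(1.5)  # 3 o'clock: wall at x=3

    def test_center_outside_rejected(self):
        with pytest.raises(InvalidGeometryError):
            radial_profile(Point(5, 5), UNIT_SQUARE)
        with pytest.raises(InvalidGeometryError):  # on the boundary
            radial_profile(Point(0.0, 0.5), UNIT_SQUARE)

    def test_n_is_parametric(self):
        prof = radial_profile(Point(0.5, 0.5), UNIT_SQUARE, n=8)
        assert len(prof) == 8
        assert prof.angles_deg[1] == pytest.approx(45.0)


class TestSimilarityInvariance:
    """Area/perimeter transform as s^2 and s; both are rigid-motion invariant."""

    @pytest.mark.parametrize("s", [0.25, 1.0, 3.7])
    def test_scaling(self, s):
        rng = np.random.default_rng(8)
        poly = star_polygon(rng)
        scaled = poly.scaled_about(Point(1.0, -2.0), s)
        assert scaled.area == pytest.approx(s**2 * poly.area, rel=1e-12)
        assert scaled.perimeter == pytest.approx(s * poly.perimeter, rel=1e-12)

    def test_rigid_motions(self):
        rng = np.random.default_rng(9)
        poly = star_polygon(rng)
        moved = poly.translated(17.0, -4.0).rotated_about(Point(0, 0), 1.1)
        assert moved.area == pytest.approx(poly.area, rel=1e-9)
        assert moved.perimeter == pytest.approx(poly.perimeter, rel=1e-9)
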