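"""Planar geometry on landmark annotations.

Everything works in image pixel space: ``x`` grows rightward (columns),
``y`` grows *downward* (rows), matching what an annotator sees on screen.
Consequently "12 o'clock" is the direction of decreasing ``y`` and
"clockwise" means clockwise as displayed (12 -> 3 -> 6 -> 9 o'clock).

Polygon bookkeeping (validity, area, perimeter, containment) is delegated to
shapely; the radial ray casting is implemented here directly so that the
nearest-intersection rule and mirror symmetry are exact and auditable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import shapely.geometry as _sg

from .errors import InvalidGeometryError

__all__ = [
    "Point",
    "Polygon",
    "RadialProfile",
    "polygon_area",
    "polygon_perimeter",
    "point_in_polygon",
    "radial_profile",
]


@dataclass(frozen=True)
class Point:
    """A 2-D pixel coordinate (x = column, rightward; y = row, downward)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise InvalidGeometryError(f"point coordinates must be finite, got ({self.x}, {self.y})")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)

    def distance_to(self, other: "Point") -> float:
        return math.hypot(self.x - other.x, self.y - other.y)

    def translated(self, dx: float, dy: float) -> "Point":
        return Point(self.x + dx, self.y + dy)

    def mirrored_x(self, axis_x: float) -> "Point":
        """Reflect about the vertical line ``x = axis_x``."""
        return Point(2.0 * axis_x - self.x, self.y)


class Polygon:
    """A simple closed polygon given by an ordered vertex ring.

    The ring is implicitly closed (the last vertex connects back to the
    first).  Construction validates the invariants: at least 3 vertices,
    consecutive vertices distinct, no self-intersection, strictly positive
    enclosed area.  Either winding direction is accepted; area and perimeter
    are winding-independent.
    """

    __slots__ = ("_v", "_shape")

    def __init__(self, vertices: Iterable[Point | Sequence[float]]):
        arr = np.array(
            [(v.x, v.y) if isinstance(v, Point) else (float(v[0]), float(v[1])) for v in vertices],
            dtype=float,
        )
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise InvalidGeometryError("polygon vertices must be a sequence of 2-D points")
        if not np.all(np.isfinite(arr)):
            raise InvalidGeometryError("polygon vertices must be finite")
        if len(arr) < 3:
            raise InvalidGeometryError(f"polygon needs at least 3 vertices, got {len(arr)}")
        closed_pairs = np.vstack([arr, arr[:1]])
        if np.any(np.all(closed_pairs[1:] == closed_pairs[:-1], axis=1)):
            raise InvalidGeometryError("consecutive polygon vertices must be distinct")
        shape = _sg.Polygon(arr)
        if not shape.is_valid or not shape.is_simple:
            raise InvalidGeometryError("polygon must be simple (no self-intersection)")
        if shape.area <= 0.0:
            raise InvalidGeometryError("polygon is degenerate: enclosed area is not strictly positive")
        self._v = arr
        self._v.setflags(write=False)
        self._shape = shape

    # -- accessors ---------------------------------------------------------
    @property
    def vertices(self) -> np.ndarray:
        """Read-only (n, 2) vertex array."""
        return self._v

    def __len__(self) -> int:
        return len(self._v)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Polygon) and self._v.shape == other._v.shape and bool(np.all(self._v == other._v))

    @property
    def area(self) -> float:
        """Enclosed area in squared pixels (shoelace magnitude)."""
        return self._shape.area

    @property
    def perimeter(self) -> float:
        """Sum of Euclidean edge lengths, closing edge included."""
        return self._shape.length

    @property
    def centroid(self) -> Point:
        c = self._shape.centroid
        return Point(c.x, c.y)

    def contains(self, pt: Point) -> bool:
        """True iff ``pt`` is strictly interior (boundary counts as outside)."""
        return self._shape.contains(_sg.Point(pt.x, pt.y))

    # -- similarity transforms (used by the synthetic generator) ----------
    def translated(self, dx: float, dy: float) -> "Polygon":
        return Polygon(self._v + np.array([dx, dy]))

    def scaled_about(self, center: Point, factor: float) -> "Polygon":
        """Isotropic scaling about ``center``; area scales by factor**2."""
        if factor <= 0:
            raise InvalidGeometryError("scale factor must be positive")
        c = center.as_array()
        return Polygon(c + factor * (self._v - c))

    def rotated_about(self, center: Point, angle_rad: float) -> "Polygon":
        c = center.as_array()
        ca, sa = math.cos(angle_rad), math.sin(angle_rad)
        rot = np.array([[ca, -sa], [sa, ca]])
        return Polygon(c + (self._v - c) @ rot.T)

    def mirrored_x(self, axis_x: float) -> "Polygon":
        """Reflect about the vertical line ``x = axis_x`` (winding reverses)."""
        out = self._v.copy()
        out[:, 0] = 2.0 * axis_x - out[:, 0]
        return Polygon(out)


@dataclass(frozen=True)
class RadialProfile:
    """Distances from a center to the breast border along equally spaced rays.

    ``angles_deg[i]`` is the rotation of ray *i* from 12 o'clock, advancing
    in the cast direction; the default 24 rays step by 15 degrees.
    """

    distances: np.ndarray
    angles_deg: np.ndarray
    clockwise: bool = True

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        a = np.asarray(self.angles_deg, dtype=float)
        object.__setattr__(self, "distances", d)
        object.__setattr__(self, "angles_deg", a)
        if d.shape != a.shape or d.ndim != 1:
            raise InvalidGeometryError("distances and angles must be 1-D and equally long")
        if np.any(d <= 0):
            raise InvalidGeometryError("all radial distances must be strictly positive")
        step = 360.0 / len(d)
        if not np.allclose(a, step * np.arange(len(d)), atol=1e-9):
            raise InvalidGeometryError("ray angles must be equally spaced starting at 12 o'clock")

    def __len__(self) -> int:
        return len(self.distances)


def polygon_area(p: Polygon) -> float:
    """Enclosed area of ``p`` in squared pixels, independent of winding."""
    return p.area


def polygon_perimeter(p: Polygon) -> float:
    """Perimeter of ``p`` in pixels, closing edge included."""
    return p.perimeter


def point_in_polygon(pt: Point, p: Polygon) -> bool:
    """Strict interior test; points on the boundary are reported outside."""
    return p.contains(pt)


def _ray_directions(n: int, clockwise: bool) -> np.ndarray:
    """Unit direction of each ray in image (y-down) coordinates.

    Ray 0 points to 12 o'clock, i.e. (0, -1).  On the displayed image a
    clockwise sweep goes 12 -> 3 o'clock, which in y-down coordinates is
    (sin t, -cos t); counter-clockwise is its x-mirror.
    """
    t = 2.0 * np.pi * np.arange(n) / n
    sx = np.sin(t) if clockwise else -np.sin(t)
    return np.column_stack([sx, -np.cos(t)])


def radial_profile(center: Point, border: Polygon, n: int = 24, clockwise: bool = True) -> RadialProfile:
    """Cast ``n`` equally spaced rays from ``center`` to the border.

    Rays start at 12 o'clock (image-up) and advance by 360/n degrees in the
    requested rotational direction *as seen on the displayed image*.  Each
    distance is from the center to the NEAREST crossing of that ray with the
    polygon boundary — robust for the near-star-shaped contours produced by
    manual breast-border tracing.

    Parameters
    ----------
    center : Point
        Ray origin; must lie strictly inside ``border`` (a nipple exactly on
        the border would give a zero distance and undefined ratio factors).
    border : Polygon
        The breast border.
    n : int
        Number of cuts; the clinical protocol uses 24.
    clockwise : bool
        Sweep direction in image space.  Mirrored breasts are cast with
        opposite directions so cut *i* faces cut *i* anatomically.
    """
    if n < 3:
        raise InvalidGeometryError(f"need at least 3 rays, got {n}")
    if not border.contains(center):
        raise InvalidGeometryError("ray origin must lie strictly inside the border polygon")

    dirs = _ray_directions(n, clockwise)                       # (n, 2)
    p = border.vertices                                        # (m, 2)
    q = np.roll(p, -1, axis=0)
    e = q - p                                                  # edge vectors (m, 2)
    w = p - center.as_array()                                  # origin -> edge start (m, 2)

    # Solve center + t*d = p + u*e per (ray, edge) via 2-D cross products.
    denom = dirs[:, 0, None] * e[None, :, 1] - dirs[:, 1, None] * e[None, :, 0]   # (n, m)
    cross_we = w[None, :, 0] * e[None, :, 1] - w[None, :, 1] * e[None, :, 0]
    cross_wd = w[None, :, 0] * dirs[:, 1, None] - w[None, :, 1] * dirs[:, 0, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = cross_we / denom
        u = cross_wd / denom
    hit = (np.abs(denom) > 1e-300) & (u >= 0.0) & (u <= 1.0) & (t > 1e-12)
    t = np.where(hit, t, np.inf)
    dist = t.min(axis=1)
    # An interior origin crosses the boundary on every ray.
    assert np.all(np.isfinite(dist)), "ray failed to hit the polygon boundary"
    return RadialProfile(distances=dist, angles_deg=(360.0 / n) * np.arange(n), clockwise=clockwise)
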