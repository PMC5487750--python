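"""Parametric synthetic annotations with controllable asymmetry.

No patient photographs are needed to exercise the scoring pipeline: this
module builds paired breast contours from a smooth radial function — an
ellipse with an optional inferior "droop" elongation and, optionally, a
seeded low-order harmonic wiggle — mirrors them exactly about a torso
midline, and then applies controlled unilateral perturbations (nipple
shift, contour scaling, vertical displacement) or per-rater annotation
jitter.

The contour family is star-shaped about its center by construction, which
guarantees the radial profile is well defined, and exact mirroring makes
the zero of the symmetry score testable to numerical precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .annotation import BreastAnnotation
from .errors import AnnotationError, BreastSymError
from .geometry import Point, Polygon

__all__ = [
    "ShapeParams",
    "AsymmetrySpec",
    "make_symmetric_pair",
    "apply_asymmetry",
    "simulate_rater_panel",
    "random_shape_params",
    "simulate_bsi_panel",
]


@dataclass(frozen=True)
class ShapeParams:
    """Parameters of one synthetic breast contour (built for the viewer-left
    side, then mirrored).

    Defaults describe a plausible frontal annotation on a ~800 px wide
    image: semi-axes 120 x 100 px, mild droop, nipple slightly below the
    contour center.

    Attributes
    ----------
    semi_axis_horizontal, semi_axis_vertical : float
        Ellipse semi-axes in pixels.
    droop : float
        Inferior elongation coefficient (>= 0); the radius toward the image
        bottom is stretched by up to ``1 + droop``.
    nipple_offset : (float, float)
        Nipple position relative to the contour center, pixels.
    torso_midline_x : float
        Vertical mirror axis, pixels.
    jugulum : Point
        Suprasternal-notch landmark (on the midline for a symmetric torso).
    center_offset : (float, float)
        Contour center relative to the jugulum: (distance from the midline
        toward the left side, distance below the jugulum).  Defaults scale
        with the semi-axes.
    n_vertices : int
        Polygonal discretization of the contour (>= 36).
    seed : int or None
        Seed for the harmonic contour wiggle; ``None`` gives the plain
        ellipse-with-droop contour.
    contour_wiggle : float
        Relative amplitude of the seeded smooth wiggle (0 disables it).
    """

    semi_axis_horizontal: float = 120.0
    semi_axis_vertical: float = 100.0
    droop: float = 0.2
    nipple_offset: tuple[float, float] = (0.0, 10.0)
    torso_midline_x: float = 400.0
    jugulum: Point = field(default_factory=lambda: Point(400.0, 80.0))
    center_offset: tuple[float, float] | None = None
    n_vertices: int = 180
    seed: int | None = None
    contour_wiggle: float = 0.0

    def __post_init__(self) -> None:
        if self.semi_axis_horizontal <= 0 or self.semi_axis_vertical <= 0:
            raise ValueError("semi-axes must be positive")
        if self.droop < 0:
            raise ValueError("droop must be nonnegative")
        if self.n_vertices < 36:
            raise ValueError(f"n_vertices must be >= 36, got {self.n_vertices}")
        if not (0.0 <= self.contour_wiggle < 0.3):
            raise ValueError("contour_wiggle must lie in [0, 0.3)")

    def _center(self) -> Point:
        a, b = self.semi_axis_horizontal, self.semi_axis_vertical
        dx, dy = self.center_offset if self.center_offset is not None else (1.5 * a, 1.6 * b)
        return Point(self.torso_midline_x - dx, self.jugulum.y + dy)


@dataclass(frozen=True)
class AsymmetrySpec:
    """A unilateral perturbation of an otherwise finished annotation.

    Attributes
    ----------
    side : {"left", "right"}
        Which breast (viewer orientation) is perturbed.
    nipple_shift : (float, float)
        Displacement of that side's nipple, pixels (y > 0 is downward).
    contour_scale : float
        Isotropic linear scaling of that side's border about its nipple;
        the enclosed area scales by ``contour_scale ** 2`` and the
        perimeter by ``contour_scale``.
    vertical_shift : float
        Downward displacement of the whole side (border and nipple), pixels.
    """

    side: str = "right"
    nipple_shift: tuple[float, float] = (0.0, 0.0)
    contour_scale: float = 1.0
    vertical_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.contour_scale <= 0:
            raise ValueError("contour_scale must be positive")


def _contour_radii(p: ShapeParams) -> tuple[np.ndarray, np.ndarray]:
    """Radii of the contour at ``n_vertices`` equally spaced polar angles
    (image coordinates: angle 0 along +x, positive toward +y = downward)."""
    a, b = p.semi_axis_horizontal, p.semi_axis_vertical
    phi = 2.0 * np.pi * np.arange(p.n_vertices) / p.n_vertices
    r = a * b / np.hypot(b * np.cos(phi), a * np.sin(phi))
    # sin(phi) > 0 points down the image, i.e. toward the inframammary fold
    r = r * (1.0 + p.droop * np.maximum(0.0, np.sin(phi)))
    if p.seed is not None and p.contour_wiggle > 0.0:
        rng = np.random.default_rng(p.seed)
        mod = np.ones_like(phi)
        for h in range(2, 7):
            amp = rng.uniform(0.0, p.contour_wiggle / (h - 1))
            phase = rng.uniform(0.0, 2.0 * np.pi)
            mod += amp * np.cos(h * phi + phase)
        r = r * mod
    return phi, r


def make_symmetric_pair(p: ShapeParams) -> BreastAnnotation:
    """Build an exactly mirror-symmetric annotation from one contour.

    The left contour and nipple are generated from ``p``; the right side is
    their reflection about ``torso_midline_x``.  The result satisfies every
    annotation invariant and scores a BSI of 0 up to floating-point error.
    """
    center = p._center()
    phi, r = _contour_radii(p)
    verts = np.column_stack(
        [center.x + r * np.cos(phi), center.y + r * np.sin(phi)]
    )
    border_left = Polygon(verts)
    nipple_left = Point(center.x + p.nipple_offset[0], center.y + p.nipple_offset[1])
    if not border_left.contains(nipple_left):
        raise AnnotationError(
            "nipple_offset places the nipple outside the contour", field="nipple_left"
        )
    m = p.torso_midline_x
    return BreastAnnotation(
        jugulum=p.jugulum,
        nipple_left=nipple_left,
        nipple_right=nipple_left.mirrored_x(m),
        border_left=border_left,
        border_right=border_left.mirrored_x(m),
        image_id=f"synthetic-seed{p.seed}",
    )


def apply_asymmetry(ann: BreastAnnotation, spec: AsymmetrySpec) -> BreastAnnotation:
    """Apply a unilateral perturbation; the untouched side is returned as-is.

    Order of operations on the perturbed side: scale the border about the
    current nipple, shift the whole side down by ``vertical_shift``, then
    displace the nipple by ``nipple_shift``.  The perturbed nipple must stay
    strictly inside the perturbed border.
    """
    if spec.side == "left":
        nipple, border = ann.nipple_left, ann.border_left
    else:
        nipple, border = ann.nipple_right, ann.border_right

    border = border.scaled_about(nipple, spec.contour_scale)
    if spec.vertical_shift != 0.0:
        border = border.translated(0.0, spec.vertical_shift)
        nipple = nipple.translated(0.0, spec.vertical_shift)
    nipple = nipple.translated(*spec.nipple_shift)
    if not border.contains(nipple):
        raise AnnotationError(
            f"asymmetry spec moves nipple_{spec.side} outside its border",
            field=f"nipple_{spec.side}",
        )
    if spec.side == "left":
        return replace(ann, nipple_left=nipple, border_left=border)
    return replace(ann, nipple_right=nipple, border_right=border)


def simulate_rater_panel(
    ann: BreastAnnotation,
    k: int,
    jitter_sd: float,
    seed: int | None = None,
    max_retries: int = 20,
) -> list[BreastAnnotation]:
    """Emulate ``k`` independent annotators re-annotating the same image.

    Every landmark point and border vertex receives isotropic Gaussian
    jitter with per-vertex standard deviation ``jitter_sd`` pixels — one
    knob standing in for click imprecision and border-tracing wiggle alike.
    Landmark clicks are independent; border jitter is smoothly correlated
    along the contour (a traced outline wanders, it does not flicker vertex
    by vertex), which also keeps large jitter from shredding the ring into
    self-intersections.  Deterministic for a fixed seed.  A jitter draw
    that still produces an invalid annotation (self-intersecting border,
    ejected nipple) is resampled up to ``max_retries`` times per rater
    before giving up.
    """
    if k < 2:
        raise ValueError(f"need at least 2 raters, got {k}")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be nonnegative")
    import warnings

    rng = np.random.default_rng(seed)
    panel: list[BreastAnnotation] = []
    for rater in range(k):
        for attempt in range(max_retries + 1):
            try:
                with warnings.catch_warnings():
                    # large jitter may flip jugulum/nipple order; that is part
                    # of the simulated annotator error, not a data problem
                    warnings.simplefilter("ignore", UserWarning)
                    panel.append(_jittered(ann, rng, jitter_sd, rater))
                break
            except BreastSymError:
                if attempt == max_retries:
                    raise AnnotationError(
                        f"could not produce a valid jittered annotation for rater {rater} "
                        f"after {max_retries + 1} attempts (jitter_sd={jitter_sd})"
                    )
    return panel


def _smooth_ring_noise(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    """Circularly correlated Gaussian noise with per-vertex marginal sd."""
    noise = rng.normal(0.0, 1.0, size=(n, 2))
    width = max(1.0, n / 12.0)  # correlation length ~ 30 degrees of arc
    idx = np.arange(n)
    lag = np.minimum(idx, n - idx)
    kernel = np.exp(-0.5 * (lag / width) ** 2)
    kernel /= kernel.sum()
    smoothed = np.real(np.fft.ifft(np.fft.fft(noise, axis=0) * np.fft.fft(kernel)[:, None], axis=0))
    return sd * smoothed / np.sqrt(np.sum(kernel**2))


def _jittered(
    ann: BreastAnnotation, rng: np.random.Generator, sd: float, rater: int
) -> BreastAnnotation:
    def jp(p: Point) -> Point:
        dx, dy = rng.normal(0.0, sd, size=2) if sd > 0 else (0.0, 0.0)
        return Point(p.x + dx, p.y + dy)

    def jpoly(poly: Polygon) -> Polygon:
        v = poly.vertices
        noise = _smooth_ring_noise(rng, len(v), sd) if sd > 0 else 0.0
        return Polygon(v + noise)

    return BreastAnnotation(
        jugulum=jp(ann.jugulum),
        nipple_left=jp(ann.nipple_left),
        nipple_right=jp(ann.nipple_right),
        border_left=jpoly(ann.border_left),
        border_right=jpoly(ann.border_right),
        image_id=f"{ann.image_id}-rater{rater}",
    )


def random_shape_params(
    seed: int | np.random.Generator | None = None, n_vertices: int = 120
) -> ShapeParams:
    """Draw a random but realistic ShapeParams (for property tests and
    simulated cohorts): semi-axes 80-160 x 70-140 px, droop up to 0.4, a
    nipple within the central third of the contour, and a mild seeded
    contour wiggle."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a = rng.uniform(80.0, 160.0)
    b = rng.uniform(70.0, 140.0)
    rad = 0.25 * min(a, b) * np.sqrt(rng.uniform(0.0, 1.0))
    ang = rng.uniform(0.0, 2.0 * np.pi)
    return ShapeParams(
        semi_axis_horizontal=a,
        semi_axis_vertical=b,
        droop=rng.uniform(0.0, 0.4),
        nipple_offset=(rad * np.cos(ang), rad * np.sin(ang)),
        center_offset=(rng.uniform(1.2, 1.8) * a, rng.uniform(1.3, 1.9) * b),
        n_vertices=n_vertices,
        seed=int(rng.integers(0, 2**31 - 1)),
        contour_wiggle=rng.uniform(0.0, 0.08),
    )


def simulate_bsi_panel(
    subjects: Sequence[BreastAnnotation],
    k: int,
    jitter_sd: float,
    seed: int | None = None,
    n_cuts: int = 24,
):
    """Score a simulated rater panel: each of ``k`` virtual raters
    re-annotates every subject with jitter, and the BSI of every copy is
    computed.  Returns a subjects x raters :class:`pandas.DataFrame` of BSI
    scores ready for :func:`breastsym.agreement.icc_absolute_agreement`."""
    import pandas as pd

    from .bsi import score_annotation

    rng = np.random.default_rng(seed)
    rows = []
    ids = []
    for s, ann in enumerate(subjects):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        panel = simulate_rater_panel(ann, k=k, jitter_sd=jitter_sd, seed=sub_seed)
        rows.append([score_annotation(a, n_cuts=n_cuts).bsi for a in panel])
        ids.append(ann.image_id or f"subject{s}")
    return pd.DataFrame(rows, index=ids, columns=[f"rater{j}" for j in range(k)])
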