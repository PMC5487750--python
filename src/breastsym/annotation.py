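"""The landmark annotation of one frontal-torso image.

One annotation carries the three clicked landmarks (jugulum = suprasternal
notch, two nipple centers) and the two manually traced breast borders.
"Left" and "right" are viewer-relative, i.e. as seen on the displayed
image, matching how the borders are drawn on screen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

from .errors import AnnotationError
from .geometry import Point, Polygon

__all__ = ["BreastAnnotation"]


@dataclass(frozen=True)
class BreastAnnotation:
    """Full landmark set for one image.

    Invariants enforced on construction:

    * each nipple lies strictly inside its own border (a nipple on or outside
      the border would make the radial ratio factors undefined);
    * the two borders share no vertices;
    * the jugulum should lie above both nipples (smaller y) — violation is
      anatomically implausible but only warned about, since unusual poses can
      produce it.
    """

    jugulum: Point
    nipple_left: Point
    nipple_right: Point
    border_left: Polygon
    border_right: Polygon
    image_id: str = ""

    def __post_init__(self) -> None:
        if not self.border_left.contains(self.nipple_left):
            raise AnnotationError(
                "nipple_left must lie strictly inside border_left", field="nipple_left"
            )
        if not self.border_right.contains(self.nipple_right):
            raise AnnotationError(
                "nipple_right must lie strictly inside border_right", field="nipple_right"
            )
        left = {tuple(v) for v in self.border_left.vertices}
        right = {tuple(v) for v in self.border_right.vertices}
        if left & right:
            raise AnnotationError(
                "border_left and border_right must not share vertices", field="border_right"
            )
        if not (self.jugulum.y < self.nipple_left.y and self.jugulum.y < self.nipple_right.y):
            warnings.warn(
                "jugulum does not lie above both nipples (larger y is lower in the image); "
                "check the annotation",
                stacklevel=2,
            )

    # -- whole-annotation similarity transforms ---------------------------
    def translated(self, dx: float, dy: float) -> "BreastAnnotation":
        return replace(
            self,
            jugulum=self.jugulum.translated(dx, dy),
            nipple_left=self.nipple_left.translated(dx, dy),
            nipple_right=self.nipple_right.translated(dx, dy),
            border_left=self.border_left.translated(dx, dy),
            border_right=self.border_right.translated(dx, dy),
        )

    def scaled_about(self, center: Point, factor: float) -> "BreastAnnotation":
        def sp(p: Point) -> Point:
            return Point(center.x + factor * (p.x - center.x), center.y + factor * (p.y - center.y))

        return replace(
            self,
            jugulum=sp(self.jugulum),
            nipple_left=sp(self.nipple_left),
            nipple_right=sp(self.nipple_right),
            border_left=self.border_left.scaled_about(center, factor),
            border_right=self.border_right.scaled_about(center, factor),
        )

    def mirrored_x(self, axis_x: float) -> "BreastAnnotation":
        """Reflect the whole scene about ``x = axis_x`` and swap sides.

        The result shows the same anatomy with left/right exchanged, so every
        bilateral symmetry factor is unchanged.
        """
        return replace(
            self,
            jugulum=self.jugulum.mirrored_x(axis_x),
            nipple_left=self.nipple_right.mirrored_x(axis_x),
            nipple_right=self.nipple_left.mirrored_x(axis_x),
            border_left=self.border_right.mirrored_x(axis_x),
            border_right=self.border_left.mirrored_x(axis_x),
        )
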