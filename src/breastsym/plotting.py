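"""Overlay rendering: landmarks, borders and radial cuts on (optionally) the
source photograph."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless rendering; callers never need a display
import matplotlib.pyplot as plt
import numpy as np

from .annotation import BreastAnnotation
from .geometry import radial_profile, _ray_directions

__all__ = ["plot_annotation", "save_overlay"]


def plot_annotation(ann: BreastAnnotation, image=None, n_cuts: int = 24, ax=None):
    """Draw an annotation (and, if given, its image) onto a matplotlib axes.

    ``image`` may be an array or a path to a raster file.  Borders are drawn
    as closed outlines, the radial cuts as thin rays from each nipple, and
    the three clicked landmarks as markers.  Returns the axes.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 7))
    if image is not None:
        if isinstance(image, (str, Path)):
            image = plt.imread(str(image))
        ax.imshow(image)

    for border, nipple, clockwise, color in (
        (ann.border_left, ann.nipple_left, True, "tab:blue"),
        (ann.border_right, ann.nipple_right, False, "tab:red"),
    ):
        v = np.vstack([border.vertices, border.vertices[:1]])
        ax.plot(v[:, 0], v[:, 1], color=color, lw=1.5)
        prof = radial_profile(nipple, border, n=n_cuts, clockwise=clockwise)
        dirs = _ray_directions(n_cuts, clockwise)
        for d, (dx, dy) in zip(prof.distances, dirs):
            ax.plot([nipple.x, nipple.x + d * dx], [nipple.y, nipple.y + d * dy],
                    color=color, lw=0.4, alpha=0.6)
        ax.plot(nipple.x, nipple.y, "o", color=color, ms=5)

    ax.plot(ann.jugulum.x, ann.jugulum.y, "k^", ms=7, label="jugulum")
    if image is None:
        ax.invert_yaxis()  # pixel convention: y grows downward
    ax.set_aspect("equal")
    ax.set_title(ann.image_id)
    return ax


def save_overlay(ann: BreastAnnotation, out_path: str | Path, image=None, n_cuts: int = 24) -> None:
    """Render the annotation overlay to a PNG file."""
    ax = plot_annotation(ann, image=image, n_cuts=n_cuts)
    ax.figure.savefig(out_path, dpi=120, bbox_inches="tight")
    plt.close(ax.figure)
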