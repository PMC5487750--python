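"""Annotation, weight-config and report files.

Annotation format
-----------------
One annotation is a UTF-8 JSON document (an explicit, versioned schema for
the landmark clicks and the traced borders):

.. code-block:: json

    {
      "schema_version": "1.0",
      "image_id": "patient-042",
      "image_path": null,
      "rater_id": null,
      "timestamp": null,
      "jugulum": [400.0, 80.0],
      "nipple_left": [215.0, 260.0],
      "nipple_right": [585.0, 260.0],
      "border_left": [[x, y], ...],
      "border_right": [[x, y], ...]
    }

Coordinates are floating-point pixels, 0-based, y increasing downward;
left/right are viewer-relative.  ``image_path``, ``rater_id`` and
``timestamp`` are optional metadata and may be null or absent.  The writer
emits canonical formatting (fixed key order, 2-space indent) so that
write -> read -> write round-trips byte-identically.

Weight config format
--------------------
A plain ``key = value`` text file (``#`` comments allowed) with the six
weight keys and optionally ``scale_max``:

.. code-block:: text

    w_direct = 0.0974
    w_horizontal = 0.0974
    ...
    scale_max = 15

Weights are renormalized to sum 1 on load.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, TextIO

from . import __version__
from .annotation import BreastAnnotation
from .bsi import BSIResult, WeightConfig
from .errors import AnnotationError, AnnotationFormatError, InvalidGeometryError
from .geometry import Point, Polygon

__all__ = [
    "SCHEMA_VERSION",
    "read_annotation",
    "write_annotation",
    "read_weight_config",
    "write_weight_config",
    "write_score_report",
]

SCHEMA_VERSION = "1.0"

_REPORT_COLUMNS = (
    "image_id",
    "f_direct",
    "f_horizontal",
    "f_vertical",
    "f_radial",
    "f_area",
    "f_circumference",
    "bsi_mammilla",
    "bsi_area",
    "bsi",
    "harris",
)


def _coord_pair(obj: object, field: str) -> Point:
    if (
        not isinstance(obj, (list, tuple))
        or len(obj) != 2
        or not all(isinstance(v, (int, float)) and not isinstance(v, bool) for v in obj)
    ):
        raise AnnotationFormatError(
            f"field {field!r} must be a [x, y] pair of numbers", field=field
        )
    try:
        return Point(float(obj[0]), float(obj[1]))
    except InvalidGeometryError as exc:
        raise AnnotationFormatError(f"field {field!r}: {exc}", field=field) from exc


def _coord_ring(obj: object, field: str) -> Polygon:
    if not isinstance(obj, list) or len(obj) < 3:
        raise AnnotationFormatError(
            f"field {field!r} must be a list of at least 3 [x, y] pairs", field=field
        )
    pts = [_coord_pair(v, f"{field}[{i}]") for i, v in enumerate(obj)]
    try:
        return Polygon(pts)
    except InvalidGeometryError as exc:
        raise AnnotationFormatError(f"field {field!r}: {exc}", field=field) from exc


def read_annotation(path: str | Path) -> BreastAnnotation:
    """Load and fully validate an annotation file.

    Raises :class:`AnnotationFormatError` for structural problems (naming
    the offending field) and :class:`AnnotationError` for geometric
    invariant violations (naming the offending landmark).
    """
    path = Path(path)
    try:
        raw = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise AnnotationFormatError(f"cannot read {path}: {exc}") from exc
    try:
        doc = json.loads(raw)
    except json.JSONDecodeError as exc:
        raise AnnotationFormatError(
            f"{path}: not valid JSON (line {exc.lineno}, column {exc.colno}): {exc.msg}"
        ) from exc
    if not isinstance(doc, dict):
        raise AnnotationFormatError(f"{path}: top level must be a JSON object")

    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise AnnotationFormatError(
            f"{path}: unsupported schema_version {version!r} (expected {SCHEMA_VERSION!r})",
            field="schema_version",
        )
    for req in ("jugulum", "nipple_left", "nipple_right", "border_left", "border_right"):
        if req not in doc:
            raise AnnotationFormatError(f"{path}: missing required field {req!r}", field=req)

    return BreastAnnotation(
        jugulum=_coord_pair(doc["jugulum"], "jugulum"),
        nipple_left=_coord_pair(doc["nipple_left"], "nipple_left"),
        nipple_right=_coord_pair(doc["nipple_right"], "nipple_right"),
        border_left=_coord_ring(doc["border_left"], "border_left"),
        border_right=_coord_ring(doc["border_right"], "border_right"),
        image_id=str(doc.get("image_id", path.stem)),
    )


def write_annotation(
    ann: BreastAnnotation,
    path: str | Path,
    image_path: str | None = None,
    rater_id: str | None = None,
    timestamp: str | None = None,
) -> None:
    """Write an annotation in canonical formatting (lossless round-trip:
    coordinates are serialized with ``repr`` precision)."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "image_id": ann.image_id,
        "image_path": image_path,
        "rater_id": rater_id,
        "timestamp": timestamp,
        "jugulum": [ann.jugulum.x, ann.jugulum.y],
        "nipple_left": [ann.nipple_left.x, ann.nipple_left.y],
        "nipple_right": [ann.nipple_right.x, ann.nipple_right.y],
        "border_left": [[float(x), float(y)] for x, y in ann.border_left.vertices],
        "border_right": [[float(x), float(y)] for x, y in ann.border_right.vertices],
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")


# -- weight config ---------------------------------------------------------

_WEIGHT_KEYS = ("w_direct", "w_horizontal", "w_vertical", "w_radial", "w_area", "w_circumference")


def read_weight_config(path: str | Path) -> WeightConfig:
    """Parse a ``key = value`` weight file; weights are renormalized to sum 1."""
    path = Path(path)
    values: dict[str, float] = {}
    scale_max = 15.0
    try:
        lines = path.read_text(encoding="utf-8").splitlines()
    except OSError as exc:
        raise AnnotationFormatError(f"cannot read {path}: {exc}") from exc
    for lineno, line in enumerate(lines, start=1):
        stripped = line.split("#", 1)[0].strip()
        if not stripped:
            continue
        if "=" not in stripped:
            raise AnnotationFormatError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, _, val = (s.strip() for s in stripped.partition("="))
        if key not in _WEIGHT_KEYS and key != "scale_max":
            raise AnnotationFormatError(f"{path}:{lineno}: unknown key {key!r}", field=key)
        try:
            num = float(val)
        except ValueError as exc:
            raise AnnotationFormatError(
                f"{path}:{lineno}: value for {key!r} is not a number: {val!r}", field=key
            ) from exc
        if key == "scale_max":
            scale_max = num
        else:
            values[key] = num
    missing = [k for k in _WEIGHT_KEYS if k not in values]
    if missing:
        raise AnnotationFormatError(f"{path}: missing weight keys {missing}", field=missing[0])
    try:
        return WeightConfig.from_raw(scale_max=scale_max, **values)
    except ValueError as exc:
        raise AnnotationFormatError(f"{path}: {exc}") from exc


def write_weight_config(weights: WeightConfig, path: str | Path) -> None:
    lines = [f"{k} = {v!r}" for k, v in weights.as_dict().items()]
    lines.append(f"scale_max = {weights.scale_max!r}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# -- score report ----------------------------------------------------------


def write_score_report(
    results: Sequence[tuple[str, BSIResult]],
    weights: WeightConfig,
    out: TextIO,
    n_cuts: int = 24,
) -> None:
    """Write one CSV row per scored annotation.

    Provenance — package version, the weight configuration and the cut
    count — is recorded as ``#`` comment lines above the header so a report
    is self-describing.  Formatting is fixed (factors to 6 decimals, scores
    to 3) so identical inputs give byte-identical reports.
    """
    out.write(f"# breastsym {__version__} score report\n")
    wd = weights.as_dict()
    out.write("# weights: " + " ".join(f"{k}={v:.6f}" for k, v in wd.items()))
    out.write(f" scale_max={weights.scale_max:g}\n")
    out.write(f"# n_cuts: {n_cuts}\n")
    out.write(",".join(_REPORT_COLUMNS) + "\n")
    for image_id, res in results:
        f = res.factors
        row = [
            image_id,
            f"{f.f_direct:.6f}",
            f"{f.f_horizontal:.6f}",
            f"{f.f_vertical:.6f}",
            f"{f.f_radial:.6f}",
            f"{f.f_area:.6f}",
            f"{f.f_circumference:.6f}",
            f"{res.bsi_mammilla:.3f}",
            f"{res.bsi_area:.3f}",
            f"{res.bsi:.3f}",
            str(res.harris),
        ]
        out.write(",".join(row) + "\n")
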