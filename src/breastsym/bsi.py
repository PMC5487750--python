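"""The Breast Symmetry Index (BSI).

The BSI condenses the bilateral asymmetry visible on one frontal photograph
into a single score between 0 (perfect mirror symmetry) and 15 (poorest
symmetry).  Six paired measurements are compared between the breasts:

a. *direct* jugulum-to-nipple distance,
b. *horizontal* nipple offset from the jugulum,
c. *vertical* nipple offset from the jugulum,
d. breast *area*,
e. breast *circumference* (border perimeter),
f. the *radial* nipple-to-border distance profile — 24 clockwise cuts around
   each border, compared cut by cut with mirror correspondence and averaged.

Each pair is collapsed to a ratio factor ``min/max`` in [0, 1] (1 = that
component is perfectly symmetric).  The factors are weighted — nipple
position counts more than area and circumference, with default weights
derived from a published expert/non-expert importance questionnaire — and
scaled to 0–15.  Components a, b, c, f form the mammilla sub-score
(``bsi_mammilla``), d and e the area sub-score (``bsi_area``); the BSI is
their sum.  For comparability with the classic 4-level Harris cosmesis scale
(1 excellent ... 4 poor) the BSI is finally banded onto Harris groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

from .annotation import BreastAnnotation
from .errors import BreastSymError
from .geometry import polygon_area, polygon_perimeter, radial_profile

__all__ = [
    "SymmetryFactors",
    "QuestionnaireSummary",
    "WeightConfig",
    "BSIResult",
    "DEFAULT_QUESTIONNAIRE",
    "ratio_factor",
    "compute_factors",
    "derive_weights",
    "default_weights",
    "compute_bsi",
    "harris_band",
    "score_annotation",
]

_FACTOR_NAMES = ("direct", "horizontal", "vertical", "radial", "area", "circumference")
_MAMMILLA_COMPONENTS = ("direct", "horizontal", "vertical", "radial")
_AREA_COMPONENTS = ("area", "circumference")


def ratio_factor(a: float, b: float) -> float:
    """Symmetry ratio of a bilateral measurement pair: ``min(a,b)/max(a,b)``.

    1 means the two sides agree exactly; values below 1 encode asymmetry.
    By convention the degenerate pair (0, 0) — both sides identically null —
    is perfectly symmetric (1.0), while a one-sided zero is maximal
    asymmetry (0.0).
    """
    if a < 0 or b < 0:
        raise ValueError(f"bilateral measurements must be nonnegative, got ({a}, {b})")
    if a == b:
        return 1.0
    return min(a, b) / max(a, b)


@dataclass(frozen=True)
class SymmetryFactors:
    """The six per-component bilateral ratio factors, each in [0, 1]."""

    f_direct: float
    f_horizontal: float
    f_vertical: float
    f_radial: float
    f_area: float
    f_circumference: float

    def __post_init__(self) -> None:
        for name in _FACTOR_NAMES:
            v = getattr(self, f"f_{name}")
            if not (0.0 <= v <= 1.0) or not math.isfinite(v):
                raise ValueError(f"factor f_{name} must lie in [0, 1], got {v}")

    def as_dict(self) -> dict[str, float]:
        return {f"f_{n}": getattr(self, f"f_{n}") for n in _FACTOR_NAMES}


@dataclass(frozen=True)
class QuestionnaireSummary:
    """Group means from the importance questionnaire behind the weighting.

    Raters scored each aspect from 1 (very important) to 4 (not important);
    ``expert`` are breast surgeons, ``nonexpert`` medical students.  Items:
    ``circumference``, ``area``, ``mamilla_position``, ``scars`` (scars is
    surveyed but never enters the BSI formula).
    """

    n_expert: int
    n_nonexpert: int
    expert_means: Mapping[str, float]
    nonexpert_means: Mapping[str, float]

    ITEMS = ("circumference", "area", "mamilla_position", "scars")

    def __post_init__(self) -> None:
        if self.n_expert <= 0 or self.n_nonexpert <= 0:
            raise ValueError("group sizes must be positive")
        for means, label in ((self.expert_means, "expert"), (self.nonexpert_means, "nonexpert")):
            for item in self.ITEMS:
                if item not in means:
                    raise ValueError(f"missing {label} mean for item {item!r}")
                if not (1.0 <= means[item] <= 4.0):
                    raise ValueError(
                        f"{label} mean for {item!r} must lie in [1, 4], got {means[item]}"
                    )

    def pooled_mean(self, item: str) -> float:
        """Size-weighted overall mean across the two rater groups."""
        m = (
            self.n_expert * self.expert_means[item]
            + self.n_nonexpert * self.nonexpert_means[item]
        ) / (self.n_expert + self.n_nonexpert)
        if not (1.0 <= m <= 4.0):
            raise ValueError(f"pooled mean for {item!r} outside [1, 4]: {m}")
        return m


#: Published questionnaire group means (10 surgeons, 8 students).
DEFAULT_QUESTIONNAIRE = QuestionnaireSummary(
    n_expert=10,
    n_nonexpert=8,
    expert_means={
        "circumference": 2.333,
        "area": 2.333,
        "mamilla_position": 1.333,
        "scars": 2.444,
    },
    nonexpert_means={
        "circumference": 2.125,
        "area": 1.875,
        "mamilla_position": 1.5,
        "scars": 1.875,
    },
)


@dataclass(frozen=True)
class WeightConfig:
    """Normalized component weights and the score ceiling.

    The six weights must be nonnegative and sum to 1, so an annotation with
    all factors at 0 saturates the scale at exactly ``scale_max``.
    """

    w_direct: float
    w_horizontal: float
    w_vertical: float
    w_radial: float
    w_area: float
    w_circumference: float
    scale_max: float = 15.0

    def __post_init__(self) -> None:
        ws = self.as_dict()
        for k, v in ws.items():
            if v < 0 or not math.isfinite(v):
                raise ValueError(f"weight {k} must be nonnegative, got {v}")
        total = sum(ws.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"weights must sum to 1 (got {total!r}); use from_raw() to normalize")
        if self.scale_max <= 0:
            raise ValueError("scale_max must be positive")

    def as_dict(self) -> dict[str, float]:
        return {f"w_{n}": getattr(self, f"w_{n}") for n in _FACTOR_NAMES}

    @classmethod
    def from_raw(cls, scale_max: float = 15.0, **raw: float) -> "WeightConfig":
        """Build from unnormalized nonnegative weights (they are rescaled to sum 1)."""
        total = sum(raw.get(f"w_{n}", 0.0) for n in _FACTOR_NAMES)
        if total <= 0:
            raise ValueError("at least one weight must be positive")
        return cls(**{f"w_{n}": raw.get(f"w_{n}", 0.0) / total for n in _FACTOR_NAMES}, scale_max=scale_max)

    @property
    def mammilla_group_weight(self) -> float:
        return self.w_direct + self.w_horizontal + self.w_vertical + self.w_radial


@dataclass(frozen=True)
class BSIResult:
    """BSI score decomposition for one annotation.

    ``bsi == bsi_mammilla + bsi_area`` by construction; ``harris`` is the
    4-level Harris group the score falls into; ``factors`` records the raw
    ratio factors for provenance.
    """

    bsi_mammilla: float
    bsi_area: float
    bsi: float
    harris: int
    factors: SymmetryFactors

    def __post_init__(self) -> None:
        if abs(self.bsi - (self.bsi_mammilla + self.bsi_area)) > 1e-9:
            raise ValueError("bsi must equal bsi_mammilla + bsi_area")
        if not (-1e-9 <= self.bsi <= 15.0 + 1e-9):
            raise ValueError(f"bsi out of range [0, 15]: {self.bsi}")
        if self.harris not in (1, 2, 3, 4):
            raise ValueError(f"harris group must be 1..4, got {self.harris}")


def compute_factors(ann: BreastAnnotation, n_cuts: int = 24) -> SymmetryFactors:
    """Measure the six bilateral ratio factors of an annotation.

    Nipple-position components compare, per side, the straight
    jugulum-to-nipple distance (direct), the absolute horizontal and vertical
    offsets of the nipple from the jugulum, and the radial nipple-to-border
    profile.  The left profile is cast clockwise and the right
    counter-clockwise so that, under mirror correspondence, cut *i* on one
    breast faces cut *i* on the other; the 24 per-cut ratios are combined by
    arithmetic mean.  Area and circumference compare the border polygons.
    """
    j, nl, nr = ann.jugulum, ann.nipple_left, ann.nipple_right

    f_direct = ratio_factor(j.distance_to(nl), j.distance_to(nr))
    f_horizontal = ratio_factor(abs(nl.x - j.x), abs(nr.x - j.x))
    f_vertical = ratio_factor(abs(nl.y - j.y), abs(nr.y - j.y))
    f_area = ratio_factor(polygon_area(ann.border_left), polygon_area(ann.border_right))
    f_circumference = ratio_factor(
        polygon_perimeter(ann.border_left), polygon_perimeter(ann.border_right)
    )

    prof_l = radial_profile(nl, ann.border_left, n=n_cuts, clockwise=True)
    prof_r = radial_profile(nr, ann.border_right, n=n_cuts, clockwise=False)
    f_radial = float(
        sum(ratio_factor(a, b) for a, b in zip(prof_l.distances, prof_r.distances)) / n_cuts
    )

    return SymmetryFactors(
        f_direct=f_direct,
        f_horizontal=f_horizontal,
        f_vertical=f_vertical,
        f_radial=f_radial,
        f_area=f_area,
        f_circumference=f_circumference,
    )


def derive_weights(q: QuestionnaireSummary = DEFAULT_QUESTIONNAIRE) -> WeightConfig:
    """Turn questionnaire importance means into normalized component weights.

    The importance scale runs 1 (very important) to 4 (not important), so a
    raw weight ``r = 5 - pooled_mean`` inverts it.  The three BSI-relevant
    items (mamilla position, area, circumference; scars is excluded — it is
    surveyed but not part of the score) are normalized to sum 1, and the
    mamilla-position weight is split equally across its four components
    (direct, horizontal, vertical, radial).  With the default questionnaire
    the nipple-position group receives ~0.39, more than area (~0.31) or
    circumference (~0.30) — the intended emphasis on nipple position.
    """
    raw = {item: 5.0 - q.pooled_mean(item) for item in ("mamilla_position", "area", "circumference")}
    total = sum(raw.values())
    g_mam, g_area, g_circ = (raw[i] / total for i in ("mamilla_position", "area", "circumference"))
    cfg = WeightConfig(
        w_direct=g_mam / 4,
        w_horizontal=g_mam / 4,
        w_vertical=g_mam / 4,
        w_radial=g_mam / 4,
        w_area=g_area,
        w_circumference=g_circ,
    )
    # intended emphasis: nipple position outweighs each of area and circumference
    assert cfg.mammilla_group_weight > cfg.w_area and cfg.mammilla_group_weight > cfg.w_circumference
    return cfg


def default_weights() -> WeightConfig:
    """Weights derived from the published questionnaire (the package default)."""
    return derive_weights(DEFAULT_QUESTIONNAIRE)


def harris_band(bsi: float) -> int:
    """Band a BSI value onto the 4-level Harris cosmesis scale.

    The published banding enumerates half-unit BSI grid points: group 1
    (excellent) up to 2.5, group 2 (good) 3–6.5, group 3 (fair) 7–10,
    group 4 (poor) 10.5–15.  Off-grid values are first rounded to the
    nearest 0.5 (ties away from zero); rounded values below 1 are group 1.
    """
    if not (-1e-9 <= bsi <= 15.0 + 1e-9):
        raise ValueError(f"BSI must lie in [0, 15], got {bsi}")
    v = min(max(bsi, 0.0), 15.0)
    half_units = math.floor(2.0 * v + 0.5)  # ties away from zero (v >= 0)
    v = half_units / 2.0
    if v <= 2.5:
        return 1
    if v <= 6.5:
        return 2
    if v <= 10.0:
        return 3
    return 4


def compute_bsi(factors: SymmetryFactors, weights: WeightConfig | None = None) -> BSIResult:
    """Weight the asymmetries ``1 - f`` and scale to the 0–15 BSI.

    ``bsi_mammilla`` aggregates the four nipple-position components,
    ``bsi_area`` the area and circumference; their sum is the BSI, which is
    0 for perfect mirror symmetry and ``scale_max`` (15) when every factor
    is 0.
    """
    w = weights if weights is not None else default_weights()
    d = {n: 1.0 - getattr(factors, f"f_{n}") for n in _FACTOR_NAMES}
    bsi_mammilla = w.scale_max * sum(getattr(w, f"w_{n}") * d[n] for n in _MAMMILLA_COMPONENTS)
    bsi_area = w.scale_max * sum(getattr(w, f"w_{n}") * d[n] for n in _AREA_COMPONENTS)
    bsi = bsi_mammilla + bsi_area
    return BSIResult(
        bsi_mammilla=bsi_mammilla,
        bsi_area=bsi_area,
        bsi=bsi,
        harris=harris_band(min(max(bsi, 0.0), 15.0)),
        factors=factors,
    )


def score_annotation(
    ann: BreastAnnotation, weights: WeightConfig | None = None, n_cuts: int = 24
) -> BSIResult:
    """Convenience: factors + weighting in one call."""
    return compute_bsi(compute_factors(ann, n_cuts=n_cuts), weights)
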