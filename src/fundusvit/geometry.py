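"""Bounding-box geometry and the cup-to-disc-ratio (CDR) diagnosis rule.

The screening pipeline reduces glaucoma diagnosis to geometry on two
axis-aligned bounding boxes: one around the optic disc (OD), one around the
optic cup (OC).  Each box yields a scalar "radius"; the ratio of cup radius
to disc radius is the CDR, and a CDR at or above a threshold (0.6 by
default) is flagged as glaucoma.

Three radius conventions are provided because the definition is genuinely
ambiguous in practice:

``euclidean``
    Distance from the box center to a corner, ``sqrt(hw**2 + hh**2)`` with
    ``hw = width/2``, ``hh = height/2``.  This treats the box diagonal as
    the diameter of a circumscribing circle.
``semi_major``
    ``max(hw, hh)`` — the semi-major axis of the tightest inscribed
    ellipse.  This is the package default: it is the convention under which
    published reference radii for disc boxes are reproduced exactly.
``vertical``
    ``hh`` alone — the clinically favoured vertical CDR, sensitive to
    vertical rim thinning.

Coordinates are continuous pixels, origin at the top-left, x rightward,
y downward; ``width = x_max - x_min`` with no +1 pixel-count correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable

__all__ = [
    "BoundingBox",
    "RadiusConvention",
    "CdrResult",
    "box_center",
    "radius",
    "compute_cdr",
    "diagnose",
    "GLAUCOMA",
    "NON_GLAUCOMA",
    "DEFAULT_THRESHOLD",
]

GLAUCOMA = "glaucoma"
NON_GLAUCOMA = "non_glaucoma"

#: Default CDR decision threshold; ratios >= this value are flagged.
DEFAULT_THRESHOLD = 0.6


class RadiusConvention(str, Enum):
    """How a bounding box is reduced to a scalar radius."""

    EUCLIDEAN = "euclidean"
    SEMI_MAJOR = "semi_major"
    VERTICAL = "vertical"


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box ``(x_min, y_min, x_max, y_max)`` in pixel coordinates.

    Continuous values are allowed.  ``x_min <= x_max`` and ``y_min <= y_max``
    are enforced at construction.
    """

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if self.x_min > self.x_max or self.y_min > self.y_max:
            raise ValueError(
                f"invalid box: ({self.x_min}, {self.y_min}, "
                f"{self.x_max}, {self.y_max}); min must not exceed max"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @classmethod
    def from_sequence(cls, coords: Iterable[float]) -> "BoundingBox":
        """Build from any 4-sequence ``(x_min, y_min, x_max, y_max)``."""
        vals = [float(v) for v in coords]
        if len(vals) != 4:
            raise ValueError(f"expected 4 coordinates, got {len(vals)}")
        return cls(*vals)

    @classmethod
    def from_xywh(cls, x: float, y: float, w: float, h: float) -> "BoundingBox":
        """Build from COCO-style ``(x, y, width, height)``."""
        return cls(x, y, x + w, y + h)

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.x_min, self.y_min, self.x_max, self.y_max)

    def scaled(self, s: float) -> "BoundingBox":
        """Uniformly scale all coordinates about the origin by ``s > 0``."""
        if s <= 0:
            raise ValueError("scale factor must be positive")
        return BoundingBox(self.x_min * s, self.y_min * s, self.x_max * s, self.y_max * s)


@dataclass(frozen=True)
class CdrResult:
    """Outcome of the cup-to-disc-ratio computation for one image.

    ``ratio`` is the unrounded OC/OD radius ratio used for the decision;
    ``display_ratio`` is the same value rounded to one decimal, matching how
    CDR values are conventionally reported.
    """

    od_radius: float
    oc_radius: float
    ratio: float
    diagnosis: str
    convention: RadiusConvention
    threshold: float

    @property
    def display_ratio(self) -> float:
        return round(self.ratio, 1)

    @property
    def rim_width(self) -> float:
        """Neuroretinal-rim proxy: disc radius minus cup radius.

        Auxiliary output only; rim thinning is not otherwise modelled.
        """
        return self.od_radius - self.oc_radius


def box_center(box: BoundingBox) -> tuple[float, float]:
    """Arithmetic midpoint ``((x_min+x_max)/2, (y_min+y_max)/2)``."""
    return (box.x_min + box.x_max) / 2.0, (box.y_min + box.y_max) / 2.0


def radius(
    box: BoundingBox,
    convention: RadiusConvention | str = RadiusConvention.SEMI_MAJOR,
) -> float:
    """Scalar radius of ``box`` under the given convention.

    A degenerate (zero-area) box yields radius 0 under every convention.
    """
    convention = RadiusConvention(convention)
    hw = box.width / 2.0
    hh = box.height / 2.0
    if convention is RadiusConvention.EUCLIDEAN:
        return math.hypot(hw, hh)
    if convention is RadiusConvention.SEMI_MAJOR:
        return max(hw, hh)
    return hh


def diagnose(ratio: float, threshold: float = DEFAULT_THRESHOLD, *, strict: bool = False) -> str:
    """Binary glaucoma call from a CDR value.

    By default the comparison is inclusive (``ratio >= threshold`` flags
    glaucoma), so a CDR of exactly 0.6 is flagged.  ``strict=True`` switches
    to a strict ``>`` comparison.
    """
    if ratio < 0:
        raise ValueError(f"CDR ratio must be non-negative, got {ratio}")
    positive = ratio > threshold if strict else ratio >= threshold
    return GLAUCOMA if positive else NON_GLAUCOMA


def compute_cdr(
    oc_box: BoundingBox,
    od_box: BoundingBox,
    convention: RadiusConvention | str = RadiusConvention.SEMI_MAJOR,
    threshold: float = DEFAULT_THRESHOLD,
    *,
    strict: bool = False,
) -> CdrResult:
    """Cup-to-disc ratio and diagnosis from the two bounding boxes.

    Raises ``ValueError`` if the disc box has zero radius under the chosen
    convention (an invalid disc detection).  The decision uses the unrounded
    ratio; rounding is display-only.
    """
    convention = RadiusConvention(convention)
    od_r = radius(od_box, convention)
    oc_r = radius(oc_box, convention)
    if od_r <= 0:
        raise ValueError(
            "optic disc box has zero radius under convention "
            f"{convention.value!r}; invalid disc detection"
        )
    ratio_ = oc_r / od_r
    return CdrResult(
        od_radius=od_r,
        oc_radius=oc_r,
        ratio=ratio_,
        diagnosis=diagnose(ratio_, threshold, strict=strict),
        convention=convention,
        threshold=threshold,
    )
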