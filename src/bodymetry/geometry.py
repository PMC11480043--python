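"""Closed-form perimeter estimators for body cross-sections.

Two estimators are provided.  The primary method treats the per-angle
half-widths sampled over a 0-180 degree sweep as radii of an inscribed
polygon and sums the triangle sides obtained from the law of cosines; the
full perimeter is twice that half-perimeter (front/back symmetry is
assumed, so asymmetric cross-sections are biased).  The baseline method is
the classic two-view ellipse approximation ``2*pi*sqrt((a^2 + b^2)/2)``
built from the 0 and 90 degree half-widths only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from bodymetry.errors import ValidationError

__all__ = [
    "RadialFan",
    "GirthEstimate",
    "cosine_side",
    "cosine_perimeter",
    "ellipse_perimeter",
    "inscribed_polygon_error",
]

_ANGLE_TOL = 1e-9


@dataclass(frozen=True)
class RadialFan:
    """Half-widths sampled at uniform angles spanning [0, 180] degrees.

    Parameters
    ----------
    angles_deg :
        Strictly increasing angles starting at 0 and ending at 180, with a
        uniform step that divides 180 exactly.
    radii :
        Non-negative half-widths, one per angle, in a consistent length
        unit (cm or px).
    """

    angles_deg: np.ndarray
    radii: np.ndarray

    def __post_init__(self):
        angles = np.asarray(self.angles_deg, dtype=float)
        radii = np.asarray(self.radii, dtype=float)
        object.__setattr__(self, "angles_deg", angles)
        object.__setattr__(self, "radii", radii)
        if angles.ndim != 1 or radii.ndim != 1:
            raise ValidationError("angles_deg and radii must be 1-D")
        if angles.size != radii.size:
            raise ValidationError(
                f"angles ({angles.size}) and radii ({radii.size}) differ in length"
            )
        if angles.size < 3:
            raise ValidationError("a radial fan needs at least 3 samples")
        if np.any(np.diff(angles) <= 0):
            raise ValidationError("angles must be strictly increasing")
        if abs(angles[0]) > _ANGLE_TOL or abs(angles[-1] - 180.0) > _ANGLE_TOL:
            raise ValidationError("angles must span exactly [0, 180] degrees")
        steps = np.diff(angles)
        if np.ptp(steps) > 1e-6:
            raise ValidationError("angles must be uniformly spaced")
        step = float(steps[0])
        if abs(180.0 / step - round(180.0 / step)) > 1e-9:
            raise ValidationError(f"angular step {step} does not divide 180")
        if np.any(radii < 0):
            raise ValidationError("radii must be non-negative")

    @property
    def step_deg(self) -> float:
        return float(self.angles_deg[1] - self.angles_deg[0])

    @classmethod
    def from_radii(cls, radii) -> "RadialFan":
        """Build a fan from radii alone, inferring uniform angles on [0, 180]."""
        radii = np.asarray(radii, dtype=float)
        if radii.size < 3:
            raise ValidationError("a radial fan needs at least 3 samples")
        return cls(np.linspace(0.0, 180.0, radii.size), radii)


@dataclass(frozen=True)
class GirthEstimate:
    """A single circumference estimate tagged with its method."""

    method: str
    value: float
    n_views: int = field(default=0)

    def __post_init__(self):
        if self.method not in ("cosine", "ellipse"):
            raise ValidationError(f"unknown method {self.method!r}")
        if self.value < 0:
            raise ValidationError("circumference must be non-negative")


def cosine_side(r1: float, r2: float, delta_deg: float) -> float:
    """Third side of a triangle from two sides and the included angle.

    Computes ``sqrt(r1^2 + r2^2 - 2*r1*r2*cos(delta))``; symmetric in
    ``r1``/``r2`` and returned in the unit of the inputs.
    """
    if r1 < 0:
        raise ValidationError(f"r1 must be non-negative, got {r1}")
    if r2 < 0:
        raise ValidationError(f"r2 must be non-negative, got {r2}")
    if not 0.0 < delta_deg < 180.0:
        raise ValidationError(
            f"delta_deg must lie strictly between 0 and 180, got {delta_deg}"
        )
    delta = math.radians(delta_deg)
    # guard tiny negative arguments from floating-point cancellation
    sq = r1 * r1 + r2 * r2 - 2.0 * r1 * r2 * math.cos(delta)
    return math.sqrt(max(sq, 0.0))


def cosine_perimeter(fan: RadialFan) -> GirthEstimate:
    """Inscribed-polygon circumference from a half-sweep of radii.

    Adjacent radii and the angular step form triangles whose outer sides
    are summed over the 0-180 degree sweep; doubling that half-perimeter
    yields the full circumference (a dodecagon for a 30 degree step).
    """
    if not isinstance(fan, RadialFan):
        fan = RadialFan.from_radii(np.asarray(fan, dtype=float))
    step = fan.step_deg
    r = fan.radii
    half = sum(
        cosine_side(r[i], r[i + 1], step) for i in range(r.size - 1)
    )
    return GirthEstimate(method="cosine", value=2.0 * half, n_views=r.size)


def ellipse_perimeter(a: float, b: float) -> GirthEstimate:
    """Ellipse-approximation circumference ``2*pi*sqrt((a^2 + b^2)/2)``.

    ``a`` and ``b`` are the half-widths seen at 0 and 90 degrees (the
    semi-axes); the formula is symmetric and exact for a circle.
    """
    if a < 0:
        raise ValidationError(f"a must be non-negative, got {a}")
    if b < 0:
        raise ValidationError(f"b must be non-negative, got {b}")
    value = 2.0 * math.pi * math.sqrt((a * a + b * b) / 2.0)
    return GirthEstimate(method="ellipse", value=value, n_views=2)


def inscribed_polygon_error(n: int) -> float:
    """Relative shortfall of a regular n-gon inscribed in a circle.

    Returns ``1 - (n/pi)*sin(pi/n)``, the fraction by which the polygon
    perimeter undershoots the circumscribing circle; strictly decreasing
    in ``n`` and tending to 0.  For the 30-degree dodecagon (n=12) this is
    1.138e-2.
    """
    if int(n) != n or n < 3:
        raise ValidationError(f"n must be an integer >= 3, got {n}")
    n = int(n)
    return 1.0 - (n / math.pi) * math.sin(math.pi / n)
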