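"""Area-proportional two-circle overlap geometry.

Each fraction is drawn as a circle whose area is proportional to its
distinct-peptide count, and each adjacent pair is pulled together until the
lens-shaped intersection area is proportional (same constant) to the number
of shared peptides.  The lens area of two circles with radii r1, r2 at
centre distance d is

    A(d) = r1^2 acos((d^2 + r1^2 - r2^2) / (2 d r1))
         + r2^2 acos((d^2 + r2^2 - r1^2) / (2 d r2))
         - sqrt((-d+r1+r2)(d+r1-r2)(d-r1+r2)(d+r1+r2)) / 2

which decreases strictly and continuously from pi*min(r1,r2)^2 at
d = |r1 - r2| (containment) to 0 at d = r1 + r2 (tangency), so the centre
distance for a target area is found by bracketed root finding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .span_analysis import AdjacentOverlap

__all__ = [
    "CircleSpec",
    "LensSolution",
    "radius_for_count",
    "lens_area",
    "solve_distance",
    "layout_chain",
]


@dataclass(frozen=True)
class CircleSpec:
    """One fraction's circle in layout units; centres share a baseline."""

    fraction: int
    radius: float
    center_x: float
    center_y: float = 0.0
    n_peptides: int = 0


@dataclass(frozen=True)
class LensSolution:
    """Solved overlap between two circles.

    ``intersection_points`` are in the left circle's frame: the x axis runs
    through both centres with the left centre at the origin.  The
    overlapping regime has exactly two points (mirror images in the axis);
    the disjoint and contained regimes have none.
    """

    distance: float
    lens_area: float
    regime: str  # disjoint | overlapping | contained
    intersection_points: tuple[tuple[float, float], ...]
    pair: Optional[tuple[int, int]] = None
    shared: Optional[int] = None


def radius_for_count(n: int, k: float) -> float:
    """Radius of a circle of area k*n (k = layout area per peptide)."""
    if k <= 0:
        raise ValueError(f"area-per-peptide constant must be positive, got {k}")
    if n < 0:
        raise ValueError(f"peptide count must be non-negative, got {n}")
    return math.sqrt(k * n / math.pi)


def lens_area(r1: float, r2: float, d: float) -> float:
    """Intersection area of two circles with radii r1, r2 at centre distance d."""
    if r1 <= 0 or r2 <= 0 or d < 0:
        raise ValueError(f"need r1, r2 > 0 and d >= 0; got r1={r1}, r2={r2}, d={d}")
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        return math.pi * min(r1, r2) ** 2
    # acos arguments are in [-1, 1] on the open interval; clip guards rounding.
    a1 = (d * d + r1 * r1 - r2 * r2) / (2.0 * d * r1)
    a2 = (d * d + r2 * r2 - r1 * r1) / (2.0 * d * r2)
    a1 = min(1.0, max(-1.0, a1))
    a2 = min(1.0, max(-1.0, a2))
    kernel = (-d + r1 + r2) * (d + r1 - r2) * (d - r1 + r2) * (d + r1 + r2)
    return (
        r1 * r1 * math.acos(a1)
        + r2 * r2 * math.acos(a2)
        - 0.5 * math.sqrt(max(kernel, 0.0))
    )


def _intersection_points(r1: float, r2: float, d: float) -> tuple[tuple[float, float], ...]:
    x = (d * d + r1 * r1 - r2 * r2) / (2.0 * d)
    y2 = r1 * r1 - x * x
    if y2 <= 0.0:
        return ()
    y = math.sqrt(y2)
    return ((x, y), (x, -y))


def solve_distance(r1: float, r2: float, target_area: float) -> LensSolution:
    """Centre distance whose lens area equals ``target_area``.

    Feasibility requires 0 <= target_area <= pi*min(r1,r2)^2 (the shared
    count can never exceed the smaller fraction).  A zero target places the
    circles tangent (d = r1 + r2), keeping the chain compact; a saturated
    target clamps to containment (d = |r1 - r2|).  Otherwise the root of
    the strictly decreasing lens-area function is bracketed and solved to
    |A(d) - target| < 1e-9 * max(1, target).
    """
    if r1 <= 0 or r2 <= 0:
        raise ValueError(f"radii must be positive, got r1={r1}, r2={r2}")
    if target_area < 0:
        raise ValueError(f"target area must be non-negative, got {target_area}")
    max_area = math.pi * min(r1, r2) ** 2
    if target_area > max_area * (1.0 + 1e-12):
        raise ValueError(
            f"target area {target_area} exceeds the smaller circle's area {max_area}; "
            "the shared count cannot exceed the smaller fraction"
        )
    if target_area == 0.0:
        d = r1 + r2
        return LensSolution(distance=d, lens_area=0.0, regime="disjoint",
                            intersection_points=())
    if target_area >= max_area * (1.0 - 1e-12):
        d = abs(r1 - r2)
        return LensSolution(distance=d, lens_area=max_area, regime="contained",
                            intersection_points=())
    lo, hi = abs(r1 - r2), r1 + r2
    d = brentq(lambda x: lens_area(r1, r2, x) - target_area, lo, hi,
               xtol=1e-14, rtol=8.9e-16, maxiter=200)
    area = lens_area(r1, r2, d)
    if abs(area - target_area) >= 1e-9 * max(1.0, target_area):
        raise ArithmeticError(
            f"lens solve failed to converge: |{area} - {target_area}| too large"
        )
    return LensSolution(
        distance=float(d),
        lens_area=float(area),
        regime="overlapping",
        intersection_points=_intersection_points(r1, r2, d),
    )


def layout_chain(
    overlaps: Sequence[AdjacentOverlap], max_radius: float = 1.0
) -> tuple[list[CircleSpec], list[LensSolution]]:
    """Place the whole fraction chain on a common baseline.

    The area constant k is chosen so the largest fraction's circle has
    radius ``max_radius``; each adjacent pair's centre distance is solved
    independently and the centres accumulate left to right.  Empty
    fractions become zero-radius markers.  Only adjacent pairs carry
    meaning: non-adjacent circles may incidentally overlap on the page.
    """
    if not overlaps:
        raise ValueError("layout_chain needs at least one adjacent pair")
    if max_radius <= 0:
        raise ValueError(f"max_radius must be positive, got {max_radius}")
    fractions = [overlaps[0].pair[0]] + [o.pair[1] for o in overlaps]
    sizes = [overlaps[0].size_left] + [o.size_right for o in overlaps]
    for o, left_size in zip(overlaps, sizes):
        if o.size_left != left_size:
            raise ValueError(f"inconsistent chain: size_left of pair {o.pair} disagrees")
    biggest = max(sizes)
    if biggest == 0:
        raise ValueError("every fraction in the chain is empty")
    k = math.pi * max_radius**2 / biggest
    radii = [radius_for_count(n, k) for n in sizes]

    solutions: list[LensSolution] = []
    xs = [0.0]
    for i, o in enumerate(overlaps):
        r1, r2 = radii[i], radii[i + 1]
        if r1 == 0.0 or r2 == 0.0:
            if o.shared:
                raise ValueError(f"pair {o.pair} shares peptides but a fraction is empty")
            sol = LensSolution(distance=r1 + r2, lens_area=0.0, regime="disjoint",
                               intersection_points=(), pair=o.pair, shared=0)
        else:
            base = solve_distance(r1, r2, k * o.shared)
            sol = LensSolution(
                distance=base.distance,
                lens_area=base.lens_area,
                regime=base.regime,
                intersection_points=base.intersection_points,
                pair=o.pair,
                shared=o.shared,
            )
        solutions.append(sol)
        xs.append(xs[-1] + sol.distance)

    circles = [
        CircleSpec(fraction=f, radius=r, center_x=x, center_y=0.0, n_peptides=n)
        for f, r, x, n in zip(fractions, radii, xs, sizes)
    ]
    return circles, solutions
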