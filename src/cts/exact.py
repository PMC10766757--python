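"""Exact arithmetic in the ring Z[sqrt(2)] over the rationals.

Every vertex coordinate reachable by placing tangram pieces at multiples of
45 degrees lives in {a + b*sqrt(2) : a, b rational}.  Representing coordinates
in this ring keeps rotations, mirror flips and bounding-box snapping exact, so
grid lookups and state signatures never suffer floating-point drift.
"""

from __future__ import annotations

import math
from fractions import Fraction
from typing import Iterable, Tuple

_SQRT2 = math.sqrt(2.0)


class Rt2:
    """A number a + b*sqrt(2) with rational a, b."""

    __slots__ = ("a", "b")

    def __init__(self, a=0, b=0):
        self.a = Fraction(a)
        self.b = Fraction(b)

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other: "Rt2") -> "Rt2":
        other = _coerce(other)
        return Rt2(self.a + other.a, self.b + other.b)

    __radd__ = __add__

    def __sub__(self, other: "Rt2") -> "Rt2":
        other = _coerce(other)
        return Rt2(self.a - other.a, self.b - other.b)

    def __rsub__(self, other) -> "Rt2":
        return _coerce(other) - self

    def __mul__(self, other) -> "Rt2":
        other = _coerce(other)
        return Rt2(
            self.a * other.a + 2 * self.b * other.b,
            self.a * other.b + self.b * other.a,
        )

    __rmul__ = __mul__

    def __neg__(self) -> "Rt2":
        return Rt2(-self.a, -self.b)

    def half(self) -> "Rt2":
        return Rt2(self.a / 2, self.b / 2)

    def div_sqrt2(self) -> "Rt2":
        """(a + b*sqrt2)/sqrt2 = b + (a/2)*sqrt2 — stays in the ring."""
        return Rt2(self.b, self.a / 2)

    # -- comparisons ----------------------------------------------------
    def __eq__(self, other) -> bool:
        if not isinstance(other, (Rt2, int, Fraction)):
            return NotImplemented
        other = _coerce(other)
        return self.a == other.a and self.b == other.b

    def __hash__(self):
        return hash((self.a, self.b))

    def __lt__(self, other) -> bool:
        return float(self) < float(_coerce(other)) - 1e-12

    def __le__(self, other) -> bool:
        return self == _coerce(other) or self < other

    def __float__(self) -> float:
        return float(self.a) + float(self.b) * _SQRT2

    def __repr__(self):
        return f"Rt2({self.a}, {self.b})"


def _coerce(x) -> Rt2:
    if isinstance(x, Rt2):
        return x
    return Rt2(x)


Point = Tuple[Rt2, Rt2]


def pt(x, y) -> Point:
    return (_coerce(x), _coerce(y))


def rot45(p: Point, k: int) -> Point:
    """Rotate a point about the origin by k * 45 degrees (counterclockwise)."""
    x, y = p
    k = k % 8
    for _ in range(k // 2):  # 90-degree steps
        x, y = -y, x
    if k % 2:  # one final 45-degree step: (x - y, x + y) / sqrt2
        x, y = (x - y).div_sqrt2(), (x + y).div_sqrt2()
    return (x, y)


def mirror_x(p: Point) -> Point:
    x, y = p
    return (-x, y)


def translate(p: Point, d: Point) -> Point:
    return (p[0] + d[0], p[1] + d[1])


def bbox(points: Iterable[Point]) -> Tuple[Rt2, Rt2, Rt2, Rt2]:
    """Exact (xmin, ymin, xmax, ymax) of a vertex list."""
    pts = list(points)
    xs = [p[0] for p in pts]
    ys = [p[1] for p in pts]
    return (min(xs), min(ys), max(xs), max(ys))


def to_floats(points: Iterable[Point]):
    return [(float(x), float(y)) for x, y in points]
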