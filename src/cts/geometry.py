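"""Exact tangram geometry: tans, placements, silhouettes and puzzle states.

This module is the ground truth the rest of the solver is checked against.
All vertex coordinates live in the ring {a + b*sqrt(2) : a, b rational}
(see :mod:`cts.exact`), which is closed under 45-degree rotations, so piece
poses are computed exactly and only the final overlap/containment tests go
through shapely with an area tolerance.

Conventions
-----------
* The small triangle has legs of length 1; the seven tans then tile an area
  of exactly 8 square units.
* A placement is (kind, grid_loc, rotation, mirror).  The piece is rotated
  about its centroid in steps of 45 degrees and then translated so that the
  lower-left corner of its bounding box coincides with the grid anchor.
* The anchor grid of a silhouette is the set of lattice points
  i/2 + j*(sqrt2/2) per coordinate (j in a small bounded range) inside the
  silhouette's bounding box, numbered row-major (by y, then x) from 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import numpy as np
from shapely.geometry import Polygon
from shapely.ops import unary_union
from shapely.prepared import prep

from .exact import Point, Rt2, bbox, mirror_x, pt, rot45, to_floats, translate

# ---------------------------------------------------------------------------
# Constants

KINDS: Tuple[str, ...] = (
    "big_triangle",
    "mid_triangle",
    "small_triangle",
    "square",
    "parallelogram",
)
ROTATIONS: Tuple[int, ...] = tuple(range(0, 360, 45))

#: number of physical pieces per kind
KIND_COUNTS: Dict[str, int] = {
    "big_triangle": 2,
    "mid_triangle": 1,
    "small_triangle": 2,
    "square": 1,
    "parallelogram": 1,
}

KIND_AREAS: Dict[str, float] = {
    "big_triangle": 2.0,
    "mid_triangle": 1.0,
    "small_triangle": 0.5,
    "square": 1.0,
    "parallelogram": 1.0,
}

#: placements whose polygon exceeds the uncovered region by more than this
#: area (square units) are illegal
AREA_TOL = 1e-6


class InvalidRotationError(ValueError):
    """Raised when a rotation is not a multiple of 45 degrees."""


class InvalidMirrorError(ValueError):
    """Raised when a non-parallelogram placement is mirrored."""


# ---------------------------------------------------------------------------
# Tans

_CANONICAL_VERTICES: Dict[str, Tuple[Point, ...]] = {
    # right angle at the origin, legs along the axes
    "big_triangle": (pt(0, 0), pt(2, 0), pt(0, 2)),
    # legs sqrt(2), hypotenuse of length 2 on the x axis, apex up
    "mid_triangle": (pt(0, 0), pt(2, 0), pt(1, 1)),
    "small_triangle": (pt(0, 0), pt(1, 0), pt(0, 1)),
    "square": (pt(0, 0), pt(1, 0), pt(1, 1), pt(0, 1)),
    # sides 1 (horizontal) and sqrt(2) (diagonal), 45/135-degree angles
    "parallelogram": (pt(0, 0), pt(1, 0), pt(2, 1), pt(1, 1)),
}


@dataclass(frozen=True)
class Tan:
    """One physical puzzle piece in canonical pose."""

    kind: str
    instance_id: int
    polygon: Tuple[Point, ...]
    area: float

    def __repr__(self):
        return f"Tan({self.kind}#{self.instance_id})"


def canonical_tans() -> List[Tan]:
    """The seven tans (2 small, 1 medium, 2 big triangles, square,
    parallelogram) in canonical pose, with exact vertex coordinates."""
    tans: List[Tan] = []
    iid = 0
    for kind in KINDS:
        for _ in range(KIND_COUNTS[kind]):
            tans.append(Tan(kind, iid, _CANONICAL_VERTICES[kind], KIND_AREAS[kind]))
            iid += 1
    return tans


# ---------------------------------------------------------------------------
# Placements and transforms


@dataclass(frozen=True)
class Placement:
    """A piece pose on the anchor grid: (kind, grid_loc, rotation, mirror)."""

    kind: str
    grid_loc: int
    rotation: int
    mirror: bool = False

    def __post_init__(self):
        if self.rotation % 45 != 0:
            raise InvalidRotationError(f"rotation {self.rotation} not a multiple of 45")
        object.__setattr__(self, "rotation", self.rotation % 360)
        if self.mirror and self.kind != "parallelogram":
            raise InvalidMirrorError(f"mirror flag set on {self.kind}")

    @property
    def key(self) -> Tuple[str, int, int, bool]:
        return (self.kind, self.grid_loc, self.rotation, self.mirror)


def pose_vertices(kind: str, rotation: int, mirror: bool = False) -> Tuple[Point, ...]:
    """Exact vertices of a rotated (and optionally mirrored) tan, translated
    so the lower-left corner of its bounding box sits at the origin."""
    if rotation % 45 != 0:
        raise InvalidRotationError(f"rotation {rotation} not a multiple of 45")
    verts: Sequence[Point] = _CANONICAL_VERTICES[kind]
    if mirror:
        verts = [mirror_x(p) for p in verts]
    k = (rotation % 360) // 45
    verts = [rot45(p, k) for p in verts]
    xmin, ymin, _, _ = bbox(verts)
    return tuple(translate(p, (-xmin, -ymin)) for p in verts)


def transform(kind: str, placement: Placement, grid: "Grid") -> Tuple[Point, ...]:
    """Exact vertices of ``placement`` on ``grid`` (rotation about the piece
    centroid, bounding-box lower-left corner snapped to the anchor)."""
    base = pose_vertices(kind, placement.rotation, placement.mirror)
    ax, ay = grid.point(placement.grid_loc)
    return tuple(translate(p, (ax, ay)) for p in base)


def _shapely(verts: Iterable[Point]) -> Polygon:
    return Polygon(to_floats(verts))


# ---------------------------------------------------------------------------
# Grid


class Grid:
    """Indexed anchor points of a silhouette's bounding region.

    Anchors are the lattice points with coordinates i/2 + j*(sqrt2/2)
    (j bounded, default |j| <= 1) inside the bounding box, numbered row-major
    from 1 (y ascending, then x ascending).
    """

    def __init__(self, xmin: Rt2, ymin: Rt2, xmax: Rt2, ymax: Rt2, j_range: int = 1):
        self.points: List[Point] = []
        xs = _lattice_values(xmin, xmax, j_range)
        ys = _lattice_values(ymin, ymax, j_range)
        for y in ys:
            for x in xs:
                self.points.append((x, y))
        self._index: Dict[Tuple[Rt2, Rt2], int] = {
            p: i + 1 for i, p in enumerate(self.points)
        }
        self._floats = np.array([(float(x), float(y)) for x, y in self.points])

    def __len__(self) -> int:
        return len(self.points)

    def point(self, idx: int) -> Point:
        if not 1 <= idx <= len(self.points):
            raise KeyError(f"grid index {idx} out of range 1..{len(self.points)}")
        return self.points[idx - 1]

    def index_of(self, p: Point) -> int:
        """Exact lookup of an anchor's index (KeyError if absent)."""
        key = (p[0], p[1])
        if key not in self._index:
            raise KeyError(f"point {float(p[0]):.4f},{float(p[1]):.4f} not on grid")
        return self._index[key]

    def nearest(self, x: float, y: float) -> int:
        """Index of the anchor nearest to a float location (snapping)."""
        d = np.hypot(self._floats[:, 0] - x, self._floats[:, 1] - y)
        return int(np.argmin(d)) + 1


def _lattice_values(lo: Rt2, hi: Rt2, j_range: int) -> List[Rt2]:
    flo, fhi = float(lo), float(hi)
    vals: Set[Rt2] = set()
    half = Fraction(1, 2)
    i_lo = math.floor(2 * flo) - 2 * j_range - 1
    i_hi = math.ceil(2 * fhi) + 2 * j_range + 1
    for i in range(i_lo, i_hi + 1):
        for j in range(-j_range, j_range + 1):
            v = Rt2(i * half, j * half)
            if flo - 1e-9 <= float(v) <= fhi + 1e-9:
                vals.add(v)
    return sorted(vals, key=float)


# ---------------------------------------------------------------------------
# Silhouette


class Silhouette:
    """A target outline of area 8, exactly coverable by the seven tans."""

    def __init__(self, name: str, target_vertices: Sequence[Point], j_range: int = 1):
        self.name = name
        self.target_vertices = tuple(target_vertices)
        self.target: Polygon = _shapely(target_vertices)
        if not self.target.is_valid:
            raise ValueError(f"silhouette {name}: target polygon is invalid")
        xmin, ymin, xmax, ymax = bbox(target_vertices)
        self.exact_bbox = (xmin, ymin, xmax, ymax)
        self.grid = Grid(xmin, ymin, xmax, ymax, j_range=j_range)

    @property
    def area(self) -> float:
        return self.target.area


# ---------------------------------------------------------------------------
# Puzzle state


@dataclass
class PlacedTan:
    tan: Tan
    placement: Placement
    polygon: Polygon  # float shapely polygon, cached


class PuzzleState:
    """Silhouette plus the placements currently on it.

    Tracks the uncovered region (target minus placed pieces), the step
    counter and the set of tan instances tagged as causing an unfeasible
    region.
    """

    def __init__(self, silhouette: Silhouette, mirror_allowed: bool = True):
        self.silhouette = silhouette
        self.mirror_allowed = mirror_allowed
        self.placed: List[PlacedTan] = []
        self.uncovered: Polygon = silhouette.target
        self.step: int = 0
        self.problem_tags: Set[int] = set()
        self._prepared = prep(self.uncovered)

    # -- bookkeeping ----------------------------------------------------
    def copy(self) -> "PuzzleState":
        st = PuzzleState(self.silhouette, self.mirror_allowed)
        st.placed = list(self.placed)
        st.uncovered = self.uncovered
        st.step = self.step
        st.problem_tags = set(self.problem_tags)
        st._prepared = prep(st.uncovered)
        return st

    def _refresh(self):
        union = unary_union([p.polygon for p in self.placed]) if self.placed else None
        self.uncovered = (
            self.silhouette.target
            if union is None
            else self.silhouette.target.difference(union)
        )
        self._prepared = prep(self.uncovered)

    def place(self, tan: Tan, placement: Placement) -> None:
        if any(p.tan.instance_id == tan.instance_id for p in self.placed):
            raise ValueError(f"{tan} already placed")
        poly = _shapely(transform(tan.kind, placement, self.silhouette.grid))
        self.placed.append(PlacedTan(tan, placement, poly))
        self.uncovered = self.uncovered.difference(poly)
        self._prepared = prep(self.uncovered)
        self.step += 1

    def remove(self, placement_key: Tuple[str, int, int, bool]) -> Tan:
        """Remove the most recently placed piece matching ``placement_key``."""
        for i in range(len(self.placed) - 1, -1, -1):
            if self.placed[i].placement.key == placement_key:
                placed = self.placed.pop(i)
                self.problem_tags.discard(placed.tan.instance_id)
                self._refresh()
                self.step += 1
                return placed.tan
        raise KeyError(f"no placed piece matches {placement_key}")

    # -- queries --------------------------------------------------------
    def placed_counts(self) -> Dict[str, int]:
        counts = {k: 0 for k in KINDS}
        for p in self.placed:
            counts[p.tan.kind] += 1
        return counts

    def free_kinds(self) -> List[str]:
        counts = self.placed_counts()
        return [k for k in KINDS if counts[k] < KIND_COUNTS[k]]

    @property
    def solved(self) -> bool:
        return len(self.placed) == 7 and self.uncovered.area <= AREA_TOL

    def is_legal(self, placement: Placement) -> bool:
        """True iff the placement's polygon lies within the uncovered region
        up to the area tolerance (this also screens piece overlap)."""
        poly = _shapely(transform(placement.kind, placement, self.silhouette.grid))
        ux0, uy0, ux1, uy1 = self.uncovered.bounds if not self.uncovered.is_empty else (
            0.0,
            0.0,
            -1.0,
            -1.0,
        )
        x0, y0, x1, y1 = poly.bounds
        if x0 < ux0 - 1e-7 or y0 < uy0 - 1e-7 or x1 > ux1 + 1e-7 or y1 > uy1 + 1e-7:
            return False
        if self._prepared.covers(poly):
            return True
        return poly.difference(self.uncovered).area <= AREA_TOL


# ---------------------------------------------------------------------------
# Placement enumeration (the brute-force oracle) and unfeasibility


def legal_placements(
    state: PuzzleState, kind: str, first_only: bool = False
) -> List[Placement]:
    """All legal placements of ``kind`` on the grid, in deterministic order
    (grid index, then rotation, then mirror).  Empty list if none."""
    grid = state.silhouette.grid
    mirrors: Tuple[bool, ...] = (False,)
    if kind == "parallelogram" and state.mirror_allowed:
        mirrors = (False, True)
    if state.uncovered.is_empty or state.uncovered.area < KIND_AREAS[kind] - AREA_TOL:
        return []
    ux0, uy0, ux1, uy1 = state.uncovered.bounds

    # float pose offsets per (rotation, mirror), relative to the anchor
    poses = {}
    for rot in ROTATIONS:
        for mir in mirrors:
            verts = pose_vertices(kind, rot, mir)
            arr = np.array(to_floats(verts))
            poses[(rot, mir)] = (arr, arr[:, 0].max(), arr[:, 1].max())

    out: List[Placement] = []
    for idx in range(1, len(grid) + 1):
        ax, ay = grid._floats[idx - 1]
        if ax < ux0 - 1e-7 or ay < uy0 - 1e-7:
            continue
        for rot in ROTATIONS:
            for mir in mirrors:
                arr, w, h = poses[(rot, mir)]
                if ax + w > ux1 + 1e-7 or ay + h > uy1 + 1e-7:
                    continue
                pl = Placement(kind, idx, rot, mir)
                if state.is_legal(pl):
                    out.append(pl)
                    if first_only:
                        return out
    return out


def detect_unfeasible(state: PuzzleState) -> Tuple[bool, Set[str]]:
    """Flag the state if some unplaced tan kind has no legal placement left.

    Such a kind's area must be split between regions that cannot host it,
    which marks the partial solution as a dead end.
    """
    blocked: Set[str] = set()
    for kind in state.free_kinds():
        if not legal_placements(state, kind, first_only=True):
            blocked.add(kind)
    return (bool(blocked), blocked)


def state_signature(state: PuzzleState) -> Tuple[Tuple[str, int, int, bool], ...]:
    """Canonical order-independent signature of the placed pieces.  Two states
    with the same placements compare equal regardless of placement order, and
    the two pieces of a same kind are interchangeable."""
    return tuple(sorted(p.placement.key for p in state.placed))
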