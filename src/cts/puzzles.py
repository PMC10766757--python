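"""Bundled puzzles: the House (with chimney) and the Monk.

The silhouettes are defined programmatically with exact coordinates in the
{a + b*sqrt2} ring.  Each puzzle carries

* a hand-verified canonical 7-placement solution, listed in salience order
  (the visually most distinctive sub-shapes first — the pieces participants
  reach for in the best-fit starting phase);
* an ``opening`` prefix of that order: the common starting pattern (for the
  Monk, the head = square + small triangle; for the House, the chimney and
  roof);
* for the Monk, the modal "unrecognized composition" error: the belly of the
  figure must be tiled by the two big triangles composed apex-to-apex, but
  a single big triangle laid with its hypotenuse along the belly base looks
  like a best fit and blocks the second big triangle.

Custom silhouettes can be round-tripped through YAML with
:func:`save_puzzle` / :func:`load_puzzle` (coordinates as exact ``[a, b]``
fraction pairs meaning a + b*sqrt2).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, List, Optional

import yaml

from .exact import Point, Rt2, pt
from .geometry import Placement, Silhouette


@dataclass
class Puzzle:
    silhouette: Silhouette
    solution: List[Placement]  # canonical placements, salience order
    opening: List[Placement]  # best-fit starting pattern (prefix of solution)
    modal_error: Optional[Placement] = None
    mirror_allowed: bool = True

    @property
    def name(self) -> str:
        return self.silhouette.name


def _placement(sil: Silhouette, kind: str, anchor: Point, rotation: int,
               mirror: bool = False) -> Placement:
    return Placement(kind, sil.grid.index_of(anchor), rotation, mirror)


_H = Fraction(1, 2)


def house() -> Puzzle:
    """House with chimney, area 8.

    Body: 2x2 square (two big triangles).  Roof: medium triangle.  Chimney:
    the square tan rotated 45 degrees, resting on the right roof slope.
    Annex (ground floor extension): parallelogram plus the two small
    triangles tiling a 2x1 rectangle.
    """
    verts = [
        pt(0, 0),
        pt(4, 0),
        pt(4, 2),
        (Rt2(4, _H), Rt2(2, _H)),  # chimney right vertex (4+r2/2, 2+r2/2)
        (Rt2(4, 0), Rt2(2, 1)),  # chimney top (4, 2+r2)
        (Rt2(4, -_H), Rt2(2, _H)),  # chimney left vertex (4-r2/2, 2+r2/2)
        pt(3, 3),
        pt(2, 2),
        pt(2, 1),
        pt(0, 1),
    ]
    sil = Silhouette("house", verts)
    solution = [
        _placement(sil, "square", (Rt2(4, -_H), Rt2(2)), 45),  # chimney
        _placement(sil, "mid_triangle", pt(2, 2), 0),  # roof
        _placement(sil, "big_triangle", pt(2, 0), 0),  # body lower-left
        _placement(sil, "big_triangle", pt(2, 0), 180),  # body upper-right
        _placement(sil, "parallelogram", pt(0, 0), 0),  # annex middle
        _placement(sil, "small_triangle", pt(0, 0), 270),  # annex upper-left
        _placement(sil, "small_triangle", pt(1, 0), 90),  # annex lower-right
    ]
    return Puzzle(sil, solution, opening=solution[:2])


def monk() -> Puzzle:
    """Monk, area 8.

    Belly: isoceles triangle (base 4, apex up) formed by the two big
    triangles composed leg-to-leg.  Torso: parallelogram leaning on the right
    belly slope, medium triangle as shoulder, small triangle as arm.  Head:
    the square plus a small triangle on top.
    """
    verts = [
        pt(0, 0),
        pt(4, 0),
        pt(3, 1),
        pt(4, 1),
        pt(3, 2),
        pt(4, 3),
        pt(Fraction(7, 2), 3),
        pt(Fraction(7, 2), 4),
        pt(Fraction(5, 2), 5),
        pt(Fraction(5, 2), 3),
        pt(2, 3),
        pt(2, 2),
    ]
    sil = Silhouette("monk", verts)
    solution = [
        _placement(sil, "square", pt(Fraction(5, 2), 3), 0),  # head
        _placement(sil, "small_triangle", pt(Fraction(5, 2), 4), 0),  # head top
        _placement(sil, "big_triangle", pt(0, 0), 90),  # belly left
        _placement(sil, "big_triangle", pt(2, 0), 0),  # belly right
        _placement(sil, "parallelogram", pt(2, 1), 90),  # torso
        _placement(sil, "mid_triangle", pt(2, 2), 180),  # shoulder
        _placement(sil, "small_triangle", pt(3, 1), 0),  # arm
    ]
    # hypotenuse flat along the belly base: looks like a best fit, but leaves
    # a diagonal band where the second big triangle cannot go
    modal_error = _placement(sil, "big_triangle", pt(0, 0), 225)
    return Puzzle(sil, solution, opening=solution[:2], modal_error=modal_error)


_BUILDERS = {"house": house, "monk": monk}


def get_puzzle(name: str) -> Puzzle:
    try:
        return _BUILDERS[name]()
    except KeyError:
        raise KeyError(f"unknown puzzle {name!r}; available: {sorted(_BUILDERS)}")


# ---------------------------------------------------------------------------
# YAML round-trip for custom silhouettes


def _coord(v: Rt2) -> List[str]:
    return [str(v.a), str(v.b)]


def _parse_coord(c) -> Rt2:
    return Rt2(Fraction(c[0]), Fraction(c[1]))


def save_puzzle(puzzle: Puzzle, path: str) -> None:
    doc: Dict = {
        "name": puzzle.name,
        "target": [[_coord(x), _coord(y)] for x, y in puzzle.silhouette.target_vertices],
        "mirror_allowed": puzzle.mirror_allowed,
        "solution": [list(p.key) for p in puzzle.solution],
        "opening": [list(p.key) for p in puzzle.opening],
        "modal_error": list(puzzle.modal_error.key) if puzzle.modal_error else None,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_puzzle(path: str) -> Puzzle:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    verts = [(_parse_coord(x), _parse_coord(y)) for x, y in doc["target"]]
    sil = Silhouette(doc["name"], verts)

    def mk(key) -> Placement:
        kind, loc, rot, mir = key
        return Placement(kind, int(loc), int(rot), bool(mir))

    return Puzzle(
        sil,
        [mk(k) for k in doc["solution"]],
        [mk(k) for k in doc["opening"]],
        mk(doc["modal_error"]) if doc.get("modal_error") else None,
        bool(doc.get("mirror_allowed", True)),
    )
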