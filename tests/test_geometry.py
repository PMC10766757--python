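"""Exact geometry: tans, transforms, legality oracle, unfeasibility."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from matplotlib.path import Path

from conftest import random_partial_state, solved_state, state_with, tan_pool
from cts.exact import Rt2, pt, rot45, to_floats
from cts.geometry import (
    KIND_AREAS,
    KIND_COUNTS,
    KINDS,
    InvalidMirrorError,
    InvalidRotationError,
    Placement,
    PuzzleState,
    canonical_tans,
    detect_unfeasible,
    legal_placements,
    pose_vertices,
    state_signature,
    transform,
)


class TestCanonicalTans:
    def test_seven_tans_with_exact_areas(self):
        tans = canonical_tans()
        assert len(tans) == 7
        by_kind = {k: [t for t in tans if t.kind == k] for k in KINDS}
        for kind, count in KIND_COUNTS.items():
            assert len(by_kind[kind]) == count
        # shoelace area of each canonical polygon matches the declared area
        total = 0.0
        for tan in tans:
            pts = to_floats(tan.polygon)
            area = 0.5 * abs(sum(
                x0 * y1 - x1 * y0
                for (x0, y0), (x1, y1) in zip(pts, pts[1:] + pts[:1])))
            assert area == pytest.approx(tan.area, abs=1e-12)
            total += area
        assert total == pytest.approx(8.0, abs=1e-12)

    def test_instance_ids_distinct(self):
        ids = [t.instance_id for t in canonical_tans()]
        assert len(set(ids)) == 7


class TestTransform:
    def test_identity_at_origin(self, house):
        grid = house.silhouette.grid
        origin_idx = grid.index_of(pt(0, 0))
        verts = transform("small_triangle", Placement("small_triangle", origin_idx, 0), grid)
        assert to_floats(verts) == [(0.0, 0.0), (1.0, 0.0), (0.0, 1.0)]

    def test_full_turn_equals_no_turn(self):
        for kind in KINDS:
            assert pose_vertices(kind, 0) == pose_vertices(kind, 360)

    def test_big_triangle_rot45_exact_ring_coordinates(self):
        # hand-rotated: (0,0),(2,0),(0,2) -> 45 deg -> bbox-normalized gives
        # (sqrt2,0), (2*sqrt2, sqrt2), (0, sqrt2)
        verts = pose_vertices("big_triangle", 45)
        expected = [
            (Rt2(0, 1), Rt2(0)),
            (Rt2(0, 2), Rt2(0, 1)),
            (Rt2(0), Rt2(0, 1)),
        ]
        assert list(verts) == expected

    def test_rotation_preserves_area_exactly(self):
        for kind in KINDS:
            base = to_floats(pose_vertices(kind, 0))
            for rot in range(0, 360, 45):
                pts = to_floats(pose_vertices(kind, rot, kind == "parallelogram"))
                area = 0.5 * abs(sum(
                    x0 * y1 - x1 * y0
                    for (x0, y0), (x1, y1) in zip(pts, pts[1:] + pts[:1])))
                assert area == pytest.approx(KIND_AREAS[kind], abs=1e-12)
            assert len(base) == len(pts)

    def test_invalid_rotation_rejected(self):
        with pytest.raises(InvalidRotationError):
            pose_vertices("square", 30)
        with pytest.raises(InvalidRotationError):
            Placement("square", 1, 30)

    def test_mirror_only_for_parallelogram(self):
        with pytest.raises(InvalidMirrorError):
            Placement("square", 1, 0, mirror=True)
        Placement("parallelogram", 1, 0, mirror=True)  # fine

    @given(st.integers(min_value=0, max_value=7), st.integers(min_value=0, max_value=7))
    @settings(max_examples=32, derandomize=True, deadline=None)
    def test_rot45_composes(self, j, k):
        p = pt(Fraction(3, 2), Fraction(-1, 2))
        assert rot45(rot45(p, j), k) == rot45(p, (j + k) % 8)


class TestSolutions:
    def test_canonical_solution_solves(self, puzzle):
        state = solved_state(puzzle)
        assert state.solved
        assert state.uncovered.area <= 1e-6
        assert len(state.placed) == 7

    def test_silhouette_area_is_eight(self, puzzle):
        assert puzzle.silhouette.area == pytest.approx(8.0, abs=1e-9)

    def test_area_conservation_on_random_states(self, puzzle):
        rng = np.random.default_rng(42)
        for _ in range(10):
            state = random_partial_state(puzzle, rng)
            placed_area = sum(p.polygon.area for p in state.placed)
            assert state.uncovered.area + placed_area == pytest.approx(8.0, abs=1e-6)


class TestLegalPlacements:
    def test_solved_state_has_none(self, puzzle):
        state = solved_state(puzzle)
        for kind in KINDS:
            assert legal_placements(state, kind) == []

    def test_exact_hole_is_found(self, puzzle):
        # leave out one piece: its exact-fit placement must be enumerated
        missing = puzzle.solution[-1]
        state = state_with(puzzle, [p for p in puzzle.solution if p is not missing])
        found = legal_placements(state, missing.kind)
        assert missing in found

    def test_deterministic_order(self, monk):
        state = PuzzleState(monk.silhouette)
        pls = legal_placements(state, "mid_triangle")
        assert pls == sorted(pls, key=lambda p: (p.grid_loc, p.rotation, p.mirror))

    def test_count_agrees_with_independent_containment_backend(self, monk):
        """Brute-force enumeration cross-checked against a second geometry
        backend (matplotlib Path point containment on a dense sample)."""
        state = PuzzleState(monk.silhouette)
        ours = {p.key for p in legal_placements(state, "big_triangle")}
        target = Path([(float(x), float(y))
                       for x, y in monk.silhouette.target_vertices])
        tx0, ty0 = target.vertices.min(axis=0), None
        bounds = (target.vertices[:, 0].min(), target.vertices[:, 1].min(),
                  target.vertices[:, 0].max(), target.vertices[:, 1].max())
        grid = monk.silhouette.grid
        independent = set()
        for idx in range(1, len(grid) + 1):
            for rot in range(0, 360, 45):
                pl = Placement("big_triangle", idx, rot)
                verts = np.array(to_floats(transform("big_triangle", pl, grid)))
                (x0, y0), (x1, y1) = verts.min(axis=0), verts.max(axis=0)
                if (x0 < bounds[0] - 1e-9 or y0 < bounds[1] - 1e-9
                        or x1 > bounds[2] + 1e-9 or y1 > bounds[3] + 1e-9):
                    continue
                centroid = verts.mean(axis=0)
                path_piece = Path(centroid + (verts - centroid) * (1 - 1e-7))
                # dense interior sample; irrational-ish jitter keeps sample
                # points off the polygon edges
                xs = np.arange(x0 + 0.0137, x1, 0.0231)
                ys = np.arange(y0 + 0.0119, y1, 0.0231)
                xx, yy = np.meshgrid(xs, ys)
                pts = np.column_stack([xx.ravel(), yy.ravel()])
                sample = pts[path_piece.contains_points(pts)]
                if len(sample) and target.contains_points(sample).all():
                    independent.add(pl.key)
        assert ours == independent


class TestUnfeasibility:
    def test_empty_silhouette_is_feasible(self, puzzle):
        flag, blocked = detect_unfeasible(PuzzleState(puzzle.silhouette))
        assert (flag, blocked) == (False, set())

    def test_solved_state_is_feasible(self, puzzle):
        flag, blocked = detect_unfeasible(solved_state(puzzle))
        assert (flag, blocked) == (False, set())

    def test_modal_error_plus_torso_blocks_big_triangle(self, monk):
        """The wrong hypotenuse-down big triangle leaves a diagonal band; once
        the torso parallelogram is placed the second big triangle has nowhere
        to go, and the oracle agrees."""
        state = state_with(monk, [monk.modal_error, monk.solution[4]])
        flag, blocked = detect_unfeasible(state)
        assert flag and "big_triangle" in blocked
        assert legal_placements(state, "big_triangle") == []


class TestStateSignature:
    def test_empty_state(self, house):
        assert state_signature(PuzzleState(house.silhouette)) == ()

    def test_order_independence(self, puzzle):
        a = state_with(puzzle, puzzle.solution[:3])
        b = state_with(puzzle, list(reversed(puzzle.solution[:3])))
        assert state_signature(a) == state_signature(b)

    def test_same_kind_instances_interchangeable(self, house):
        """Swapping which physical small triangle goes in which slot leaves
        the signature unchanged."""
        smalls = [p for p in house.solution if p.kind == "small_triangle"]
        state_a = PuzzleState(house.silhouette)
        state_b = PuzzleState(house.silhouette)
        pool_a, pool_b = tan_pool(), tan_pool()
        s1, s2 = pool_a["small_triangle"]
        state_a.place(s1, smalls[0])
        state_a.place(s2, smalls[1])
        t1, t2 = pool_b["small_triangle"]
        state_b.place(t2, smalls[0])
        state_b.place(t1, smalls[1])
        assert state_signature(state_a) == state_signature(state_b)

    @given(st.permutations(range(5)))
    @settings(max_examples=20, derandomize=True, deadline=None)
    def test_signature_permutation_invariant(self, monk, perm):
        base = monk.solution[:5]
        state = state_with(monk, [base[i] for i in perm])
        assert state_signature(state) == state_signature(state_with(monk, base))


class TestRemoval:
    def test_place_remove_roundtrip(self, puzzle):
        state = state_with(puzzle, puzzle.solution[:2])
        sig = state_signature(state)
        extra = puzzle.solution[2]
        pool = tan_pool()
        state.place(pool[extra.kind].pop(), extra)
        state.remove(extra.key)
        assert state_signature(state) == sig
        assert state.step == 4  # both actions counted
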