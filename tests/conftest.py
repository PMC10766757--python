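import pytest

from cts.cognition import VariantParams
from cts.geometry import KINDS, PuzzleState, canonical_tans
from cts.puzzles import get_puzzle
from cts.vision import build_templates


@pytest.fixture(scope="session")
def house():
    return get_puzzle("house")


@pytest.fixture(scope="session")
def monk():
    return get_puzzle("monk")


@pytest.fixture(scope="session", params=["house", "monk"])
def puzzle(request):
    return get_puzzle(request.param)


@pytest.fixture(scope="session")
def bank16():
    return build_templates(16, mirror_allowed=True)


@pytest.fixture
def quiet_params():
    """Balanced variant with activation noise off (deterministic)."""
    return VariantParams.preset("balanced", noise_s=0.0)


def tan_pool():
    pool = {k: [] for k in KINDS}
    for tan in canonical_tans():
        pool[tan.kind].append(tan)
    return pool


def state_with(puzzle, placements):
    """A puzzle state with the given placements applied in order."""
    state = PuzzleState(puzzle.silhouette, puzzle.mirror_allowed)
    pool = tan_pool()
    for pl in placements:
        state.place(pool[pl.kind].pop(), pl)
    return state


def solved_state(puzzle):
    return state_with(puzzle, puzzle.solution)


def random_partial_state(puzzle, rng, max_pieces=4):
    """A random partial state built from uniformly drawn legal placements."""
    from cts.geometry import ROTATIONS, Placement

    state = PuzzleState(puzzle.silhouette, puzzle.mirror_allowed)
    pool = tan_pool()
    grid = puzzle.silhouette.grid
    n_target = int(rng.integers(1, max_pieces + 1))
    placed = 0
    tries = 0
    while placed < n_target and tries < 300:
        tries += 1
        free = [k for k in KINDS if pool[k]]
        kind = free[int(rng.integers(len(free)))]
        mir = bool(rng.integers(2)) if kind == "parallelogram" else False
        pl = Placement(kind, int(rng.integers(1, len(grid) + 1)),
                       int(ROTATIONS[int(rng.integers(8))]), mir)
        if state.is_legal(pl):
            state.place(pool[kind].pop(), pl)
            placed += 1
    return state
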