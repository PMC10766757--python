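"""Behavioral traces: data model, I/O, frequency tables, heatmaps and the
synthetic participant generator.

A trace is the ordered record of place/remove actions of one solver
(human-like synthetic participant or model run).  The CSV dialect is
``participant_id,step,action,kind,grid_loc,rotation,mirror`` with 1-based
consecutive steps; JSON-lines files carry the same fields.

The synthetic generator emulates the three-phase structure observed in human
tangram solving: a best-fit starting phase (the puzzle's salient opening
pattern), an exploration phase mixing unrecognized-composition errors,
random legal placements and backtracking, and a best-fit final phase (the
"aha" completion).  With probability ``p_perfect`` a trace is a minimal
7-step solution.  Every generated trace replays legally.
"""

from __future__ import annotations

import csv
import json
import math
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import yaml

from .geometry import (
    KIND_COUNTS,
    KINDS,
    ROTATIONS,
    Placement,
    PuzzleState,
    Tan,
    canonical_tans,
    state_signature,
)
from .puzzles import Puzzle

Key = Tuple[str, int, int, bool]


class TraceParseError(ValueError):
    def __init__(self, message: str, line: Optional[int] = None):
        super().__init__(f"line {line}: {message}" if line else message)
        self.line = line


class TraceValidationError(ValueError):
    pass


class ReplayError(RuntimeError):
    def __init__(self, message: str, step: Optional[int] = None):
        super().__init__(message)
        self.step = step


# ---------------------------------------------------------------------------
# Data model


@dataclass(frozen=True)
class StepRecord:
    participant_id: str
    step: int  # 1-based, consecutive within a trace
    action: str  # "place" | "remove"
    kind: str
    grid_loc: int
    rotation: int
    mirror: bool = False

    @property
    def key(self) -> Key:
        return (self.kind, self.grid_loc, self.rotation, self.mirror)


@dataclass
class Trace:
    participant_id: str
    steps: List[StepRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.steps)

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    def place_records(self) -> List[StepRecord]:
        return [s for s in self.steps if s.action == "place"]

    def append(self, action: str, placement: Placement) -> StepRecord:
        rec = StepRecord(self.participant_id, len(self.steps) + 1, action,
                         placement.kind, placement.grid_loc, placement.rotation,
                         placement.mirror)
        self.steps.append(rec)
        return rec


# ---------------------------------------------------------------------------
# Validation and replay


def validate_trace(trace: Trace) -> None:
    """Steps must be consecutive from 1; a remove must reference a
    currently-placed (kind, grid_loc, rotation, mirror); piece counts must
    respect the physical set (2 small, 2 big, 1 of each other kind)."""
    placed: Counter = Counter()
    kind_counts: Counter = Counter()
    for i, rec in enumerate(trace.steps):
        if rec.step != i + 1:
            raise TraceValidationError(
                f"{trace.participant_id}: step {rec.step} at position {i + 1}")
        if rec.action == "place":
            placed[rec.key] += 1
            kind_counts[rec.kind] += 1
            if kind_counts[rec.kind] > KIND_COUNTS[rec.kind]:
                raise TraceValidationError(
                    f"{trace.participant_id} step {rec.step}: too many {rec.kind}")
        elif rec.action == "remove":
            if placed[rec.key] <= 0:
                raise TraceValidationError(
                    f"{trace.participant_id} step {rec.step}: remove of "
                    f"never-placed {rec.key}")
            placed[rec.key] -= 1
            kind_counts[rec.kind] -= 1
        else:
            raise TraceValidationError(
                f"{trace.participant_id} step {rec.step}: bad action {rec.action!r}")


def replay_states(trace: Trace, puzzle: Puzzle,
                  upto: Optional[int] = None) -> List[PuzzleState]:
    """Replay a trace onto a fresh state; returns the state after every step
    (index i = state after step i+1).  Raises ReplayError naming the
    offending step if an action is geometrically illegal."""
    state = PuzzleState(puzzle.silhouette, puzzle.mirror_allowed)
    pool: Dict[str, List[Tan]] = {k: [] for k in KINDS}
    for tan in canonical_tans():
        pool[tan.kind].append(tan)
    states: List[PuzzleState] = []
    steps = trace.steps[:upto] if upto is not None else trace.steps
    for rec in steps:
        pl = Placement(rec.kind, rec.grid_loc, rec.rotation, rec.mirror)
        if rec.action == "place":
            if not pool[rec.kind]:
                raise ReplayError(f"step {rec.step}: no free {rec.kind}", rec.step)
            if not state.is_legal(pl):
                raise ReplayError(f"step {rec.step}: illegal placement {pl.key}",
                                  rec.step)
            state.place(pool[rec.kind].pop(), pl)
        else:
            try:
                tan = state.remove(pl.key)
            except KeyError as exc:
                raise ReplayError(f"step {rec.step}: {exc}", rec.step) from exc
            pool[rec.kind].append(tan)
        states.append(state.copy())
    return states


def replay_signatures(trace: Trace, puzzle: Puzzle) -> List[Tuple[Key, ...]]:
    return [state_signature(st) for st in replay_states(trace, puzzle)]


# ---------------------------------------------------------------------------
# I/O

_FIELDS = ["participant_id", "step", "action", "kind", "grid_loc", "rotation", "mirror"]


def _rec_from_row(row: Dict[str, str], line: int) -> StepRecord:
    try:
        return StepRecord(
            participant_id=str(row["participant_id"]),
            step=int(row["step"]),
            action=str(row["action"]),
            kind=str(row["kind"]),
            grid_loc=int(row["grid_loc"]),
            rotation=int(row["rotation"]),
            mirror=str(row.get("mirror", "False")).strip().lower() in ("1", "true"),
        )
    except (KeyError, ValueError) as exc:
        raise TraceParseError(str(exc), line) from exc


def read_traces(path: str, validate: bool = True) -> List[Trace]:
    """Read traces from CSV or JSON-lines (by extension).  Records may be
    interleaved across participants; within a participant they must be in
    step order."""
    by_id: Dict[str, Trace] = {}
    records: List[StepRecord] = []
    if str(path).endswith((".jsonl", ".json")):
        with open(path) as fh:
            for ln, raw in enumerate(fh, 1):
                raw = raw.strip()
                if not raw:
                    continue
                try:
                    row = json.loads(raw)
                except json.JSONDecodeError as exc:
                    raise TraceParseError(str(exc), ln) from exc
                records.append(_rec_from_row(row, ln))
    else:
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is not None and set(_FIELDS) - set(reader.fieldnames):
                raise TraceParseError(
                    f"missing columns {set(_FIELDS) - set(reader.fieldnames)}", 1)
            for ln, row in enumerate(reader, 2):
                records.append(_rec_from_row(row, ln))
    for rec in records:
        by_id.setdefault(rec.participant_id, Trace(rec.participant_id)).steps.append(rec)
    traces = list(by_id.values())
    if validate:
        for tr in traces:
            validate_trace(tr)
    return traces


def write_traces(traces: Sequence[Trace], path: str) -> None:
    if str(path).endswith((".jsonl", ".json")):
        with open(path, "w") as fh:
            for tr in traces:
                for rec in tr.steps:
                    fh.write(json.dumps(rec.__dict__) + "\n")
        return
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_FIELDS)
        writer.writeheader()
        for tr in traces:
            for rec in tr.steps:
                writer.writerow(rec.__dict__)


# ---------------------------------------------------------------------------
# Phases and frequency tables

DEFAULT_PHASE_BINS = (4, 11)  # phase 1: steps 1-4; phase 2: 5-11; phase 3: later


def phase_of(step: int, phase_bins: Tuple[int, int] = DEFAULT_PHASE_BINS) -> int:
    if step <= phase_bins[0]:
        return 1
    if step <= phase_bins[1]:
        return 2
    return 3


def default_phase_bins(traces: Sequence[Trace]) -> Tuple[int, int]:
    """Phase 1 ends at step 4; phase 2 at the ceiling of the mean step count."""
    mean = float(np.mean([t.n_steps for t in traces]))
    return (4, max(5, math.ceil(mean)))


class FrequencyTable:
    """Phase-conditioned relative frequencies of place actions.

    Maps (kind, grid_loc, rotation, phase) -> f in [0, 1]; within each phase
    the frequencies sum to 1 (empty phases are absent).
    """

    def __init__(self, entries: Dict[Tuple[str, int, int, int], float]):
        self._map = dict(entries)

    def get(self, kind: str, grid_loc: int, rotation: int, phase: int,
            default: float = 0.0) -> float:
        return self._map.get((kind, grid_loc, rotation % 360, phase), default)

    def items(self):
        return self._map.items()

    def __len__(self):
        return len(self._map)

    def phases(self) -> Set[int]:
        return {k[3] for k in self._map}

    def phase_sum(self, phase: int) -> float:
        return sum(v for k, v in self._map.items() if k[3] == phase)

    def max_value(self) -> float:
        return max(self._map.values()) if self._map else 0.0


def build_frequency_table(traces: Sequence[Trace],
                          phase_bins: Tuple[int, int] = DEFAULT_PHASE_BINS
                          ) -> FrequencyTable:
    """Per phase, counts of place actions normalized to sum to 1."""
    counts: Counter = Counter()
    totals: Counter = Counter()
    for tr in traces:
        for rec in tr.steps:
            if rec.action != "place":
                continue
            ph = phase_of(rec.step, phase_bins)
            counts[(rec.kind, rec.grid_loc, rec.rotation, ph)] += 1
            totals[ph] += 1
    return FrequencyTable(
        {k: v / totals[k[3]] for k, v in counts.items()})


def canonical_trace(puzzle: Puzzle, participant_id: str = "canonical") -> Trace:
    """The minimal 7-step solution, in salience order."""
    tr = Trace(participant_id)
    for pl in puzzle.solution:
        tr.append("place", pl)
    return tr


def canonical_frequency_table(puzzle: Puzzle,
                              phase_bins: Tuple[int, int] = (4, 7)) -> FrequencyTable:
    """A frequency table concentrated on the canonical solution."""
    return build_frequency_table([canonical_trace(puzzle)], phase_bins)


# ---------------------------------------------------------------------------
# Heatmaps


@dataclass
class Heatmap:
    """Per-step relative frequency of the chosen piece kind.

    ``matrix[s-1, p]`` is the fraction of traces whose s-th place action used
    kind ``kinds[p]``, among traces with at least s place actions.
    """

    matrix: np.ndarray  # (n_steps, 5)
    kinds: Tuple[str, ...] = KINDS
    support: np.ndarray = None  # traces contributing to each step row

    @property
    def n_steps(self) -> int:
        return self.matrix.shape[0]


def build_heatmap(traces: Sequence[Trace]) -> Heatmap:
    seqs = [[r.kind for r in tr.place_records()] for tr in traces]
    n_steps = max((len(s) for s in seqs), default=0)
    mat = np.zeros((n_steps, len(KINDS)))
    support = np.zeros(n_steps, dtype=int)
    kidx = {k: i for i, k in enumerate(KINDS)}
    for seq in seqs:
        for s, kind in enumerate(seq):
            mat[s, kidx[kind]] += 1
            support[s] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mat = np.where(support[:, None] > 0, mat / np.maximum(support[:, None], 1), 0.0)
    return Heatmap(mat, KINDS, support)


# ---------------------------------------------------------------------------
# Synthetic participants


@dataclass
class SynthParams:
    """Generator knobs.

    p_perfect: probability of a minimal 7-step solution (phase structure
    collapses to start + final).  p_composition_error: probability that a
    non-perfect trace commits the puzzle's modal unrecognized-composition
    error.  exploration_geometric_rate: success rate of the geometric
    exploration-length distribution (higher = shorter exploration).
    """

    p_perfect: float = 0.3
    p_composition_error: float = 0.7
    exploration_geometric_rate: float = 0.15
    p_explore_remove: float = 0.35
    max_explore: int = 20
    seed: int = 0

    def __post_init__(self):
        for name in ("p_perfect", "p_composition_error", "p_explore_remove"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.0 < self.exploration_geometric_rate <= 1.0:
            raise ValueError("exploration_geometric_rate must be in (0, 1]")


#: perfect-strategy ratios observed in the human cohorts the generator emulates
DEFAULT_P_PERFECT = {"house": 0.43, "monk": 0.27}


def default_synth_params(puzzle_name: str, seed: int = 0, **overrides) -> SynthParams:
    kw = dict(p_perfect=DEFAULT_P_PERFECT.get(puzzle_name, 0.3), seed=seed)
    kw.update(overrides)
    return SynthParams(**kw)


def _random_legal_placement(state: PuzzleState, rng: np.random.Generator,
                            forbidden: Set[Key], tries: int = 60) -> Optional[Placement]:
    grid = state.silhouette.grid
    free = state.free_kinds()
    if not free:
        return None
    for _ in range(tries):
        kind = free[int(rng.integers(len(free)))]
        idx = int(rng.integers(1, len(grid) + 1))
        rot = int(ROTATIONS[int(rng.integers(8))])
        mir = bool(rng.integers(2)) if (kind == "parallelogram" and state.mirror_allowed) else False
        pl = Placement(kind, idx, rot, mir)
        if pl.key in forbidden:
            continue
        if state.is_legal(pl):
            return pl
    return None


def synth_participants(puzzle: Puzzle, sp: SynthParams, n: int) -> List[Trace]:
    """Generate ``n`` legally replayable traces with the three-phase
    structure (best-fit start, exploration with errors and backtracking,
    best-fit completion)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(sp.seed)
    solution_keys = [pl.key for pl in puzzle.solution]
    out: List[Trace] = []
    for i in range(n):
        trace = Trace(f"synth{i:04d}")
        if rng.random() < sp.p_perfect:
            rest = [pl for pl in puzzle.solution if pl not in puzzle.opening]
            order = list(puzzle.opening) + [rest[j] for j in rng.permutation(len(rest))]
            for pl in order:
                trace.append("place", pl)
            out.append(trace)
            continue

        state = PuzzleState(puzzle.silhouette, puzzle.mirror_allowed)
        pool: Dict[str, List[Tan]] = {k: [] for k in KINDS}
        for tan in canonical_tans():
            pool[tan.kind].append(tan)

        def place(pl: Placement):
            state.place(pool[pl.kind].pop(), pl)
            trace.append("place", pl)

        def remove(key: Key):
            tan = state.remove(key)
            pool[tan.kind].append(tan)
            trace.append("remove", Placement(*key))

        for pl in puzzle.opening:
            place(pl)
        made_error = (puzzle.modal_error is not None
                      and rng.random() < sp.p_composition_error)
        if made_error:
            place(puzzle.modal_error)

        n_explore = int(rng.geometric(sp.exploration_geometric_rate)) - 1
        if not made_error:
            n_explore = max(1, n_explore)  # a non-perfect trace must stray
        n_explore = min(n_explore, sp.max_explore)
        # the composition error goes unnoticed until the final phase; any
        # other placement (including the opening) may be reconsidered
        protected = {puzzle.modal_error.key} if made_error else set()
        for _ in range(n_explore):
            removable = [p.placement.key for p in state.placed
                         if p.placement.key not in protected]
            if removable and rng.random() < sp.p_explore_remove:
                remove(removable[int(rng.integers(len(removable)))])
                continue
            pl = _random_legal_placement(state, rng, forbidden=set(solution_keys))
            if pl is not None:
                place(pl)
            elif removable:
                remove(removable[int(rng.integers(len(removable)))])
            else:
                break

        # noticing phase: clear everything that is not part of the solution
        for key in [p.placement.key for p in reversed(state.placed)
                    if p.placement.key not in solution_keys]:
            remove(key)
        # aha completion: best fit the rest, in salience order
        placed_keys = {p.placement.key for p in state.placed}
        for pl in puzzle.solution:
            if pl.key not in placed_keys:
                place(pl)
        assert state.solved
        out.append(trace)
    return out


# ---------------------------------------------------------------------------
# Transcribed observed-frequency fixture (Monk, big triangle, initial phase)


def load_observed_big_triangle_table() -> List[Dict]:
    """The transcribed printed table of big-triangle action frequencies in
    the Monk's initial phase (grid value, rotation, choice %), as published.
    The accompanying text places the modal error at a different printed grid
    location than the table row; the transcription preserves the table."""
    rows = []
    with resources.files("cts").joinpath("data/monk_big_triangle_initial_phase.csv").open() as fh:
        for row in csv.DictReader(fh):
            rows.append({"grid_value": int(row["grid_value"]),
                         "rotation": int(row["rotation"]),
                         "choice_pct": float(row["choice_pct"])})
    return rows


def load_observed_table_mapping() -> Dict[Tuple[int, int], Key]:
    """Mapping from the printed (grid value, rotation) pairs onto placements
    in this package's Monk grid numbering."""
    with resources.files("cts").joinpath("data/monk_table_grid_mapping.yaml").open() as fh:
        doc = yaml.safe_load(fh)
    out: Dict[Tuple[int, int], Key] = {}
    for row in doc["mapping"]:
        kind, loc, rot, mir = row["placement"]
        out[(int(row["table"][0]), int(row["table"][1]))] = (
            str(kind), int(loc), int(rot), bool(mir))
    return out


def observed_initial_frequency_table() -> FrequencyTable:
    """Phase-1 frequency table for the Monk big triangle, built from the
    transcribed observed table through the grid mapping."""
    mapping = load_observed_table_mapping()
    entries: Dict[Tuple[str, int, int, int], float] = {}
    for row in load_observed_big_triangle_table():
        key = mapping[(row["grid_value"], row["rotation"])]
        entries[(key[0], key[1], key[2], 1)] = row["choice_pct"] / 100.0
    return FrequencyTable(entries)
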