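"""The coordinator: vision -> scoring -> decision -> state update.

A :class:`Coordinator` owns the puzzle state, the pool of free tan
instances, the declarative store, the list of committed actions (for piece
backtracking) and the problem queue (for region backtracking).  When the
geometric unfeasibility check first fires, the most recent placement is
tagged into the problem queue — the solver noticed a problem and will stay
focused on clearing it, removing tagged placements queue-first, before any
new placement is considered.

Both simulation (:func:`run_trial`, :func:`run_batch`) and anticipation
(:func:`predict_next`, which replays a participant's prefix and asks the
model for the next move without committing it) are thin drivers over the
coordinator.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Deque, Dict, List, Optional, Tuple

import numpy as np

from .cognition import (
    ActionOption,
    DeadEndError,
    Decision,
    DeclarativeStore,
    StoredAction,
    VariantParams,
    decide,
)
from .geometry import KINDS, Placement, PuzzleState, Tan, canonical_tans, detect_unfeasible
from .puzzles import Puzzle
from .traces import (
    DEFAULT_PHASE_BINS,
    FrequencyTable,
    ReplayError,
    StepRecord,
    Trace,
    phase_of,
)
from .vision import DEFAULT_RESOLUTION, TemplateBank, build_templates, extract_action_options

Key = Tuple[str, int, int, bool]


@dataclass
class TrialResult:
    trace: Trace
    solved: bool
    n_steps: int
    seed: Optional[int]


@dataclass
class PredictedAction:
    """The model's suggested next move (not committed)."""

    action: str  # "place" | "remove"
    kind: str
    grid_loc: int
    rotation: int
    mirror: bool = False
    option: Optional[ActionOption] = None

    @property
    def key(self) -> Key:
        return (self.kind, self.grid_loc, self.rotation, self.mirror)


class Coordinator:
    def __init__(self, puzzle: Puzzle, params: VariantParams,
                 freqs: Optional[FrequencyTable], seed: Optional[int] = None,
                 resolution: int = DEFAULT_RESOLUTION,
                 phase_bins: Tuple[int, int] = DEFAULT_PHASE_BINS,
                 bank: Optional[TemplateBank] = None,
                 participant_id: str = "model"):
        self.puzzle = puzzle
        self.params = params
        self.freqs = freqs
        self.resolution = resolution
        self.phase_bins = phase_bins
        self.rng = np.random.default_rng(seed) if seed is not None else None
        self.bank = bank if bank is not None else build_templates(
            resolution, puzzle.mirror_allowed)
        self.state = PuzzleState(puzzle.silhouette, puzzle.mirror_allowed)
        self.pool: Dict[str, List[Tan]] = {k: [] for k in KINDS}
        for tan in canonical_tans():
            self.pool[tan.kind].append(tan)
        self.trace = Trace(participant_id)
        self.store = DeclarativeStore()
        self.stored_actions: List[StoredAction] = []
        self.problem_queue: Deque[Key] = deque()
        self.unfeasible = False

    # -- bookkeeping ----------------------------------------------------
    @property
    def current_step(self) -> int:
        return len(self.trace.steps) + 1

    @property
    def phase(self) -> int:
        return phase_of(self.current_step, self.phase_bins)

    def _refresh_unfeasible(self) -> None:
        flag, _blocked = detect_unfeasible(self.state)
        if flag and not self.unfeasible and self.state.placed:
            # problem noticed: tag the action taken as uncertain
            placed = self.state.placed[-1]
            self.state.problem_tags.add(placed.tan.instance_id)
            if placed.placement.key not in self.problem_queue:
                self.problem_queue.append(placed.placement.key)
        if not flag:
            self.problem_queue.clear()
        self.unfeasible = flag

    # -- deciding -------------------------------------------------------
    def extract_options(self) -> List[ActionOption]:
        freqs = self.freqs if self.params.frequency_screen else None
        return extract_action_options(
            self.state, self.bank, freqs, self.phase, self.resolution,
            frequency_screen=self.params.frequency_screen)

    def next_decision(self) -> Decision:
        options = self.extract_options()
        self.store.clear_options()
        return decide(self.state, options, self.params, self.rng,
                      self.stored_actions, store=self.store,
                      problem_queue=self.problem_queue,
                      unfeasible=self.unfeasible, freqs=self.freqs,
                      phase=self.phase)

    # -- applying -------------------------------------------------------
    def apply(self, decision: Decision) -> StepRecord:
        if decision.type == "place":
            opt: ActionOption = decision.payload
            pl = Placement(opt.kind, opt.grid_loc, opt.rotation, opt.mirror)
            if not self.pool[pl.kind]:
                raise DeadEndError(f"no free {pl.kind} instance")
            self.stored_actions.append(
                StoredAction(pl.key, opt.f, self.current_step))
            self.state.place(self.pool[pl.kind].pop(), pl)
            rec = self.trace.append("place", pl)
        else:
            key: Key = decision.payload
            tan = self.state.remove(key)
            self.pool[tan.kind].append(tan)
            for i in range(len(self.stored_actions) - 1, -1, -1):
                if self.stored_actions[i].key == key:
                    del self.stored_actions[i]
                    break
            if key in self.problem_queue:
                self.problem_queue.remove(key)
            rec = self.trace.append("remove", Placement(*key))
        self._refresh_unfeasible()
        return rec

    def force_apply(self, rec: StepRecord) -> None:
        """Apply a participant's recorded action (replay), keeping the same
        internal bookkeeping a model run would have."""
        pl = Placement(rec.kind, rec.grid_loc, rec.rotation, rec.mirror)
        if rec.action == "place":
            if not self.pool[pl.kind]:
                raise ReplayError(f"step {rec.step}: no free {pl.kind}", rec.step)
            if not self.state.is_legal(pl):
                raise ReplayError(f"step {rec.step}: illegal placement {pl.key}",
                                  rec.step)
            f = (self.freqs.get(pl.kind, pl.grid_loc, pl.rotation, self.phase)
                 if self.freqs is not None else 0.0)
            self.stored_actions.append(StoredAction(pl.key, f, self.current_step))
            self.state.place(self.pool[pl.kind].pop(), pl)
            self.trace.append("place", pl)
            # a committed placement counts as just retrieved
            self.store.recently_retrieved.append(pl.key)
            while len(self.store.recently_retrieved) > self.params.finst_span:
                self.store.recently_retrieved.popleft()
        else:
            try:
                tan = self.state.remove(pl.key)
            except KeyError as exc:
                raise ReplayError(f"step {rec.step}: {exc}", rec.step) from exc
            self.pool[tan.kind].append(tan)
            for i in range(len(self.stored_actions) - 1, -1, -1):
                if self.stored_actions[i].key == pl.key:
                    del self.stored_actions[i]
                    break
            if pl.key in self.problem_queue:
                self.problem_queue.remove(pl.key)
            self.trace.append("remove", pl)
        self._refresh_unfeasible()


# ---------------------------------------------------------------------------
# Drivers


def run_trial(puzzle: Puzzle, params: VariantParams,
              freqs: Optional[FrequencyTable], seed: Optional[int] = None,
              max_steps: int = 50, resolution: int = DEFAULT_RESOLUTION,
              phase_bins: Tuple[int, int] = DEFAULT_PHASE_BINS,
              bank: Optional[TemplateBank] = None,
              participant_id: str = "model") -> TrialResult:
    """One simulated solution attempt.  Terminates on a solved state, on
    ``max_steps`` actions, or on a dead end (nothing placed and nothing
    retrievable), which is recorded as an unsolved trial."""
    coord = Coordinator(puzzle, params, freqs, seed, resolution, phase_bins,
                        bank, participant_id)
    while not coord.state.solved and len(coord.trace.steps) < max_steps:
        try:
            decision = coord.next_decision()
            coord.apply(decision)
        except DeadEndError:
            break
    return TrialResult(coord.trace, coord.state.solved,
                       len(coord.trace.steps), seed)


def run_batch(puzzle: Puzzle, params: VariantParams,
              freqs: Optional[FrequencyTable], n_runs: int,
              base_seed: int = 0, **kwargs) -> List[TrialResult]:
    """``n_runs`` independent trials with seeds base_seed..base_seed+n-1."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    bank = kwargs.pop("bank", None)
    if bank is None:
        bank = build_templates(kwargs.get("resolution", DEFAULT_RESOLUTION),
                               puzzle.mirror_allowed)
    return [
        run_trial(puzzle, params, freqs, seed=base_seed + i, bank=bank,
                  participant_id=f"model{base_seed + i:04d}", **kwargs)
        for i in range(n_runs)
    ]


def _decision_to_prediction(decision: Decision) -> PredictedAction:
    if decision.type == "place":
        opt: ActionOption = decision.payload
        return PredictedAction("place", opt.kind, opt.grid_loc, opt.rotation,
                               opt.mirror, opt)
    kind, loc, rot, mir = decision.payload
    return PredictedAction("remove", kind, loc, rot, mir)


def predict_next(trace_prefix: Trace, puzzle: Puzzle, params: VariantParams,
                 freqs: Optional[FrequencyTable], seed: Optional[int] = None,
                 resolution: int = DEFAULT_RESOLUTION,
                 phase_bins: Tuple[int, int] = DEFAULT_PHASE_BINS,
                 bank: Optional[TemplateBank] = None) -> PredictedAction:
    """Replay a participant's prefix onto a fresh state, then return the
    model's chosen next action without committing it."""
    coord = Coordinator(puzzle, params, freqs, seed, resolution, phase_bins, bank)
    for rec in trace_prefix.steps:
        coord.force_apply(rec)
    return _decision_to_prediction(coord.next_decision())
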