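"""Memory-retrieval model over action-options.

Each visually extracted action-option is scored by a strength combining its
phase-conditioned training-data frequency f and its visual similarity s:

* linear variants:  strength = k_d * f + k_cv * s        (vision-, frequency-)
* balanced variant: strength = f * (1 - lambda * (1 - s))

The strength is the option's base-level activation.  The six strongest
options form the context buffer (a nod to the 7 +/- 2 span of visual working
memory) and receive spreading activation W/|context|.  Retrieval returns the
not-recently-retrieved chunk with the highest activation
A = B + S + logistic noise, if it exceeds the retrieval threshold; a
retrieval failure models the second, frequency-guided kind of backtracking
(remove the placed action with the lowest current-phase frequency), while a
flagged unfeasible region preempts retrieval and triggers queue-based region
backtracking.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Deque, Dict, List, Optional, Sequence, Tuple

import numpy as np

Key = Tuple[str, int, int, bool]


class DeadEndError(RuntimeError):
    """Backtracking was requested but nothing is placed: the run is stuck."""


class InvalidParameterError(ValueError):
    pass


@dataclass
class ActionOption:
    """A candidate (piece kind, grid location, rotation) with its visual
    similarity s_i, phase-conditioned frequency f and combined strength."""

    kind: str
    grid_loc: int
    rotation: int
    mirror: bool = False
    s_i: float = 0.0
    f: float = 0.0
    phase: int = 1
    strength: Optional[float] = None

    @property
    def key(self) -> Key:
        return (self.kind, self.grid_loc, self.rotation, self.mirror)


@dataclass
class VariantParams:
    """Tunable parameters of one solver variant.

    ``combine`` selects the strength formula: "linear" uses k_d*f + k_cv*s;
    "penalty" uses f*(1 - lam*(1 - s)) (the balanced variant, where the
    frequency of choice is discounted by the size of the template-matching
    error).
    """

    name: str = "balanced"
    combine: str = "penalty"
    k_d: float = 0.5
    k_cv: float = 0.5
    lam: float = 0.5
    noise_s: float = 0.25
    tau: float = 0.0  # retrieval threshold
    context_capacity: int = 6
    spreading_W: float = 1.0
    finst_span: int = 4
    frequency_screen: bool = True

    def __post_init__(self):
        if self.k_d < 0 or self.k_cv < 0:
            raise InvalidParameterError("strength weights must be non-negative")
        if self.k_d + self.k_cv <= 0:
            raise InvalidParameterError("k_d + k_cv must be positive")
        if self.context_capacity < 1:
            raise InvalidParameterError("context_capacity must be >= 1")
        if self.noise_s < 0 or self.spreading_W < 0:
            raise InvalidParameterError("noise_s and spreading_W must be >= 0")

    @classmethod
    def preset(cls, name: str, **overrides) -> "VariantParams":
        base = {
            "vision": dict(name="vision", combine="linear", k_d=0.2, k_cv=0.8,
                           frequency_screen=False),
            "frequency": dict(name="frequency", combine="linear", k_d=0.8, k_cv=0.2),
            "balanced": dict(name="balanced", combine="penalty", lam=0.5),
        }[name]
        base.update(overrides)
        return cls(**base)


def compute_strength(option: ActionOption, params: VariantParams) -> float:
    """Score an option and store the result on it."""
    if not (0.0 <= option.f <= 1.0) or not (0.0 <= option.s_i <= 1.0):
        raise InvalidParameterError("f and s_i must lie in [0, 1]")
    if params.combine == "penalty":
        strength = option.f * (1.0 - params.lam * (1.0 - option.s_i))
    else:
        strength = params.k_d * option.f + params.k_cv * option.s_i
    option.strength = float(strength)
    return option.strength


def score_options(options: Sequence[ActionOption], params: VariantParams) -> None:
    for opt in options:
        compute_strength(opt, params)


def _rank_key(opt: ActionOption) -> Tuple:
    # strongest first; ties: higher f, lower grid_loc, lower rotation
    return (-(opt.strength or 0.0), -opt.f, opt.grid_loc, opt.rotation, opt.mirror)


def build_context(options: Sequence[ActionOption], capacity: int = 6) -> List[ActionOption]:
    """The ``capacity`` strongest options (the imaginal-buffer context)."""
    if capacity < 1:
        raise InvalidParameterError("capacity must be >= 1")
    return sorted(options, key=_rank_key)[:capacity]


# ---------------------------------------------------------------------------
# Declarative store and retrieval


@dataclass
class DeclarativeStore:
    chunks: Dict[Key, ActionOption] = field(default_factory=dict)
    recently_retrieved: Deque[Key] = field(default_factory=deque)

    def add_options(self, options: Sequence[ActionOption]) -> None:
        for opt in options:
            self.chunks[opt.key] = opt

    def clear_options(self) -> None:
        self.chunks.clear()


def activation(chunk: ActionOption, context: Sequence[ActionOption],
               params: VariantParams, rng: Optional[np.random.Generator] = None) -> float:
    """A = B + S + eps: base-level B is the option strength; spreading S is
    W/|context| for each context entry matching the chunk (association 1 for
    a self-match, 0 otherwise); eps ~ logistic(0, noise_s)."""
    B = chunk.strength if chunk.strength is not None else 0.0
    S = 0.0
    if context:
        wj = params.spreading_W / len(context)
        S = wj * sum(1 for c in context if c.key == chunk.key)
    eps = 0.0
    if params.noise_s > 0:
        if rng is None:
            raise ValueError("rng required when noise_s > 0")
        eps = float(rng.logistic(0.0, params.noise_s))
    return B + S + eps


def retrieve(store: DeclarativeStore, context: Sequence[ActionOption],
             params: VariantParams,
             rng: Optional[np.random.Generator] = None) -> Optional[ActionOption]:
    """Highest-activation chunk not recently retrieved, if above the
    threshold; ``None`` models a retrieval failure.  The retrieved chunk id
    joins the recently-retrieved (finst) list, oldest evicted beyond
    ``finst_span``."""
    best: Optional[ActionOption] = None
    best_a = -np.inf
    recently = set(store.recently_retrieved)
    for key in sorted(store.chunks, key=lambda k: _rank_key(store.chunks[k])):
        if key in recently:
            continue
        a = activation(store.chunks[key], context, params, rng)
        if a > best_a:
            best, best_a = store.chunks[key], a
    if best is None or best_a <= params.tau:
        return None
    store.recently_retrieved.append(best.key)
    while len(store.recently_retrieved) > params.finst_span:
        store.recently_retrieved.popleft()
    return best


# ---------------------------------------------------------------------------
# Decisions


@dataclass
class StoredAction:
    """A committed action remembered for potential backtracking."""

    key: Key
    f: float  # frequency at commit time
    step: int


@dataclass
class Decision:
    type: str  # "place" | "region_backtrack" | "piece_backtrack"
    payload: object  # ActionOption (place) or Key (backtracks)


def piece_backtrack_target(stored_actions: Sequence[StoredAction], freqs,
                           phase: Optional[int] = None) -> Key:
    """The placed action with the lowest frequency (ties: most recent).

    With ``freqs`` and ``phase`` given, frequencies are re-evaluated at the
    current phase — an action with no support in the current phase comes
    first; otherwise the commit-time frequency is used.
    """
    if not stored_actions:
        raise DeadEndError("piece backtrack requested with nothing placed")

    def current_f(sa: StoredAction) -> float:
        if freqs is not None and phase is not None:
            return float(freqs.get(sa.key[0], sa.key[1], sa.key[2], phase))
        return sa.f

    best = None
    best_f = np.inf
    for sa in reversed(stored_actions):  # most recent first => wins ties
        fv = current_f(sa)
        if fv < best_f:
            best, best_f = sa, fv
    return best.key


def region_backtrack_step(state, problem_queue: Deque[Key]) -> Optional[Key]:
    """Head of the problem queue (the first noticed problematic action), to
    be removed next; ``None`` when the queue is exhausted (callers then fall
    through to piece backtracking)."""
    if not problem_queue:
        return None
    return problem_queue[0]


def decide(state, options: Sequence[ActionOption], params: VariantParams,
           rng: Optional[np.random.Generator], stored_actions: Sequence[StoredAction],
           store: Optional[DeclarativeStore] = None,
           problem_queue: Optional[Deque[Key]] = None,
           unfeasible: bool = False, freqs=None, phase: Optional[int] = None) -> Decision:
    """One decision: region backtrack if an unfeasible region was noticed
    (queue-based, preempting retrieval), otherwise retrieve an action-option
    to place, otherwise piece-backtrack the weakest stored action."""
    if unfeasible:
        head = region_backtrack_step(state, problem_queue or deque())
        if head is not None:
            return Decision("region_backtrack", head)
        # noticed problem but queue exhausted: combine the two strategies
        return Decision("piece_backtrack",
                        piece_backtrack_target(stored_actions, freqs, phase))
    if store is None:
        store = DeclarativeStore()
    score_options(options, params)
    store.add_options(options)
    context = build_context(options, params.context_capacity)
    chunk = retrieve(store, context, params, rng)
    if chunk is not None:
        return Decision("place", chunk)
    return Decision("piece_backtrack",
                    piece_backtrack_target(stored_actions, freqs, phase))
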