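"""Evaluation of model runs against behavioral traces.

Four methods: overall step statistics with the perfect-strategy ratio;
per-step piece-choice heatmap RMSE

    RMSE_s = sqrt( sum_p (h(p,s,model) - h(p,s,data))^2 / 5 )

averaged over steps; step-by-step states plausibility (the fraction of model
states at step s that also occur among the data states within s +/- offset,
the offset growing with s to absorb longer backtracking); and k-step-window
prediction accuracy (a predicted action counts as a hit if it happens within
the participant's next ``window`` steps).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .cognition import VariantParams
from .puzzles import Puzzle
from .traces import (
    FrequencyTable,
    Heatmap,
    Trace,
    build_heatmap,
    replay_signatures,
)


@dataclass
class EvalReport:
    mean_steps: float
    sd_steps: float
    perfect_ratio: float
    heatmap_rmse_per_step: List[float] = field(default_factory=list)
    heatmap_rmse_mean: float = float("nan")
    plausibility: float = float("nan")
    prediction_accuracy: float = float("nan")

    def as_dict(self) -> Dict[str, object]:
        return {
            "mean_steps": self.mean_steps,
            "sd_steps": self.sd_steps,
            "perfect_ratio": self.perfect_ratio,
            "heatmap_rmse_per_step": self.heatmap_rmse_per_step,
            "heatmap_rmse_mean": self.heatmap_rmse_mean,
            "plausibility": self.plausibility,
            "prediction_accuracy": self.prediction_accuracy,
        }


# ---------------------------------------------------------------------------
# 1. Overall statistics


def overall_stats(traces: Sequence[Trace], puzzle: Optional[Puzzle] = None,
                  count_removals: bool = True) -> Tuple[float, float, float]:
    """Mean and sample SD of per-trace step counts, and the perfect-strategy
    ratio (solved in the minimal 7 steps, one per tan).

    With ``puzzle`` given, solvedness is established by geometric replay;
    otherwise a trace counts as perfect iff it consists of exactly 7 place
    actions and no removal (true for every generated cohort, where only
    solved traces are emitted).
    """
    if not traces:
        raise ValueError("no traces")
    counts = [
        t.n_steps if count_removals else len(t.place_records()) for t in traces
    ]
    mean = float(np.mean(counts))
    sd = float(np.std(counts, ddof=1)) if len(counts) > 1 else 0.0
    perfect = 0
    for t, c in zip(traces, counts):
        if c != 7 or len(t.place_records()) != 7:
            continue
        if puzzle is not None:
            states = _replay_final(t, puzzle)
            if not states:
                continue
        perfect += 1
    return mean, sd, perfect / len(traces)


def _replay_final(trace: Trace, puzzle: Puzzle) -> bool:
    from .traces import replay_states

    states = replay_states(trace, puzzle)
    return bool(states) and states[-1].solved


# ---------------------------------------------------------------------------
# 2. Heatmap RMSE


def heatmap_rmse(model_hm: Heatmap, data_hm: Heatmap,
                 n_steps: Optional[int] = None) -> Tuple[List[float], float]:
    """Per-step RMSE between two piece-choice heatmaps and its mean over the
    compared step range (by default the steps covered by both)."""
    if tuple(model_hm.kinds) != tuple(data_hm.kinds):
        raise ValueError("heatmaps have mismatched piece-kind axes")
    n = min(model_hm.n_steps, data_hm.n_steps)
    if n_steps is not None:
        if n_steps > n:
            raise ValueError(f"step range {n_steps} not covered by both heatmaps")
        n = n_steps
    if n == 0:
        raise ValueError("no common steps to compare")
    diff = model_hm.matrix[:n] - data_hm.matrix[:n]
    per_step = list(np.sqrt((diff ** 2).sum(axis=1) / diff.shape[1]))
    return per_step, float(np.mean(per_step))


# ---------------------------------------------------------------------------
# 3. Step-by-step states plausibility


def default_offset_schedule(s: int) -> int:
    """Offset grows with the step index: 1 for steps 3-6, 2 for 7-10, ..."""
    return 1 + max(0, (s - 3)) // 4


def states_plausibility(model_traces: Sequence[Trace],
                        data_traces: Sequence[Trace], puzzle: Puzzle,
                        step_range: Optional[Tuple[int, int]] = None,
                        offset_schedule: Callable[[int], int] = default_offset_schedule,
                        dedupe: bool = False) -> float:
    """Fraction of model states at steps in ``step_range`` (default 3 to
    mean+1*sd of the data step counts) matching some data state signature at
    a step within +/- offset(s)."""
    if not model_traces or not data_traces:
        raise ValueError("model and data traces must be non-empty")
    if step_range is None:
        counts = [t.n_steps for t in data_traces]
        hi = math.ceil(float(np.mean(counts)) + float(np.std(counts, ddof=1))
                       if len(counts) > 1 else float(counts[0]))
        step_range = (3, max(3, hi))
    lo, hi = step_range

    data_sigs: Dict[int, Set] = {}
    for tr in data_traces:
        for s, sig in enumerate(replay_signatures(tr, puzzle), start=1):
            data_sigs.setdefault(s, set()).add(sig)

    total = 0
    matched = 0
    seen: Set[Tuple[int, Tuple]] = set()
    for tr in model_traces:
        sigs = replay_signatures(tr, puzzle)
        for s in range(lo, min(hi, len(sigs)) + 1):
            sig = sigs[s - 1]
            if dedupe:
                if (s, sig) in seen:
                    continue
                seen.add((s, sig))
            total += 1
            off = offset_schedule(s)
            lo_s, hi_s = max(1, s - off), s + off
            if any(sig in data_sigs.get(t, ()) for t in range(lo_s, hi_s + 1)):
                matched += 1
    if total == 0:
        raise ValueError("no model states fall in the evaluated step range")
    return matched / total


# ---------------------------------------------------------------------------
# 4. Prediction accuracy


def prediction_hits(trace: Trace, puzzle: Puzzle, params: VariantParams,
                    freqs: Optional[FrequencyTable], window: int = 2,
                    seed: Optional[int] = None, match: str = "exact",
                    **coord_kwargs) -> List[bool]:
    """Hit/miss for the model's prediction at every step of one trace: a hit
    iff the suggested action occurs among the trace's next ``window``
    actions.  ``match='kind'`` relaxes the comparison to action type and
    piece kind only."""
    from .simulator import Coordinator, _decision_to_prediction

    if window < 1:
        raise ValueError("window must be >= 1")
    coord = Coordinator(puzzle, params, freqs, seed, **coord_kwargs)
    hits: List[bool] = []
    for k, rec in enumerate(trace.steps):
        pred = _decision_to_prediction(coord.next_decision())
        upcoming = trace.steps[k:k + window]
        if match == "kind":
            hit = any(r.action == pred.action and r.kind == pred.kind
                      for r in upcoming)
        else:
            hit = any(r.action == pred.action
                      and (r.kind, r.grid_loc, r.rotation) ==
                      (pred.kind, pred.grid_loc, pred.rotation)
                      for r in upcoming)
        hits.append(hit)
        coord.force_apply(rec)
    return hits


def prediction_accuracy(data_traces: Sequence[Trace], puzzle: Puzzle,
                        params: VariantParams,
                        freqs: Optional[FrequencyTable], window: int = 2,
                        seed: Optional[int] = None, match: str = "exact",
                        **coord_kwargs) -> float:
    """Fraction of prediction points across all traces where the model's
    suggested action happens within the next ``window`` participant steps."""
    if not data_traces:
        raise ValueError("no traces")
    all_hits: List[bool] = []
    for i, tr in enumerate(data_traces):
        try:
            all_hits.extend(prediction_hits(tr, puzzle, params, freqs, window,
                                            None if seed is None else seed + i,
                                            match, **coord_kwargs))
        except Exception as exc:
            raise RuntimeError(f"trace {tr.participant_id}: {exc}") from exc
    if not all_hits:
        raise ValueError("no prediction points")
    return float(np.mean(all_hits))


# ---------------------------------------------------------------------------
# Combined report


def evaluate(model_traces: Sequence[Trace], data_traces: Sequence[Trace],
             puzzle: Puzzle, params: Optional[VariantParams] = None,
             freqs: Optional[FrequencyTable] = None, window: int = 2,
             seed: Optional[int] = None, **coord_kwargs) -> EvalReport:
    """Full evaluation of a set of model runs against data traces; the
    prediction metric is only computed when ``params`` is given."""
    mean, sd, ratio = overall_stats(model_traces)
    per_step, rmse_mean = heatmap_rmse(build_heatmap(model_traces),
                                       build_heatmap(data_traces))
    plaus = states_plausibility(model_traces, data_traces, puzzle)
    report = EvalReport(mean, sd, ratio, per_step, rmse_mean, plaus)
    if params is not None:
        report.prediction_accuracy = prediction_accuracy(
            data_traces, puzzle, params, freqs, window, seed, **coord_kwargs)
    return report
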