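"""The four evaluation methods: statistics, heatmap RMSE, plausibility,
prediction accuracy."""

import math

import numpy as np
import pytest

from cts import traces as T
from cts.geometry import Placement
from cts.evaluation import (
    default_offset_schedule,
    heatmap_rmse,
    overall_stats,
    prediction_hits,
    prediction_accuracy,
    states_plausibility,
)
from cts.simulator import run_trial
from cts.traces import Heatmap, Trace, build_heatmap, canonical_frequency_table


def make_trace(puzzle, placements, pid="p"):
    tr = Trace(pid)
    for pl in placements:
        tr.append("place", pl)
    return tr


class TestOverallStats:
    def test_all_canonical(self, monk):
        tr = [make_trace(monk, monk.solution, f"p{i}") for i in range(3)]
        assert overall_stats(tr, puzzle=monk) == (7.0, 0.0, 1.0)

    def test_mixed_lengths(self, monk):
        t1 = make_trace(monk, monk.solution, "p1")
        t2 = Trace("p2")
        for pl in monk.solution[:4]:
            t2.append("place", pl)
        for pl in monk.solution[:4]:
            t2.append("remove", pl)
        for pl in monk.solution:
            t2.append("place", pl)
        mean, sd, ratio = overall_stats([t1, t2], puzzle=monk)
        assert mean == pytest.approx((7 + 15) / 2)
        assert ratio == 0.5

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            overall_stats([])

    def test_perfect_ratio_recovers_generator_parameter(self, monk):
        sp = T.default_synth_params("monk", seed=13)
        cohort = T.synth_participants(monk, sp, 100)
        _, _, ratio = overall_stats(cohort)
        sd = math.sqrt(0.27 * 0.73 / 100)
        assert abs(ratio - 0.27) <= 3 * sd


class TestHeatmapRMSE:
    def test_identical_heatmaps_zero(self, monk):
        sp = T.default_synth_params("monk", seed=1)
        cohort = T.synth_participants(monk, sp, 10)
        hm = build_heatmap(cohort)
        per_step, mean = heatmap_rmse(hm, hm)
        assert mean == 0.0
        assert all(v == 0.0 for v in per_step)

    def test_one_hot_disagreement_closed_form(self):
        a = Heatmap(np.array([[1.0, 0, 0, 0, 0]]), support=np.array([1]))
        b = Heatmap(np.array([[0, 1.0, 0, 0, 0]]), support=np.array([1]))
        per_step, mean = heatmap_rmse(a, b)
        assert per_step[0] == pytest.approx(math.sqrt(2 / 5), abs=1e-6)
        assert mean == pytest.approx(0.632456, abs=1e-6)

    def test_small_shift_closed_form(self):
        a = Heatmap(np.array([[0.5, 0.5, 0, 0, 0]]), support=np.array([1]))
        b = Heatmap(np.array([[0.6, 0.4, 0, 0, 0]]), support=np.array([1]))
        per_step, _ = heatmap_rmse(a, b)
        assert per_step[0] == pytest.approx(math.sqrt(0.02 / 5), abs=1e-6)

    def test_metric_properties(self, monk):
        rng = np.random.default_rng(0)
        rows = rng.dirichlet(np.ones(5), size=4)
        a = Heatmap(rows, support=np.ones(4, int))
        b = Heatmap(rng.dirichlet(np.ones(5), size=4), support=np.ones(4, int))
        ab = heatmap_rmse(a, b)[1]
        ba = heatmap_rmse(b, a)[1]
        assert ab == pytest.approx(ba)
        assert ab >= 0
        assert heatmap_rmse(a, a)[1] == 0.0

    def test_one_hot_bound(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            a = np.zeros((1, 5)); a[0, rng.integers(5)] = 1.0
            b = np.zeros((1, 5)); b[0, rng.integers(5)] = 1.0
            val = heatmap_rmse(Heatmap(a, support=np.array([1])),
                               Heatmap(b, support=np.array([1])))[1]
            assert val <= math.sqrt(2 / 5) + 1e-12

    def test_mismatched_axes_error(self):
        a = Heatmap(np.zeros((1, 5)), kinds=("a", "b", "c", "d", "e"),
                    support=np.array([1]))
        b = Heatmap(np.zeros((1, 5)), support=np.array([1]))
        with pytest.raises(ValueError):
            heatmap_rmse(a, b)


class TestStatesPlausibility:
    def test_self_comparison_is_one(self, monk):
        sp = T.default_synth_params("monk", seed=4)
        cohort = T.synth_participants(monk, sp, 8)
        assert states_plausibility(cohort, cohort, monk) == 1.0

    def test_disjoint_states_zero(self, monk, house):
        sp = T.default_synth_params("monk", seed=4)
        model = T.synth_participants(monk, sp, 4)
        # data traces never visit the model's states: different opening region
        data = [make_trace(monk, [monk.modal_error], "d0")]
        # force a comparable range despite the short data trace
        val = states_plausibility(model, data, monk, step_range=(3, 6))
        assert val == 0.0

    def test_shifted_trace_matches_with_offset(self, monk):
        base = T.canonical_trace(monk)
        # model trace delayed by a place/remove stutter: states shifted by 2
        model = Trace("m")
        model.append("place", monk.solution[0])
        model.append("remove", monk.solution[0])
        for pl in monk.solution:
            model.append("place", pl)
        exact = states_plausibility([model], [base], monk,
                                    offset_schedule=lambda s: 2)
        assert exact == 1.0
        strict = states_plausibility([model], [base], monk,
                                     offset_schedule=lambda s: 0)
        assert strict < 1.0

    def test_monotone_in_offset(self, monk):
        sp = T.default_synth_params("monk", seed=6)
        model = T.synth_participants(monk, sp, 5)
        data = T.synth_participants(monk, T.default_synth_params("monk", seed=60), 5)
        vals = [states_plausibility(model, data, monk,
                                    offset_schedule=lambda s, o=o: o)
                for o in (0, 1, 2, 4)]
        assert vals == sorted(vals)

    def test_default_offset_schedule_grows(self):
        assert [default_offset_schedule(s) for s in (3, 6, 7, 10, 11)] == \
            [1, 1, 2, 2, 3]

    def test_empty_inputs_error(self, monk):
        with pytest.raises(ValueError):
            states_plausibility([], [], monk)


class TestPredictionAccuracy:
    def test_self_prediction_is_one(self, puzzle, bank16, quiet_params):
        freqs = canonical_frequency_table(puzzle)
        result = run_trial(puzzle, quiet_params, freqs, seed=0,
                           phase_bins=(4, 7), bank=bank16)
        acc = prediction_accuracy([result.trace], puzzle, quiet_params, freqs,
                                  window=2, phase_bins=(4, 7), bank=bank16)
        assert acc == 1.0

    def test_window_semantics_hit_at_two_miss_at_three(self, house, bank16,
                                                       quiet_params):
        """The model's suggestion two steps ahead counts as a hit; three
        steps ahead it does not."""
        freqs = canonical_frequency_table(house)
        canon = T.canonical_trace(house).steps
        prefix = canon[:4]
        from cts.simulator import predict_next

        pred = predict_next(Trace("p", list(prefix)), house, quiet_params,
                            freqs, phase_bins=(4, 7), bank=bank16)
        assert pred.action == "place"
        rest = [s for s in canon[4:] if s.key != pred.key]
        predicted = next(s for s in canon[4:] if s.key == pred.key)

        def with_delay(delay):
            order = list(prefix) + rest[:delay - 1] + [predicted] + rest[delay - 1:]
            tr = Trace("d")
            for s in order:
                tr.append("place", Placement(s.kind, s.grid_loc, s.rotation,
                                             s.mirror))
            return tr

        hits2 = prediction_hits(with_delay(2), house, quiet_params, freqs,
                                window=2, phase_bins=(4, 7), bank=bank16)
        assert hits2[4]  # suggestion happens 2 steps after the prefix: hit
        hits3 = prediction_hits(with_delay(3), house, quiet_params, freqs,
                                window=2, phase_bins=(4, 7), bank=bank16)
        assert not hits3[4]  # 3 steps ahead: miss

    def test_monotone_in_window(self, monk, bank16, quiet_params):
        sp = T.default_synth_params("monk", seed=8)
        cohort = T.synth_participants(monk, sp, 3)
        freqs = T.build_frequency_table(cohort, T.default_phase_bins(cohort))
        accs = [prediction_accuracy(cohort, monk, quiet_params, freqs,
                                    window=w, bank=bank16) for w in (1, 2, 4)]
        assert accs == sorted(accs)

    def test_kind_match_at_least_exact_match(self, monk, bank16, quiet_params):
        sp = T.default_synth_params("monk", seed=8)
        cohort = T.synth_participants(monk, sp, 2)
        freqs = T.build_frequency_table(cohort, T.default_phase_bins(cohort))
        exact = prediction_accuracy(cohort, monk, quiet_params, freqs,
                                    window=2, bank=bank16)
        coarse = prediction_accuracy(cohort, monk, quiet_params, freqs,
                                     window=2, match="kind", bank=bank16)
        assert coarse >= exact
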