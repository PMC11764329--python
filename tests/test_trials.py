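import numpy as np
import pytest
from scipy import stats

from cagetime.events import ParseError, pool_condition_days
from cagetime.simulate import SimulationConfig, simulate_cohort
from cagetime.trials import (build_choice_table, build_trials,
                             check_learning_criterion, summarize_activity)

from conftest import make_log, visit_rows


def one_visit_trials(dur, pokes, with_off=True):
    log = make_log(visit_rows("ratA", "2024-03-01T16:10:00", dur, pokes,
                              with_off=with_off))
    return build_trials(log)


class TestClassification:
    def test_short_stimulus_poke_left_is_timed_correct(self):
        (t,) = one_visit_trials(1.0, [(1.3, "left")])
        assert t.classification == "timed"
        assert t.response_side == "left" and t.correct is True
        assert t.response_latency_s == pytest.approx(1.3)

    def test_premature_poke_does_not_stop_trial(self):
        (t,) = one_visit_trials(4.0, [(2.0, "right"), (4.5, "right")])
        assert t.classification == "timed" and t.correct is True
        assert t.n_premature_pokes == 1
        assert t.response_latency_s == pytest.approx(4.5)

    def test_no_poke_is_omission(self):
        (t,) = one_visit_trials(2.5, [])
        assert t.classification == "omission"
        assert t.response_side is None

    def test_premature_only_is_neither_timed_nor_omission(self):
        (t,) = one_visit_trials(4.0, [(1.0, "left")])
        assert t.classification == "premature_only"

    def test_intermediate_duration_has_no_correctness(self):
        (t,) = one_visit_trials(2.5, [(3.0, "right")])
        assert t.correct is None

    def test_offset_falls_back_to_nominal_duration(self):
        (t,) = one_visit_trials(1.0, [(1.3, "left")], with_off=False)
        assert t.classification == "timed"

    def test_unknown_duration_raises_with_timestamp(self):
        log = make_log(visit_rows("ratA", "2024-03-01T16:10:00", 7.0, []))
        with pytest.raises(ParseError, match="unknown duration"):
            build_trials(log)

    def test_repeat_index_increments_after_anchor_error(self):
        rows = visit_rows("ratA", "2024-03-01T16:10:00", 1.0, [(1.3, "right")])
        # re-presentation of the same anchor inside the same visit
        rows = rows[:-1] + visit_rows("ratA", "2024-03-01T16:10:10", 1.0,
                                      [(1.4, "left")])[1:]
        trials = build_trials(make_log(rows))
        assert [t.repeat_index for t in trials] == [0, 1]
        assert [t.correct for t in trials] == [False, True]

    def test_partition_into_exactly_one_class(self, small_cohort):
        cfg, log, _ = small_cohort
        trials = build_trials(pool_condition_days(log, "saline"))
        counts = {c: sum(t.classification == c for t in trials)
                  for c in ("timed", "premature_only", "omission")}
        assert sum(counts.values()) == len(trials)
        n_stim = (pool_condition_days(log, "saline")
                  .events["event_kind"] == "stimulus_on").sum()
        assert len(trials) == n_stim  # one trial per stimulus presentation


class TestChoiceTable:
    def test_arithmetic(self):
        rows = []
        sides = ["right"] * 9 + ["left"]
        for k, side in enumerate(sides):
            rows += visit_rows("ratA", f"2024-03-01T16:{10 + k}:00", 4.0,
                               [(4.3, side)])
        table = build_choice_table(build_trials(make_log(rows)), "saline")
        assert table.p_long[4.0] == pytest.approx(0.9)

    def test_undefined_durations_flagged_and_shape_kept(self):
        rows = visit_rows("ratA", "2024-03-01T16:10:00", 1.0, [(1.3, "left")])
        rows += visit_rows("ratA", "2024-03-01T16:12:00", 4.0, [(4.3, "right")])
        table = build_choice_table(build_trials(make_log(rows)), "saline")
        assert set(table.durations) == {1.0, 1.65, 2.5, 3.25, 4.0}
        p = table.p_long
        assert sum(np.isnan(p[t]) for t in table.durations) == 3

    def test_counts_match_brute_force_event_scan(self, small_cohort):
        """Oracle: recount right/left pokes after offset straight from events."""
        cfg, log, _ = small_cohort
        pooled = pool_condition_days(log, "saline")
        animal = pooled.events["animal_id"].iloc[0]
        trials = [t for t in build_trials(pooled) if t.animal_id == animal]
        table = build_choice_table(trials, "saline")

        ev = pooled.events.query("animal_id == @animal").reset_index(drop=True)
        n_long = {t: 0 for t in table.durations}
        n_short = {t: 0 for t in table.durations}
        open_dur, offset = None, None
        for row in ev.itertuples():
            if row.event_kind == "stimulus_on":
                open_dur = float(row.stimulus_duration_s)
                offset = None
            elif row.event_kind == "stimulus_off":
                offset = row.timestamp
            elif row.event_kind == "nosepoke" and open_dur is not None:
                if offset is not None and row.timestamp >= offset:
                    (n_long if row.side == "right" else n_short)[open_dur] += 1
                    open_dur = None  # first timed poke closes the trial
            elif row.event_kind == "visit_end":
                open_dur = None
        assert n_long == table.n_long and n_short == table.n_short

    def test_exclude_repeats_flag(self):
        rows = visit_rows("ratA", "2024-03-01T16:10:00", 1.0, [(1.3, "right")])
        rows = rows[:-1] + visit_rows("ratA", "2024-03-01T16:10:10", 1.0,
                                      [(1.4, "left")])[1:]
        trials = build_trials(make_log(rows))
        with_rep = build_choice_table(trials, "s", include_repeats=True)
        without = build_choice_table(trials, "s", include_repeats=False)
        assert with_rep.n_timed(1.0) == 2 and without.n_timed(1.0) == 1


class TestActivitySummary:
    def test_arithmetic(self):
        rows = []
        t = 0
        for _ in range(10):  # 10 timed
            rows += visit_rows("ratA", f"2024-03-01T16:{t:02d}:00", 2.5, [(3.0, "right")])
            t += 1
        for _ in range(3):  # 3 omissions
            rows += visit_rows("ratA", f"2024-03-01T16:{t:02d}:00", 2.5, [])
            t += 1
        for _ in range(2):  # 2 premature pokes on timed trials
            rows += visit_rows("ratA", f"2024-03-01T16:{t:02d}:00", 2.5,
                               [(1.0, "left"), (3.0, "right")])
            t += 1
        s = summarize_activity(build_trials(make_log(rows)))
        assert (s.total_activity, s.omissions, s.prematures) == (12, 3, 2)
        assert s.pct_omission == pytest.approx(25.0)
        assert s.pct_premature == pytest.approx(100 * 2 / 12)

    def test_zero_activity_percentages_undefined(self):
        s = summarize_activity(build_trials(
            make_log(visit_rows("ratA", "2024-03-01T16:10:00", 2.5, []))))
        assert s.omissions == 1 and np.isnan(s.pct_omission)

    def test_omission_rate_within_binomial_band(self):
        """Generator's omission probability recovered within a 99.9% binomial CI."""
        cfg = SimulationConfig(n_animals=1, omission_prob=0.15, premature_prob=0.0,
                               visit_rate_cv=0.0)
        log, _ = simulate_cohort(cfg, seed=5)
        trials = build_trials(pool_condition_days(log, "saline"))
        n = len(trials)
        k = sum(t.classification == "omission" for t in trials)
        lo, hi = stats.binom.interval(0.999, n, 0.15)
        assert lo <= k <= hi


class TestLearningCriterion:
    def _anchor_trials(self, n_ok_1, n_bad_1, n_ok_4, n_bad_4):
        rows, t = [], 0
        specs = ([(1.0, "left")] * n_ok_1 + [(1.0, "right")] * n_bad_1
                 + [(4.0, "right")] * n_ok_4 + [(4.0, "left")] * n_bad_4)
        for dur, side in specs:
            rows += visit_rows("ratA", f"2024-03-01T{16 + t // 60}:{t % 60:02d}:00",
                               dur, [(dur + 0.3, side)])
            t += 1
        return build_trials(make_log(rows))

    def test_criterion_met_at_threshold(self):
        chk = check_learning_criterion(self._anchor_trials(8, 2, 9, 1))
        assert chk.per_anchor_error_pct[1.0] == pytest.approx(20.0)
        assert chk.per_anchor_error_pct[4.0] == pytest.approx(10.0)
        assert chk.overall_met

    def test_chance_performance_fails(self):
        chk = check_learning_criterion(self._anchor_trials(5, 5, 5, 5))
        assert not chk.overall_met

    def test_pooled_criterion_can_mask_one_anchor(self):
        # 4 s errors at 30% but pooled only 20%: pooled passes, per-anchor fails
        chk = check_learning_criterion(self._anchor_trials(63, 7, 49, 21))
        assert chk.pooled_met
        assert not chk.per_anchor_met[4.0]
        assert not chk.overall_met

    def test_no_anchor_trials_flagged(self):
        trials = build_trials(make_log(
            visit_rows("ratA", "2024-03-01T16:10:00", 2.5, [(3.0, "left")])))
        chk = check_learning_criterion(trials)
        assert np.isnan(chk.pooled_error_pct) and not chk.overall_met
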