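"""Behavioural measures against hand-computed values on the fixture log."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rewritelab.fixtures import fixture_graph, three_participant_trials
from rewritelab.metrics import (
    WMOutcome,
    apply_exclusions,
    between_rule_times,
    block_solution_table,
    cursor_speed,
    extract_attempts,
    optimality_stats,
    strategy_weights,
    trials_from_jsonl,
    trials_to_jsonl,
    wm_correctness,
    wm_score,
)


@pytest.fixture(scope="module")
def fixture_trials():
    return three_participant_trials()


@pytest.fixture(scope="module")
def fixture_graphs():
    g = fixture_graph()
    return {("ABC", "XYZ"): g}


class TestExtractAttempts:
    def test_counts_and_validity(self, fixture_trials):
        t1, t2, t3 = fixture_trials
        a1 = extract_attempts(t1)
        assert [a.valid for a in a1] == [True, True, True]
        assert a1[0].t_start == 1.0 and a1[0].t_end == 1.5
        a2 = extract_attempts(t2)
        assert [a.valid for a in a2] == [True, True, False, True, True, True]
        a3 = extract_attempts(t3)
        assert [a.valid for a in a3] == [False, True]

    def test_either_order_pairs(self, fixture_trials):
        # f1's third attempt is symbol-then-rule
        a = extract_attempts(fixture_trials[0])[2]
        assert a.rule_id == 2 and a.position == 1 and a.valid

    def test_empty_event_list(self):
        from rewritelab.metrics import TrialRecord

        t = TrialRecord("x", 1, "t1", "A", "B", "F", [], solved=False)
        assert extract_attempts(t) == []

    def test_unpaired_activation_discarded_with_warning(self, caplog):
        from rewritelab.metrics import TrialEvent, TrialRecord

        t = TrialRecord(
            "x", 1, "t1", "AB", "BB", "F",
            [
                TrialEvent(1.0, "rule_activate", {"rule": 0}),
                TrialEvent(2.0, "rule_activate", {"rule": 1}),
                TrialEvent(2.5, "symbol_activate", {"position": 0}),
            ],
            solved=False,
        )
        with caplog.at_level("WARNING"):
            attempts = extract_attempts(t)
        assert len(attempts) == 1
        assert attempts[0].rule_id == 1
        assert "discarding" in caplog.text


class TestBetweenRuleTimes:
    def test_hand_computed_gaps(self, fixture_trials):
        t1, t2, t3 = fixture_trials
        assert between_rule_times(t1) == pytest.approx([2.5, 1.6])
        assert between_rule_times(t2) == pytest.approx([2.5, 2.5, 1.5, 1.6, 1.5])
        assert between_rule_times(t3) == pytest.approx([2.5])

    def test_single_attempt_yields_empty(self):
        from rewritelab.metrics import TrialEvent, TrialRecord

        t = TrialRecord(
            "x", 1, "t1", "AB", "BB", "F",
            [
                TrialEvent(1.0, "rule_activate", {"rule": 0}),
                TrialEvent(1.5, "symbol_activate", {"position": 0}),
            ],
            solved=False,
        )
        assert between_rule_times(t) == []

    def test_end_to_end_convention(self, fixture_trials):
        assert between_rule_times(fixture_trials[0], "end_to_end") == pytest.approx(
            [2.9, 2.1]
        )


class TestCursorSpeed:
    def test_hand_computed_speeds(self, fixture_trials):
        t1, t2, t3 = fixture_trials
        # f1: 500/0.5, 200/0.4, 300/0.5 -> mean of 1000, 500, 600
        assert cursor_speed(t1) == pytest.approx((1000 + 500 + 600) / 3)
        # f2: 1000, 1000, 600, 750, 1000, 1000
        assert cursor_speed(t2) == pytest.approx((1000 + 1000 + 600 + 750 + 1000 + 1000) / 6)
        assert cursor_speed(t3) == pytest.approx(1000.0)


class TestOptimality:
    def test_minimal_distance_mode_hand_trace(self, fixture_trials, fixture_graphs):
        df = optimality_stats(fixture_trials, fixture_graphs, "minimal_distance")
        get = lambda p, d: df[
            (df.participant == p) & (df.distance == d)
        ].iloc[0]
        # f1 solves minimally: optimal at distances 3, 2, 1
        for d in (1, 2, 3):
            assert get("f1", d).proportion == 1.0
        # f2's first visit to ABC (5 moves remaining vs distance 3) is not optimal
        assert get("f2", 3).n == 2 and get("f2", 3).n_optimal == 1
        # the detour state WBC is 4 from goal, and f2 returns in exactly 4
        assert get("f2", 4).proportion == 1.0
        # unsolved f3 contributes nothing in this mode
        assert "f3" not in set(df.participant)

    def test_median_group_mode_hand_trace(self, fixture_trials, fixture_graphs):
        df = optimality_stats(fixture_trials, fixture_graphs, "median_group")
        get = lambda p, d: df[
            (df.participant == p) & (df.distance == d)
        ].iloc[0]
        # f1: observed lengths 3,2,1 against medians 3,2,1
        for d in (1.0, 2.0, 3.0):
            assert get("f1", d).proportion == 1.0
        # f2: states in the median-3 group are visited 3 times; only the
        # third (2 + invalid = 3 attempts remaining... ) meets the median
        assert get("f2", 3.0).n == 3 and get("f2", 3.0).n_optimal == 1
        assert get("f2", 4.0).proportion == 0.0  # 5 attempts remaining from WBC
        # f3 is unsolved: every visited state counts as a failure
        assert get("f3", 3.0).n == 2 and get("f3", 3.0).n_optimal == 0


class TestStrategyWeights:
    def test_symmetric_input_gives_equal_thirds(self):
        rep = strategy_weights(0.5, 0.5, 0.5)
        assert rep.w_t == pytest.approx(1 / 3)
        assert rep.w_w == pytest.approx(1 / 3)
        assert rep.w_i == pytest.approx(1 / 3)

    def test_worked_example(self):
        rep = strategy_weights(2 / 3, 1 / 2, 0.5)
        assert rep.w_t == pytest.approx(0.5)
        assert rep.w_w == pytest.approx(0.25)
        assert rep.w_i == pytest.approx(0.25)

    @given(
        st.floats(0.01, 0.99), st.floats(0.01, 0.99), st.floats(0.01, 0.99)
    )
    @settings(max_examples=200, deadline=None)
    def test_weights_sum_to_one_and_ignore_z(self, x, y, z):
        rep = strategy_weights(x, y, z)
        assert rep.w_t + rep.w_w + rep.w_i == pytest.approx(1.0, abs=1e-9)
        rep2 = strategy_weights(x, y, 1.0 - z)
        assert (rep.w_t, rep.w_w, rep.w_i) == (rep2.w_t, rep2.w_w, rep2.w_i)

    def test_extreme_inputs_clamped(self):
        rep = strategy_weights(0.0, 1.0, 0.5)
        assert rep.x == 0.01 and rep.y == 0.99
        assert 0 <= rep.w_t <= 1


class TestWorkingMemory:
    def test_correctness_right_aligned(self):
        oc = WMOutcome(sequence="123456", response="456")
        assert wm_correctness(oc).tolist() == [1, 1, 1, 0, 0, 0]
        oc2 = WMOutcome(sequence="123456", response="956")
        assert wm_correctness(oc2).tolist() == [1, 1, 0, 0, 0, 0]

    def test_analytic_crossing_recovered(self):
        # construct outcomes whose fitted curve must cross 1/9 near offset 5:
        # deterministic correctness 1 for offsets 0-4, 0 for 5+ puts the
        # steep crossing between 4 and 5
        seqs = ["123456789124" for _ in range(12)]
        outcomes = [
            WMOutcome(sequence=s, response=s[-5:]) for s in seqs
        ]
        score, flagged = wm_score(outcomes)
        assert not flagged
        assert 5.0 <= score <= 6.5

    def test_perfect_final_three_responder(self):
        seqs = [
            "124961245793", "215721583964", "183462951785", "294784216392",
        ] * 3
        outcomes = [WMOutcome(sequence=s, response=s[-3:]) for s in seqs]
        score, _ = wm_score(outcomes)
        assert 3.0 <= score <= 4.5

    def test_all_wrong_scores_one(self):
        # the sequence contains no "8", so every typed digit is wrong
        outcomes = [
            WMOutcome(sequence="124961245793", response="888888888888")
        ] * 3
        score, flagged = wm_score(outcomes)
        assert score == 1.0 and flagged

    def test_all_correct_scores_ceiling(self):
        s = "124961245793"
        score, flagged = wm_score([WMOutcome(sequence=s, response=s)] * 3)
        assert score == float(len(s)) and flagged


class TestExclusions:
    def _wm_good(self):
        s = "124961245793"
        return [WMOutcome(sequence=s, response=s[-6:])] * 5

    def _wm_bad(self):
        s = "124961245793"
        return [WMOutcome(sequence=s, response="888888")] * 5

    def _trial(self, p, session, solved):
        from rewritelab.metrics import TrialRecord

        return TrialRecord(p, session, "t1", "A", "B", "F", [], solved=solved)

    def test_zero_solves_in_one_session_excludes(self):
        trials = [self._trial("p", s, s != 3) for s in range(1, 5)]
        wm = {("p", s): self._wm_good() for s in range(1, 5)}
        included, report = apply_exclusions(trials, wm)
        assert included == set()
        assert report.iloc[0].reason == "no_solve_in_session"

    def test_chance_wm_excludes(self):
        trials = [self._trial("p", s, True) for s in range(1, 5)]
        wm = {("p", s): self._wm_bad() for s in range(1, 5)}
        included, report = apply_exclusions(trials, wm)
        assert included == set()
        assert report.iloc[0].reason == "wm_at_chance"

    def test_missing_session_is_incomplete(self):
        trials = [self._trial("p", s, True) for s in range(1, 4)]
        wm = {("p", s): self._wm_good() for s in range(1, 4)}
        included, report = apply_exclusions(trials, wm)
        assert report.iloc[0].reason == "incomplete"

    def test_capable_participant_included(self):
        trials = [self._trial("p", s, True) for s in range(1, 5)]
        wm = {("p", s): self._wm_good() for s in range(1, 5)}
        included, _ = apply_exclusions(trials, wm)
        assert included == {"p"}


def test_block_solution_table(fixture_trials):
    df = block_solution_table(fixture_trials)
    assert len(df) == 3
    row = df[df.participant == "f1"].iloc[0]
    assert row.solved_proportion == 1.0
    assert row.mean_between_rule_time == pytest.approx(2.05)
    assert df.n_trials.sum() == 3


def test_jsonl_round_trip(fixture_trials):
    text = trials_to_jsonl(fixture_trials)
    back = trials_from_jsonl(text)
    assert back == fixture_trials
    # and measures survive the round trip exactly
    assert between_rule_times(back[0]) == between_rule_times(fixture_trials[0])
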