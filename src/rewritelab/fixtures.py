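"""A small synthetic, hand-traceable event-log fixture.

Three participants work on the same linear-chain task ``ABC -> XYZ`` under a
five-rule system in which the only solution path is
``ABC -> XBC -> XYC -> XYZ`` with a recoverable detour through ``WBC``:

    r0: A -> X      r1: XB -> XY    r2: YC -> YZ
    r3: A -> W      r4: W -> A      (detour and its undo)

Participant f1 solves minimally; f2 takes the W detour and one invalid
attempt before solving; f3 makes one invalid and one valid attempt and times
out.  Every timestamp, coordinate and outcome is chosen so the behavioural
measures can be verified by hand — the expected values live next to the
tests that assert them.  This module is synthetic demonstration data, not
study material.
"""

from __future__ import annotations

from rewritelab.engine import Ruleset, StateGraph, enumerate_state_graph
from rewritelab.metrics import TrialEvent, TrialRecord

__all__ = ["fixture_ruleset", "fixture_graph", "three_participant_trials"]


def fixture_ruleset() -> Ruleset:
    return Ruleset.from_pairs(
        [("A", "X"), ("XB", "XY"), ("YC", "YZ"), ("A", "W"), ("W", "A")],
        id="F",
    )


def fixture_graph() -> StateGraph:
    return enumerate_state_graph("ABC", "XYZ", fixture_ruleset())


def _attempt(t1, kind1, payload1, t2, kind2, payload2, new_state=None, t_sc=None):
    events = [TrialEvent(t1, kind1, payload1), TrialEvent(t2, kind2, payload2)]
    if new_state is not None:
        events.append(TrialEvent(t_sc, "state_change", {"state": new_state}))
    return events


def three_participant_trials() -> list[TrialRecord]:
    """The three fixture trials, all in training block t1 of session 1."""
    rule = lambda r, x, y: {"rule": r, "x": x, "y": y}
    sym = lambda p, x, y: {"position": p, "x": x, "y": y}

    # f1: minimal 3-step solve; speeds 1000, 500, 600 px/s; gaps 2.5, 1.6 s
    ev1 = (
        _attempt(1.0, "rule_activate", rule(0, 0, 0),
                 1.5, "symbol_activate", sym(0, 300, 400), "XBC", 1.52)
        + _attempt(4.0, "rule_activate", rule(1, 0, 0),
                   4.4, "symbol_activate", sym(0, 200, 0), "XYC", 4.42)
        + _attempt(6.0, "symbol_activate", sym(1, 100, 100),
                   6.5, "rule_activate", rule(2, 100, 400), "XYZ", 6.52)
    )
    t1 = TrialRecord("f1", 1, "t1", "ABC", "XYZ", "F", ev1,
                     solved=True, steps=3, score=228, min_solution_length=3)

    # f2: detour through WBC and back, one invalid attempt, then solves
    ev2 = (
        _attempt(2.0, "rule_activate", rule(3, 0, 0),
                 2.5, "symbol_activate", sym(0, 300, 400), "WBC", 2.52)
        + _attempt(5.0, "rule_activate", rule(4, 0, 0),
                   5.5, "symbol_activate", sym(0, 300, 400), "ABC", 5.52)
        + _attempt(8.0, "rule_activate", rule(1, 0, 0),
                   8.5, "symbol_activate", sym(1, 0, 300))  # invalid: XB not at 1
        + _attempt(10.0, "rule_activate", rule(0, 0, 0),
                   10.4, "symbol_activate", sym(0, 300, 0), "XBC", 10.42)
        + _attempt(12.0, "rule_activate", rule(1, 0, 0),
                   12.5, "symbol_activate", sym(0, 300, 400), "XYC", 12.52)
        + _attempt(14.0, "rule_activate", rule(2, 0, 0),
                   14.5, "symbol_activate", sym(1, 300, 400), "XYZ", 14.52)
    )
    t2 = TrialRecord("f2", 1, "t1", "ABC", "XYZ", "F", ev2,
                     solved=True, steps=5, score=120, min_solution_length=3)

    # f3: one invalid and one valid attempt, then times out unsolved
    ev3 = (
        _attempt(3.0, "rule_activate", rule(1, 0, 0),
                 3.5, "symbol_activate", sym(2, 300, 400))  # invalid
        + _attempt(6.0, "rule_activate", rule(0, 0, 0),
                   6.5, "symbol_activate", sym(0, 300, 400), "XBC", 6.52)
    )
    t3 = TrialRecord("f3", 1, "t1", "ABC", "XYZ", "F", ev3,
                     solved=False, steps=1, score=0, min_solution_length=3)
    return [t1, t2, t3]
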