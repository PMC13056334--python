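"""Participant-level behavioural measures computed from trial event logs.

Covers attempt extraction from raw click/activation streams, between-rule
(decision) times, action-sequence optimality and efficiency, strategy-report
weight conversion, running-span working-memory scoring, cursor movement
speed, and the cohort exclusion filters.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, logit

from .engine import INFINITY, StateGraph, median_remaining_solution_length

logger = logging.getLogger(__name__)

__all__ = [
    "TrialEvent",
    "TrialRecord",
    "Attempt",
    "StrategyReport",
    "WMOutcome",
    "extract_attempts",
    "between_rule_times",
    "optimality_stats",
    "strategy_weights",
    "wm_correctness",
    "wm_score",
    "apply_exclusions",
    "cursor_speed",
    "block_solution_table",
    "trials_to_jsonl",
    "trials_from_jsonl",
]

WM_CHANCE = 1.0 / 9.0  # digits are drawn from "1".."9"

ACTIVATION_KINDS = {"rule_activate", "symbol_activate"}


@dataclass(frozen=True)
class TrialEvent:
    """One timestamped event within a trial.

    ``payload`` carries whichever of rule id, position, new state string, or
    screen coordinates applies to the event kind.
    """

    t: float
    kind: str
    payload: dict = field(default_factory=dict)


@dataclass
class TrialRecord:
    participant: str
    session: int
    block: str  # one of p1, t1..t6, p2
    start: str
    goal: str
    ruleset_id: str
    events: list[TrialEvent]
    solved: bool
    steps: int = 0
    score: int = 0
    min_solution_length: int = 0

    def state_sequence(self) -> list[str]:
        """States visited in order, applying state changes, undo and reset."""
        states = [self.start]
        history = [self.start]
        for ev in self.events:
            if ev.kind == "state_change":
                history.append(ev.payload["state"])
                states.append(ev.payload["state"])
            elif ev.kind == "undo" and len(history) > 1:
                history.pop()
                states.append(history[-1])
            elif ev.kind == "reset":
                history = [self.start]
                states.append(self.start)
        return states


@dataclass(frozen=True)
class Attempt:
    """A maximal rule-activation + symbol-activation pair, in either order."""

    rule_id: int
    position: int
    valid: bool
    t_start: float
    t_end: float
    xy_start: tuple[float, float] | None = None
    xy_end: tuple[float, float] | None = None


def extract_attempts(trial: TrialRecord) -> list[Attempt]:
    """Parse the event stream into rule-application attempts.

    An attempt is a rule activation and a state-symbol activation in either
    order; the task software applies the rule (emitting a ``state_change``
    when valid) as soon as the pair completes.  A repeated activation of the
    same kind before the pair completes discards the earlier event, with a
    warning, mirroring re-selection in the interface.
    """
    attempts: list[Attempt] = []
    pending: TrialEvent | None = None
    awaiting_change: list[TrialEvent] | None = None

    def close(valid: bool) -> None:
        nonlocal awaiting_change
        if awaiting_change is None:
            return
        first, second = awaiting_change
        rid = first.payload.get("rule", second.payload.get("rule"))
        pos = first.payload.get("position", second.payload.get("position"))
        attempts.append(
            Attempt(
                rule_id=rid,
                position=pos,
                valid=valid,
                t_start=first.t,
                t_end=second.t,
                xy_start=_xy(first),
                xy_end=_xy(second),
            )
        )
        awaiting_change = None

    for ev in trial.events:
        if ev.kind in ACTIVATION_KINDS:
            close(valid=False)
            if pending is None:
                pending = ev
            elif pending.kind == ev.kind:
                logger.warning(
                    "trial %s/%s: discarding unpaired %s at t=%.3f",
                    trial.participant, trial.block, pending.kind, pending.t,
                )
                pending = ev
            else:
                awaiting_change = [pending, ev]
                pending = None
        elif ev.kind == "state_change":
            close(valid=True)
        elif ev.kind in ("undo", "reset"):
            close(valid=False)
            pending = None
    close(valid=False)
    if pending is not None:
        logger.warning(
            "trial %s/%s: discarding unpaired %s at t=%.3f",
            trial.participant, trial.block, pending.kind, pending.t,
        )
    return attempts


def _xy(ev: TrialEvent) -> tuple[float, float] | None:
    if "x" in ev.payload and "y" in ev.payload:
        return (float(ev.payload["x"]), float(ev.payload["y"]))
    return None


def between_rule_times(
    trial: TrialRecord, convention: str = "gap"
) -> list[float]:
    """Times separating consecutive attempts within a trial.

    ``gap`` (default): start of attempt k+1 minus end of attempt k — the idle
    time between completed attempts.  ``end_to_end``: end-to-end differences
    between consecutive attempts.  Fewer than two attempts yields ``[]``.
    """
    attempts = extract_attempts(trial)
    if len(attempts) < 2:
        return []
    if convention == "gap":
        return [
            b.t_start - a.t_end for a, b in zip(attempts, attempts[1:])
        ]
    if convention == "end_to_end":
        return [b.t_end - a.t_end for a, b in zip(attempts, attempts[1:])]
    raise ValueError(f"unknown convention {convention!r}")


def mean_between_rule_time(trial: TrialRecord, convention: str = "gap") -> float:
    times = between_rule_times(trial, convention)
    return float(np.mean(times)) if times else float("nan")


def optimality_stats(
    trials: Iterable[TrialRecord],
    graphs: dict[tuple[str, str], StateGraph],
    mode: str = "minimal_distance",
) -> pd.DataFrame:
    """Per participant x block x distance table of action-sequence optimality.

    ``graphs`` maps (start, goal) to the task's state graph.

    minimal_distance: for every state visited in *solved* trials, scores
    whether the number of successful applications remaining to the solve
    equals the state's distance to goal; rows are keyed by that distance.

    median_group: for every visited state, the group key is the median length
    of all acyclic solution paths from it; the observed length counts valid
    and invalid attempts (undo/reset ignored) from the state to the end of
    the trial, and is scored against the group median.  Unsolved trials count
    every visited state as a failure.
    """
    rows: list[dict] = []
    for trial in trials:
        graph = graphs[(trial.start, trial.goal)]
        if mode == "minimal_distance":
            if not trial.solved:
                continue
            states = _states_at_valid_applications(trial)
            n = len(states)  # number of valid applications == solution length
            for k, s in enumerate(states):
                remaining = n - k
                d = graph.distance(s)
                if d == INFINITY:
                    continue
                rows.append(
                    {
                        "participant": trial.participant,
                        "block": trial.block,
                        "distance": int(d),
                        "optimal": int(remaining == d),
                    }
                )
        elif mode == "median_group":
            attempts = extract_attempts(trial)
            states = _states_at_attempts(trial, attempts)
            n_att = len(attempts)
            # attempts remaining from each attempt index to the end of trial
            for k, s in enumerate(states):
                med = median_remaining_solution_length(s, graph)
                if med == INFINITY:
                    continue
                observed = n_att - k
                ok = trial.solved and observed <= med
                rows.append(
                    {
                        "participant": trial.participant,
                        "block": trial.block,
                        "distance": med,
                        "optimal": int(ok),
                    }
                )
        else:
            raise ValueError(f"unknown mode {mode!r}")
    if not rows:
        return pd.DataFrame(
            columns=["participant", "block", "distance", "n", "n_optimal", "proportion"]
        )
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["participant", "block", "distance"])["optimal"]
        .agg(n="count", n_optimal="sum")
        .reset_index()
    )
    out["proportion"] = out["n_optimal"] / out["n"]
    return out


def _states_at_valid_applications(trial: TrialRecord) -> list[str]:
    """The state occupied before each successful rule application."""
    states = []
    current = trial.start
    history = [trial.start]
    for ev in trial.events:
        if ev.kind == "state_change":
            states.append(current)
            current = ev.payload["state"]
            history.append(current)
        elif ev.kind == "undo" and len(history) > 1:
            history.pop()
            current = history[-1]
        elif ev.kind == "reset":
            history = [trial.start]
            current = trial.start
    return states


def _states_at_attempts(trial: TrialRecord, attempts: list[Attempt]) -> list[str]:
    """The state occupied at the start of each attempt (valid or invalid)."""
    states = []
    current = trial.start
    history = [trial.start]
    it = iter(attempts)
    next_attempt = next(it, None)
    for ev in trial.events:
        while next_attempt is not None and next_attempt.t_start <= ev.t and (
            next_attempt.t_start < ev.t or ev.kind in ACTIVATION_KINDS
        ):
            states.append(current)
            next_attempt = next(it, None)
        if ev.kind == "state_change":
            current = ev.payload["state"]
            history.append(current)
        elif ev.kind == "undo" and len(history) > 1:
            history.pop()
            current = history[-1]
        elif ev.kind == "reset":
            history = [trial.start]
            current = trial.start
    while next_attempt is not None:
        states.append(current)
        next_attempt = next(it, None)
    return states


@dataclass(frozen=True)
class StrategyReport:
    """Pairwise strategy preferences and the derived per-strategy weights.

    ``x``: preference for try-and-see over work-it-out; ``y``: work-it-out
    over intuition; ``z``: intuition over try-and-see.  ``z`` enters the
    definitions but not the conversion formulae; the weights are invariant
    to it (its role in the survey is a consistency check).
    """

    x: float
    y: float
    z: float
    w_t: float  # try-and-see
    w_w: float  # work-it-out
    w_i: float  # intuition


def strategy_weights(x: float, y: float, z: float = 0.5) -> StrategyReport:
    """Convert pairwise preferences into weights summing to 1.

    Inputs of exactly 0 or 1 are clamped to 0.01 / 0.99 (the conversion
    assumes non-extreme preferences) and logged.
    """
    cx, cy, cz = (min(max(v, 0.01), 0.99) for v in (x, y, z))
    if (cx, cy, cz) != (x, y, z):
        logger.info("strategy preferences clamped: (%s, %s, %s)", x, y, z)
    w_t = cx * cy / (1.0 - cx + cx * cy)
    w_w = w_t * (1.0 - cx) / cx
    w_i = w_w * (1.0 - cy) / cy
    return StrategyReport(cx, cy, cz, w_t, w_w, w_i)


@dataclass(frozen=True)
class WMOutcome:
    """One running-span trial: the shown digit sequence and the typed response."""

    sequence: str
    response: str


def wm_correctness(outcome: WMOutcome) -> np.ndarray:
    """Per-offset correctness, offset 0 being the final digit of the sequence.

    The typed response is right-aligned against the sequence tail: the k-th
    digit from the end of the response is compared with the k-th digit from
    the end of the sequence; offsets the response does not cover are wrong.
    """
    n = len(outcome.sequence)
    out = np.zeros(n, dtype=int)
    for o in range(n):
        if o < len(outcome.response) and (
            outcome.response[-1 - o] == outcome.sequence[-1 - o]
        ):
            out[o] = 1
    return out


def _fit_recall_curve(outcomes: list[WMOutcome]) -> tuple[float, float, bool]:
    """Binomial-regression fit of recall on offset: (beta0, beta1, degenerate)."""
    offs, correct = [], []
    for oc in outcomes:
        c = wm_correctness(oc)
        offs.extend(range(len(c)))
        correct.extend(c.tolist())
    y = np.array(correct, dtype=float)
    X = sm.add_constant(np.array(offs, dtype=float))
    if y.all() or not y.any():
        return (math.inf if y.all() else -math.inf), 0.0, True
    try:
        import warnings

        from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        b0, b1 = (float(v) for v in res.params)
        if not (math.isfinite(b0) and math.isfinite(b1)):
            raise ValueError("diverged")
        return b0, b1, False
    except Exception:
        from sklearn.linear_model import LogisticRegression

        clf = LogisticRegression(C=1e6, max_iter=2000)
        clf.fit(X[:, 1:], y)
        return float(clf.intercept_[0]), float(clf.coef_[0][0]), False


def wm_score(outcomes: list[WMOutcome]) -> tuple[float, bool]:
    """Working-memory score for one participant-session: (score, flagged).

    Fits recall probability as a logistic function of offset and finds the
    offset ``o*`` where the curve crosses chance (1/9); the score is
    ``clamp(o*, 0, max offset) + 1``.  Degenerate fits are flagged: a
    non-decreasing curve or all-correct responses score ``max offset + 1``;
    all-wrong responses score 1.
    """
    if not outcomes:
        raise ValueError("need at least one outcome")
    max_offset = max(len(oc.sequence) for oc in outcomes) - 1
    b0, b1, degenerate = _fit_recall_curve(outcomes)
    if degenerate:
        return (float(max_offset + 1), True) if b0 > 0 else (1.0, True)
    if b1 >= 0:
        return float(max_offset + 1), True
    o_star = (logit(WM_CHANCE) - b0) / b1
    return float(min(max(o_star, 0.0), max_offset) + 1.0), False


def offset0_recall_probability(outcomes: list[WMOutcome]) -> float:
    """Fitted probability of recalling the final digit (offset 0)."""
    b0, _b1, degenerate = _fit_recall_curve(outcomes)
    if degenerate:
        return 1.0 if b0 > 0 else 0.0
    return float(expit(b0))


def apply_exclusions(
    trials: Iterable[TrialRecord],
    wm: dict[tuple[str, int], list[WMOutcome]],
    n_sessions: int = 4,
) -> tuple[set[str], pd.DataFrame]:
    """Apply the cohort exclusion criteria; return (included ids, report).

    A participant is kept only if, in every session, they solved at least one
    problem-solving trial and their fitted probability of recalling the final
    working-memory digit exceeds chance (1/9).  Participants with missing
    sessions are excluded with reason "incomplete".
    """
    solved: dict[tuple[str, int], int] = {}
    participants: set[str] = set()
    for tr in trials:
        participants.add(tr.participant)
        key = (tr.participant, tr.session)
        solved[key] = solved.get(key, 0) + int(tr.solved)
    participants |= {p for p, _s in wm}
    rows = []
    included: set[str] = set()
    for p in sorted(participants):
        sessions = range(1, n_sessions + 1)
        missing = [s for s in sessions if (p, s) not in solved or (p, s) not in wm]
        if missing:
            rows.append({"participant": p, "included": False, "reason": "incomplete"})
            continue
        if any(solved[(p, s)] == 0 for s in sessions):
            rows.append(
                {"participant": p, "included": False, "reason": "no_solve_in_session"}
            )
            continue
        if any(
            offset0_recall_probability(wm[(p, s)]) <= WM_CHANCE for s in sessions
        ):
            rows.append(
                {"participant": p, "included": False, "reason": "wm_at_chance"}
            )
            continue
        included.add(p)
        rows.append({"participant": p, "included": True, "reason": ""})
    return included, pd.DataFrame(rows)


def cursor_speed(trial: TrialRecord) -> float:
    """Mean cursor speed (pixels/second) over the trial's attempts.

    Movements are taken as straight lines between the two click coordinates
    of each attempt; attempts with missing coordinates or a zero time delta
    are skipped (the latter with a warning).
    """
    speeds = []
    for a in extract_attempts(trial):
        if a.xy_start is None or a.xy_end is None:
            continue
        dt = a.t_end - a.t_start
        if dt <= 0:
            logger.warning("zero time delta between paired clicks; attempt skipped")
            continue
        dist = math.hypot(
            a.xy_end[0] - a.xy_start[0], a.xy_end[1] - a.xy_start[1]
        )
        speeds.append(dist / dt)
    return float(np.mean(speeds)) if speeds else float("nan")


def block_solution_table(trials: Iterable[TrialRecord]) -> pd.DataFrame:
    """Tidy per participant x block summary of basic trial measures."""
    rows = [
        {
            "participant": tr.participant,
            "session": tr.session,
            "block": tr.block,
            "solved": int(tr.solved),
            "steps": tr.steps,
            "score": tr.score,
            "mean_between_rule_time": mean_between_rule_time(tr),
            "cursor_speed": cursor_speed(tr),
        }
        for tr in trials
    ]
    df = pd.DataFrame(rows)
    return (
        df.groupby(["participant", "session", "block"])
        .agg(
            n_trials=("solved", "count"),
            n_solved=("solved", "sum"),
            solved_proportion=("solved", "mean"),
            mean_between_rule_time=("mean_between_rule_time", "mean"),
            mean_cursor_speed=("cursor_speed", "mean"),
            mean_score=("score", "mean"),
        )
        .reset_index()
    )


# ---------------------------------------------------------------------------
# JSON-Lines event-log interchange


def trials_to_jsonl(trials: Iterable[TrialRecord]) -> str:
    lines = []
    for tr in trials:
        lines.append(
            json.dumps(
                {
                    "participant": tr.participant,
                    "session": tr.session,
                    "block": tr.block,
                    "task": {
                        "start": tr.start,
                        "goal": tr.goal,
                        "ruleset_id": tr.ruleset_id,
                        "min_solution_length": tr.min_solution_length,
                    },
                    "events": [
                        {"t": ev.t, "kind": ev.kind, **ev.payload}
                        for ev in tr.events
                    ],
                    "solved": tr.solved,
                    "steps": tr.steps,
                    "score": tr.score,
                }
            )
        )
    return "\n".join(lines) + "\n"


def trials_from_jsonl(text: str) -> list[TrialRecord]:
    trials = []
    for line in text.splitlines():
        if not line.strip():
            continue
        obj = json.loads(line)
        events = [
            TrialEvent(
                t=e["t"],
                kind=e["kind"],
                payload={k: v for k, v in e.items() if k not in ("t", "kind")},
            )
            for e in obj["events"]
        ]
        trials.append(
            TrialRecord(
                participant=obj["participant"],
                session=obj["session"],
                block=obj["block"],
                start=obj["task"]["start"],
                goal=obj["task"]["goal"],
                ruleset_id=obj["task"]["ruleset_id"],
                min_solution_length=obj["task"].get("min_solution_length", 0),
                events=events,
                solved=obj["solved"],
                steps=obj.get("steps", 0),
                score=obj.get("score", 0),
            )
        )
    return trials
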