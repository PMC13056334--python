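"""Synthetic study cohorts: agents, sessions, event logs, surveys, span trials.

The simulator emulates the longitudinal transfer-study design this package
analyses: four sessions, each with two 12-trial problem-solving blocks and a
20-trial running-span block; one probe block before training (p1) and one
after (p2) drawn from the untrained taskset, with six training blocks
(t1..t6) covering all 72 trained tasks once.

Two agent mechanisms operationalise the competing accounts of problem-solving
skill.  *Associative* agents learn strengths over (rule, local-pattern)
associations — reusable within a ruleset but meaningless for a different
one.  *Heuristic* agents score candidate next states with the logistic
state-value model over the 13 rule-independent features and can carry the
learned coefficients across tasksets when transfer is enabled.  The two
regimes let the full analysis pipeline be exercised under both a
transfer-present and a transfer-absent ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from random import Random

import numpy as np
from scipy.special import expit

from .engine import Ruleset, StateGraph
from .features import FEATURE_NAMES, compute_features
from .metrics import StrategyReport, TrialEvent, TrialRecord, WMOutcome
from .taskgen import TRIAL_TIME_LIMIT, Task, Taskset, task_graph, trial_score

__all__ = [
    "AgentProfile",
    "StudyDesign",
    "CohortDataset",
    "make_digit_sequence",
    "check_digit_sequence",
    "simulate_trial",
    "simulate_cohort",
    "default_profiles",
]


@dataclass
class AgentProfile:
    """Parameters of one simulated participant.

    ``mechanism`` selects the decision policy: ``associative`` (pattern ->
    action strengths), ``heuristic`` (state-value scoring of successors), or
    ``mixture`` (per-decision coin flip with ``mixture_weight`` on the
    heuristic policy).  ``value_betas`` holds the 14 coefficients (intercept
    first) of the state-value model the heuristic policy starts from.
    Decision times are log-normal with a location that declines linearly per
    cumulative attempt (practice speeds decisions); ``wm_capacity`` is the
    offset at which running-span recall has fallen halfway to floor.
    """

    id: str
    mechanism: str = "heuristic"
    learning_rate: float = 0.25
    softmax_temperature: float = 0.35
    value_betas: np.ndarray = field(
        default_factory=lambda: np.zeros(len(FEATURE_NAMES) + 1)
    )
    mixture_weight: float = 0.5
    decision_time_loc: float = math.log(2.2)
    decision_time_scale: float = 0.45
    # per-attempt decline of the log decision time; the default compounds to
    # roughly a 45% speed-up across a four-session study (~1,500 attempts),
    # the magnitude of the preparation-time practice effect the design targets
    practice_decay: float = 0.0004
    min_decision_time: float = 0.35
    error_rate: float = 0.08
    search_depth: int = 1
    learn_epochs: int = 1  # replay passes over a trial's visited states
    wm_capacity: float = 5.0
    strategy_bias: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def copy(self) -> "AgentProfile":
        return replace(self, value_betas=self.value_betas.copy())


@dataclass(frozen=True)
class StudyDesign:
    """The session/block schedule of the study."""

    n_sessions: int = 4
    blocks_per_session: int = 2
    trials_per_block: int = 12
    wm_trials_per_session: int = 20

    def block_labels(self) -> list[tuple[int, str]]:
        """(session, label) pairs in chronological order: p1, t1..t6, p2."""
        labels = ["p1"] + [f"t{i}" for i in range(1, 7)] + ["p2"]
        out = []
        i = 0
        for session in range(1, self.n_sessions + 1):
            for _ in range(self.blocks_per_session):
                out.append((session, labels[i]))
                i += 1
        return out


# ---------------------------------------------------------------------------
# running-span digit sequences


def check_digit_sequence(seq: str) -> list[str]:
    """Independent checker of the three sequence constraints; returns violations."""
    problems = []
    digits = [int(c) for c in seq]
    for d in set(digits):
        if digits.count(d) > 3:
            problems.append(f"digit {d} appears more than three times")
    for i in range(len(digits)):
        window = digits[i : i + 6]
        for d in set(window):
            if window.count(d) > 2:
                problems.append(f"digit {d} repeated more than once in a window of six")
    for a, b in zip(digits, digits[1:]):
        if abs(a - b) == 1:
            problems.append(f"adjacent digits {a},{b} are numerically consecutive")
    return problems


def make_digit_sequence(length: int, rng: Random, max_restarts: int = 500) -> str:
    """A running-span sequence of ``length`` digits from 1-9 meeting all constraints.

    Constraints: no digit more than three times overall, no digit more than
    twice in any window of six, and no numerically consecutive neighbours
    (in either direction).  Built digit-by-digit with restarts.
    """
    if not 12 <= length <= 21:
        raise ValueError("sequence length must lie in [12, 21]")
    for _ in range(max_restarts):
        seq: list[int] = []
        ok = True
        for _i in range(length):
            cands = [
                d
                for d in range(1, 10)
                if seq.count(d) < 3
                and seq[-5:].count(d) < 2
                and (not seq or abs(seq[-1] - d) != 1)
            ]
            if not cands:
                ok = False
                break
            seq.append(rng.choice(cands))
        if ok:
            return "".join(str(d) for d in seq)
    raise RuntimeError(f"could not build a valid sequence of length {length}")


# ---------------------------------------------------------------------------
# trial simulation


@lru_cache(maxsize=200_000)
def _value_features(state: str, goal: str) -> np.ndarray:
    f = compute_features(state, goal)
    return np.array([1.0] + [f[k] for k in FEATURE_NAMES])


def _pattern_key(state: str, rule_lhs_len: int, pos: int, rid: int) -> tuple:
    """Local-context key for associative strengths: rule + flanking symbols."""
    left = state[pos - 1 : pos]
    right = state[pos + rule_lhs_len : pos + rule_lhs_len + 1]
    return (rid, left, right)


class _AgentState:
    """Mutable learning state of one agent across the study.

    Attempt counters are kept per ruleset: the decision-time practice effect
    is specific to the rule material being considered, so probe blocks do
    not inherit the full speed-up accrued on the trained ruleset.
    """

    def __init__(self, profile: AgentProfile):
        self.profile = profile
        self.betas = profile.value_betas.copy()
        self.strengths: dict[tuple, float] = {}
        self.cum_attempts: dict[str, int] = {}

    def snapshot_betas(self) -> np.ndarray:
        return self.betas.copy()


def _lookahead_score(
    state: str,
    goal: str,
    graph: StateGraph,
    betas: np.ndarray,
    depth: int,
    step_penalty: float = 0.1,
) -> float:
    """Value of a candidate state with up to ``depth - 1`` further search steps.

    The heuristic-search account allows the solver to evaluate states a few
    steps ahead; the score of a state is the best value found in its search
    cone, minus a small per-step penalty so nearer high-value states win
    ties.  ``depth`` of 1 is plain one-step evaluation.
    """
    best = float(betas @ _value_features(state, goal))
    if depth <= 1 or state == goal:
        return best
    frontier = [state]
    for step in range(1, depth):
        nxt: list[str] = []
        for u in frontier:
            for _rid, _pos, v in graph.out_edges(u):
                nxt.append(v)
                val = float(betas @ _value_features(v, goal)) - step_penalty * step
                if val > best:
                    best = val
        frontier = nxt
        if not frontier:
            break
    return best


def _softmax_pick(scores: np.ndarray, temperature: float, rng: Random) -> int:
    z = scores / max(temperature, 1e-6)
    z = z - z.max()
    p = np.exp(z)
    p /= p.sum()
    u = rng.random()
    return int(np.searchsorted(np.cumsum(p), u))


def simulate_trial(
    agent: _AgentState | AgentProfile,
    task: Task,
    graph: StateGraph,
    rng: Random,
    participant: str = "sim",
    session: int = 1,
    block: str = "t1",
    betas_override: np.ndarray | None = None,
    learn: bool = True,
) -> TrialRecord:
    """Simulate one problem-solving trial, emitting a full event log.

    The agent repeatedly selects a (rule, position) action: the heuristic
    policy softmax-samples successors by their state-value score, the
    associative policy by learned pattern strengths.  Occasional invalid
    applications are attempted at ``error_rate``; a dead end triggers a
    reset.  Timestamps follow the log-normal decision-time model and the
    trial is truncated at the 75-second limit.  Click coordinates are
    synthesised from a fixed screen layout plus jitter.
    """
    state = agent if isinstance(agent, _AgentState) else _AgentState(agent)
    prof = state.profile
    betas = betas_override if betas_override is not None else state.betas
    rules = {r.id: r for r in graph.ruleset.rules}

    events: list[TrialEvent] = []
    t = 0.0
    current = task.start
    history = [current]
    visited = [current]
    steps = 0
    solved = False
    last_reset_index = 0
    path_actions: list[tuple] = []

    def click_xy(kind: str, idx: int) -> tuple[float, float]:
        if kind == "rule":
            base = (150.0, 200.0 + 60.0 * idx)
        else:
            base = (250.0 + 30.0 * idx, 520.0)
        return (base[0] + rng.gauss(0, 4), base[1] + rng.gauss(0, 4))

    while t < TRIAL_TIME_LIMIT:
        if current == task.goal:
            solved = True
            break
        actions = graph.out_edges(current)
        if not actions:
            t += 1.0
            if t >= TRIAL_TIME_LIMIT:
                break
            events.append(TrialEvent(round(t, 3), "reset"))
            current = task.start
            history = [current]
            last_reset_index = len(visited)  # everything before led to a dead end
            visited.append(current)
            continue

        loc = max(
            prof.decision_time_loc
            - prof.practice_decay * state.cum_attempts.get(task.ruleset_id, 0),
            math.log(prof.min_decision_time),
        )
        dt = math.exp(rng.gauss(loc, prof.decision_time_scale))
        t += max(dt, prof.min_decision_time)
        if t >= TRIAL_TIME_LIMIT:
            break

        if rng.random() < prof.error_rate:
            # a slip: attempt a rule at a position where it does not apply
            valid = {(rid, pos) for rid, pos, _v in actions}
            invalid = [
                (r.id, pos)
                for r in graph.ruleset.rules
                for pos in range(len(current))
                if (r.id, pos) not in valid
            ]
            if invalid:
                rid, pos = invalid[rng.randrange(len(invalid))]
                move = 0.2 + 0.4 * rng.random()
                x1, y1 = click_xy("rule", rid)
                x2, y2 = click_xy("symbol", pos)
                events.append(
                    TrialEvent(round(t, 3), "rule_activate",
                               {"rule": rid, "x": x1, "y": y1})
                )
                t += move
                events.append(
                    TrialEvent(round(t, 3), "symbol_activate",
                               {"position": pos, "x": x2, "y": y2})
                )
                state.cum_attempts[task.ruleset_id] = state.cum_attempts.get(task.ruleset_id, 0) + 1
                continue

        use_heuristic = prof.mechanism == "heuristic" or (
            prof.mechanism == "mixture" and rng.random() < prof.mixture_weight
        )
        if use_heuristic:
            scores = np.array(
                [
                    _lookahead_score(v, task.goal, graph, betas, prof.search_depth)
                    for _r, _p, v in actions
                ]
            )
        else:
            scores = np.array(
                [
                    state.strengths.get(
                        _pattern_key(current, len(rules[rid].lhs), pos, rid), 0.0
                    )
                    for rid, pos, _v in actions
                ]
            )
        k = _softmax_pick(scores, prof.softmax_temperature, rng)
        rid, pos, nxt = actions[k]

        move = 0.2 + 0.4 * rng.random()
        x1, y1 = click_xy("rule", rid)
        x2, y2 = click_xy("symbol", pos)
        order = rng.random() < 0.5  # rule first or symbol first
        first = TrialEvent(round(t, 3), "rule_activate" if order else "symbol_activate",
                           {"rule": rid, "x": x1, "y": y1} if order
                           else {"position": pos, "x": x2, "y": y2})
        t += move
        second = TrialEvent(round(t, 3), "symbol_activate" if order else "rule_activate",
                            {"position": pos, "x": x2, "y": y2} if order
                            else {"rule": rid, "x": x1, "y": y1})
        if t >= TRIAL_TIME_LIMIT:
            break
        events += [first, second]
        t += 0.02
        events.append(TrialEvent(round(t, 3), "state_change", {"state": nxt}))
        path_actions.append(
            (_pattern_key(current, len(rules[rid].lhs), pos, rid))
        )
        steps += 1
        state.cum_attempts[task.ruleset_id] = state.cum_attempts.get(task.ruleset_id, 0) + 1
        current = nxt
        history.append(current)
        visited.append(current)
        if current == task.goal:
            solved = True
            break

    score = trial_score(max(TRIAL_TIME_LIMIT - t, 0.0), max(steps, 1)) if solved else 0

    if learn:
        if prof.mechanism in ("associative", "mixture") and solved:
            for key in path_actions:
                q = state.strengths.get(key, 0.0)
                state.strengths[key] = q + prof.learning_rate * (1.0 - q)
        if prof.mechanism in ("heuristic", "mixture"):
            # nudge the value model toward the realised outcome of every
            # visited state: on a solved trial only the final trajectory
            # segment (after the last reset) reached the goal; everything
            # explored before a reset, and every state of a failed trial,
            # did not.  Replaying the trial a few times sharpens the update
            # without the instability of one large step.
            labels = [
                1.0 if solved and i >= last_reset_index else 0.0
                for i in range(len(visited))
            ]
            for _ in range(prof.learn_epochs):
                for s, label in zip(visited, labels):
                    x = _value_features(s, task.goal)
                    p = expit(float(betas @ x))
                    betas += prof.learning_rate * (label - p) * x / max(
                        1.0, np.abs(x).max()
                    )

    return TrialRecord(
        participant=participant,
        session=session,
        block=block,
        start=task.start,
        goal=task.goal,
        ruleset_id=task.ruleset_id,
        min_solution_length=task.min_solution_length,
        events=events,
        solved=solved,
        steps=steps,
        score=score,
    )


# ---------------------------------------------------------------------------
# working-memory and strategy-report simulation


def simulate_wm_trial(capacity: float, length: int, rng: Random) -> WMOutcome:
    """One running-span trial for an agent of the given capacity.

    Recall probability at offset ``o`` is a floor-adjusted logistic
    ``1/9 + 8/9 * expit(capacity - o)``; the typed response covers the final
    few digits, wrong recalls substituting a different digit.
    """
    seq = make_digit_sequence(length, rng)
    n_typed = min(length, max(1, int(round(capacity)) + 3))
    typed = []
    for o in range(n_typed - 1, -1, -1):
        p = 1.0 / 9.0 + (8.0 / 9.0) * expit(capacity - o)
        true = seq[-1 - o]
        if rng.random() < p:
            typed.append(true)
        else:
            others = [c for c in "123456789" if c != true]
            typed.append(rng.choice(others))
    return WMOutcome(sequence=seq, response="".join(typed))


def simulate_strategy_report(
    profile: AgentProfile, rng: Random, concentration: float = 40.0
) -> StrategyReport:
    """Pairwise-preference survey response from the agent's strategy bias.

    Draws weights from a Dirichlet around ``strategy_bias`` and encodes them
    as the three pairwise preferences, exercising the x,y,z -> weights
    round-trip used by the analysis.
    """
    base = np.array(profile.strategy_bias, dtype=float)
    base = base / base.sum()
    w = np.array(
        [rng.gammavariate(concentration * b + 0.5, 1.0) for b in base]
    )
    w_t, w_w, w_i = w / w.sum()
    x = w_t / (w_t + w_w)
    y = w_w / (w_w + w_i)
    z = w_i / (w_i + w_t)
    from .metrics import strategy_weights

    return strategy_weights(float(x), float(y), float(z))


# ---------------------------------------------------------------------------
# full cohort


@dataclass
class CohortDataset:
    """Everything one simulated cohort produces, in analysis-ready form."""

    trials: list[TrialRecord]
    wm: dict[tuple[str, int], list[WMOutcome]]
    strategy: dict[tuple[str, str], StrategyReport]  # (participant, block)
    groups: dict[str, str]  # participant -> "A" | "B"
    transfer_enabled: bool = False

    def write(self, directory: str) -> None:
        """Write the JSONL event log plus CSV survey/span tables."""
        import csv
        import os

        from .metrics import trials_to_jsonl

        os.makedirs(directory, exist_ok=True)
        with open(os.path.join(directory, "trials.jsonl"), "w") as fh:
            fh.write(trials_to_jsonl(self.trials))
        with open(os.path.join(directory, "strategy.csv"), "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["participant", "block", "x", "y", "z"])
            for (p, b), rep in sorted(self.strategy.items()):
                w.writerow([p, b, rep.x, rep.y, rep.z])
        with open(os.path.join(directory, "wm.csv"), "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["participant", "session", "sequence", "response"])
            for (p, s), outcomes in sorted(self.wm.items()):
                for oc in outcomes:
                    w.writerow([p, s, oc.sequence, oc.response])


def default_profiles(
    n: int,
    mechanism: str,
    rng: Random,
    learning_rate: float | None = None,
    softmax_temperature: float | None = None,
    search_depth: int | None = None,
) -> list[AgentProfile]:
    """A cohort of agents with modest individual differences.

    Heuristic agents default to a search depth of 2 (novice-grade
    lookahead), three replay passes per trial, and a larger learning rate —
    their update nudges 14 logistic coefficients through bounded feature
    gradients, so individual steps move behaviour far less than the
    associative delta rule, which rewrites a single pattern strength
    directly.  The defaults for each mechanism are set so that
    training-block solution curves rise steadily from a baseline solution
    rate near 0.15, the regime the study design targets.  Associative
    agents evaluate no states and use search depth 1.
    """
    heuristic_like = mechanism in ("heuristic", "mixture")
    if search_depth is None:
        search_depth = 2 if heuristic_like else 1
    if learning_rate is None:
        learning_rate = 0.7 if heuristic_like else 0.5
    if softmax_temperature is None:
        softmax_temperature = 0.3 if heuristic_like else 0.25
    profiles = []
    for i in range(n):
        betas = np.zeros(len(FEATURE_NAMES) + 1)
        profiles.append(
            AgentProfile(
                id=f"{mechanism[:4]}{i:03d}",
                mechanism=mechanism,
                learning_rate=learning_rate * math.exp(rng.gauss(0, 0.2)),
                softmax_temperature=softmax_temperature
                * math.exp(rng.gauss(0, 0.15)),
                value_betas=betas,
                search_depth=search_depth,
                learn_epochs=3 if heuristic_like else 1,
                decision_time_loc=math.log(2.2) + rng.gauss(0, 0.15),
                wm_capacity=max(1.5, rng.gauss(5.0, 1.2)),
                strategy_bias=tuple(
                    max(0.2, rng.gauss(1.0, 0.25)) for _ in range(3)
                ),
            )
        )
    return profiles


def simulate_cohort(
    design: StudyDesign,
    profiles: list[AgentProfile],
    tasksets: tuple[Taskset, Taskset],
    transfer_enabled: bool,
    rng: Random,
) -> CohortDataset:
    """Simulate the full study for a cohort of agents.

    Agents alternate between counterbalance groups A and B (group A trains on
    the first taskset and is probed on the second; group B the reverse).
    Training blocks cover all trained tasks once in random order; probe
    blocks sample 12 untrained tasks, with p2 avoiding tasks shown in p1.
    When ``transfer_enabled`` heuristic agents carry their learned value
    coefficients into the post-training probe; otherwise (and for associative
    agents' pattern strengths, which cannot apply to unseen rules) probe
    blocks start from naive parameters.
    """
    ts_a, ts_b = tasksets
    graphs: dict[tuple[str, str], StateGraph] = {}
    for ts in tasksets:
        for task in ts.tasks:
            graphs[(task.start, task.goal)] = task_graph(task, ts.ruleset)

    trials: list[TrialRecord] = []
    wm: dict[tuple[str, int], list[WMOutcome]] = {}
    strategy: dict[tuple[str, str], StrategyReport] = {}
    groups: dict[str, str] = {}

    wm_lengths = [12 + (i % 10) for i in range(design.wm_trials_per_session)]

    for idx, profile in enumerate(profiles):
        group = "A" if idx % 2 == 0 else "B"
        groups[profile.id] = group
        trained, probed = (ts_a, ts_b) if group == "A" else (ts_b, ts_a)
        agent = _AgentState(profile.copy())
        naive_betas = profile.value_betas.copy()

        probe_pool = list(probed.tasks)
        rng.shuffle(probe_pool)
        if len(probe_pool) < 2 * design.trials_per_block:
            raise ValueError(
                "probe taskset too small for two disjoint probe blocks"
            )
        p1_tasks = probe_pool[: design.trials_per_block]
        p2_tasks = probe_pool[
            design.trials_per_block : 2 * design.trials_per_block
        ]

        training_order: list[Task] = []

        def next_training_task() -> Task:
            # covers the whole trained taskset before repeating any task
            if not training_order:
                refill = list(trained.tasks)
                rng.shuffle(refill)
                training_order.extend(refill)
            return training_order.pop()

        probe_learning_betas: np.ndarray | None = None
        for session, label in design.block_labels():
            is_probe = label.startswith("p")
            if is_probe:
                tasks = p1_tasks if label == "p1" else p2_tasks
                if profile.mechanism != "associative" and not transfer_enabled:
                    probe_learning_betas = naive_betas.copy()
                else:
                    probe_learning_betas = None
            else:
                tasks = [next_training_task() for _ in range(design.trials_per_block)]
            for task in tasks:
                tr = simulate_trial(
                    agent,
                    task,
                    graphs[(task.start, task.goal)],
                    rng,
                    participant=profile.id,
                    session=session,
                    block=label,
                    betas_override=probe_learning_betas,
                )
                trials.append(tr)
            strategy[(profile.id, label)] = simulate_strategy_report(profile, rng)

        for session in range(1, design.n_sessions + 1):
            lengths = list(wm_lengths)
            rng.shuffle(lengths)
            wm[(profile.id, session)] = [
                simulate_wm_trial(profile.wm_capacity, n, rng) for n in lengths
            ]

    return CohortDataset(
        trials=trials,
        wm=wm,
        strategy=strategy,
        groups=groups,
        transfer_enabled=transfer_enabled,
    )
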