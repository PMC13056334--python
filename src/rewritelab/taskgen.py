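"""Generation of study-grade rulesets and tasksets, plus trial scoring.

Tasksets emulate the difficulty regime of the transformation-problem study
design this package supports: 5-rule rulesets with identical structure
profiles but non-isomorphic content, and tasks filtered so that each has
2-4 distinct minimal solutions, a minimal solution length in {4, 5, 6}
(balanced counts), a goal of at least 3 symbols, a possible "wrong turn" at
every state on a minimal solution path, and no commutative transitions.

The default rule-structure profile uses strictly length-decreasing rules
(``|rhs| < |lhs|``).  This makes the reachable state space of every start
string finite, so state-graph enumeration is exact (never truncated) and
every generated task's difficulty metadata is exact rather than capped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from random import Random

from .engine import (
    INFINITY,
    EnumerationCaps,
    Rule,
    Ruleset,
    StateGraph,
    Task,
    count_minimal_solutions,
    enumerate_state_graph,
    has_commutative_transition,
    rulesets_isomorphic,
    wrong_turn_everywhere,
)

__all__ = [
    "DifficultySpec",
    "StructureSpec",
    "Taskset",
    "GenerationExhausted",
    "generate_ruleset",
    "generate_ruleset_pair",
    "generate_taskset",
    "generate_taskset_pair",
    "verify_task",
    "verify_taskset",
    "trial_score",
]

# the study design: 72 tasks per taskset, 24 per minimal solution length
STUDY_N_PER_LENGTH = 24


class GenerationExhausted(RuntimeError):
    """Raised when rejection sampling uses up its attempt budget."""


@dataclass(frozen=True)
class DifficultySpec:
    """Printed difficulty criteria a task must satisfy."""

    n_solutions_range: tuple[int, int] = (2, 4)
    min_length_range: tuple[int, int] = (4, 6)
    goal_min_length: int = 3
    require_wrong_turns: bool = True
    forbid_commutative: bool = True

    def __post_init__(self) -> None:
        if self.n_solutions_range[0] > self.n_solutions_range[1]:
            raise ValueError("empty n_solutions_range")
        if self.min_length_range[0] > self.min_length_range[1]:
            raise ValueError("empty min_length_range")
        if self.goal_min_length < 1:
            raise ValueError("goal_min_length must be >= 1")


@dataclass(frozen=True)
class StructureSpec:
    """Structural recipe for a ruleset: (|lhs|, |rhs|) profile and alphabet size.

    The default profile mixes one-symbol and two-symbol shrink rules, which
    empirically yields rich but finite state spaces on a 3-symbol alphabet.
    """

    n_rules: int = 5
    lhs_rhs_length_profile: tuple[tuple[int, int], ...] = (
        (2, 1), (2, 1), (2, 1), (3, 1), (3, 1),
    )
    alphabet_size: int = 3
    disjoint_alphabets: bool = True

    def __post_init__(self) -> None:
        if len(self.lhs_rhs_length_profile) != self.n_rules:
            raise ValueError("profile size must equal n_rules")


@dataclass
class Taskset:
    """A ruleset plus its generated tasks and the per-length balance."""

    id: str
    ruleset: Ruleset
    tasks: list[Task]
    balance: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.balance:
            self.balance = {}
            for t in self.tasks:
                self.balance[t.min_solution_length] = (
                    self.balance.get(t.min_solution_length, 0) + 1
                )
        pairs = [(t.start, t.goal) for t in self.tasks]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate (start, goal) pair in taskset")


def _alphabet(offset: int, size: int) -> list[str]:
    return [chr(ord("A") + offset + i) for i in range(size)]


def generate_ruleset(
    spec: StructureSpec,
    rng: Random,
    id: str = "rs",
    alphabet: list[str] | None = None,
    max_attempts: int = 1000,
) -> Ruleset:
    """Random ruleset realising the structure profile, rules pairwise distinct."""
    alpha = alphabet if alphabet is not None else _alphabet(0, spec.alphabet_size)
    for _ in range(max_attempts):
        seen: set[tuple[str, str]] = set()
        rules: list[Rule] = []
        ok = True
        for i, (nl, nr) in enumerate(spec.lhs_rhs_length_profile):
            for _ in range(200):
                lhs = "".join(rng.choice(alpha) for _ in range(nl))
                rhs = "".join(rng.choice(alpha) for _ in range(nr))
                if lhs != rhs and (lhs, rhs) not in seen:
                    seen.add((lhs, rhs))
                    rules.append(Rule(i, lhs, rhs))
                    break
            else:
                ok = False
                break
        if ok:
            return Ruleset(id, tuple(rules), frozenset(alpha))
    raise GenerationExhausted("could not realise the structure profile")


def _viable(
    ruleset: Ruleset,
    difficulty: DifficultySpec,
    rng: Random,
    start_lengths: tuple[int, int],
    probe_starts: int = 120,
) -> bool:
    """Quick screen: can this ruleset produce a task at every required length?"""
    found: set[int] = set()
    lengths = set(
        range(difficulty.min_length_range[0], difficulty.min_length_range[1] + 1)
    )
    for _ in range(probe_starts):
        task = _sample_task(
            ruleset, difficulty, lengths - found, rng, start_lengths, max_goals=6
        )
        if task is not None:
            found.add(task.min_solution_length)
            if found == lengths:
                return True
    return False


def generate_ruleset_pair(
    spec: StructureSpec,
    rng: Random,
    difficulty: DifficultySpec | None = None,
    start_lengths: tuple[int, int] = (11, 15),
    max_attempts: int = 200,
) -> tuple[Ruleset, Ruleset]:
    """Two rulesets with identical structure profiles that are not isomorphic.

    By default the two rulesets use disjoint alphabets (the shared-alphabet
    mode is available through ``spec.disjoint_alphabets``).  Each candidate
    ruleset is screened for viability — it must be able to produce at least
    one task at every required minimal solution length — so that taskset
    generation on the returned pair does not stall.
    """
    difficulty = difficulty or DifficultySpec()
    alpha_a = _alphabet(0, spec.alphabet_size)
    alpha_b = (
        _alphabet(spec.alphabet_size, spec.alphabet_size)
        if spec.disjoint_alphabets
        else alpha_a
    )

    def draw(id: str, alpha: list[str]) -> Ruleset:
        for _ in range(max_attempts):
            rs = generate_ruleset(spec, rng, id=id, alphabet=alpha)
            if _viable(rs, difficulty, rng, start_lengths):
                return rs
        raise GenerationExhausted(
            f"no viable ruleset for profile {spec.lhs_rhs_length_profile} "
            f"after {max_attempts} attempts"
        )

    rs_a = draw("A", alpha_a)
    for _ in range(max_attempts):
        rs_b = draw("B", alpha_b)
        if not rulesets_isomorphic(rs_a, rs_b):
            return rs_a, rs_b
    raise GenerationExhausted(
        "all generated candidate rulesets were isomorphic to the first"
    )


def _distance_map(graph: StateGraph, goal: str) -> dict[str, float]:
    """Reverse BFS distances to ``goal`` over the enumerated edges."""
    from collections import deque

    preds: dict[str, list[str]] = {}
    for u, _rid, _pos, v in graph.edges:
        preds.setdefault(v, []).append(u)
    dist: dict[str, float] = {goal: 0.0}
    q = deque([goal])
    while q:
        v = q.popleft()
        for u in preds.get(v, []):
            if u not in dist:
                dist[u] = dist[v] + 1
                q.append(u)
    return dist


def task_graph(task: Task, ruleset: Ruleset, max_nodes: int = 100_000) -> StateGraph:
    """Exact state graph of a task under generation-grade caps."""
    caps = EnumerationCaps(
        max_depth=len(task.start) + 2, max_length=len(task.start), max_nodes=max_nodes
    )
    return enumerate_state_graph(task.start, task.goal, ruleset, caps)


def _sample_task(
    ruleset: Ruleset,
    difficulty: DifficultySpec,
    wanted_lengths: set[int],
    rng: Random,
    start_lengths: tuple[int, int],
    max_goals: int = 10,
    used_pairs: set[tuple[str, str]] | None = None,
) -> Task | None:
    """One rejection-sampling attempt: a random start, then candidate goals."""
    alpha = sorted(ruleset.alphabet)
    ls = rng.randint(*start_lengths)
    start = "".join(rng.choice(alpha) for _ in range(ls))
    caps = EnumerationCaps(max_depth=ls + 2, max_length=ls, max_nodes=100_000)
    graph = enumerate_state_graph(start, "", ruleset, caps)
    if graph.truncated:
        return None
    lo, hi = difficulty.min_length_range
    cands = sorted(
        n
        for n in graph.nodes
        if lo <= graph.depth_from_start[n] <= hi
        and len(n) >= difficulty.goal_min_length
        and n != start
    )
    rng.shuffle(cands)
    commutes: bool | None = None
    for goal in cands[:max_goals]:
        if used_pairs and (start, goal) in used_pairs:
            continue
        dist = _distance_map(graph, goal)
        d = dist.get(start, INFINITY)
        if d == INFINITY or int(d) not in wanted_lengths:
            continue
        g2 = StateGraph(
            start=start,
            goal=goal,
            ruleset=ruleset,
            nodes=graph.nodes,
            edges=graph.edges,
            depth_from_start=graph.depth_from_start,
            distance_to_goal={n: dist.get(n, INFINITY) for n in graph.nodes},
        )
        nmin = count_minimal_solutions(g2)
        nlo, nhi = difficulty.n_solutions_range
        if not nlo <= nmin <= nhi:
            continue
        if difficulty.require_wrong_turns and not wrong_turn_everywhere(g2):
            continue
        if difficulty.forbid_commutative:
            if commutes is None:
                commutes = has_commutative_transition(g2)
            if commutes:
                return None  # property of the start's whole graph: reject the start
        return Task(start, goal, ruleset.id, int(d), nmin)
    return None


def generate_taskset(
    ruleset: Ruleset,
    difficulty: DifficultySpec = DifficultySpec(),
    n_per_length: int = STUDY_N_PER_LENGTH,
    rng: Random | None = None,
    start_lengths: tuple[int, int] = (11, 15),
    max_attempts: int = 50_000,
    id: str | None = None,
) -> Taskset:
    """Rejection-sample a balanced taskset meeting every difficulty criterion.

    Collects ``n_per_length`` tasks for each minimal solution length in
    ``difficulty.min_length_range``, with unique (start, goal) pairs.  Raises
    :class:`GenerationExhausted` after ``max_attempts`` sampled start strings
    rather than silently relaxing any criterion.
    """
    if n_per_length < 1:
        raise ValueError("n_per_length must be >= 1")
    rng = rng or Random(0)
    lo, hi = difficulty.min_length_range
    need = {d: n_per_length for d in range(lo, hi + 1)}
    tasks: list[Task] = []
    used: set[tuple[str, str]] = set()
    for _ in range(max_attempts):
        wanted = {d for d, n in need.items() if n > 0}
        if not wanted:
            break
        task = _sample_task(
            ruleset, difficulty, wanted, rng, start_lengths, used_pairs=used
        )
        if task is None:
            continue
        tasks.append(task)
        used.add((task.start, task.goal))
        need[task.min_solution_length] -= 1
    if any(n > 0 for n in need.values()):
        raise GenerationExhausted(
            f"attempt budget {max_attempts} exhausted; still missing {need}"
        )
    tasks.sort(key=lambda t: (t.min_solution_length, t.start, t.goal))
    return Taskset(id or ruleset.id, ruleset, tasks)


def generate_taskset_pair(
    seed: int,
    n_per_length: int = STUDY_N_PER_LENGTH,
    structure: StructureSpec = StructureSpec(),
    difficulty: DifficultySpec = DifficultySpec(),
    start_lengths: tuple[int, int] = (11, 15),
) -> tuple[Taskset, Taskset]:
    """Convenience wrapper: a seeded non-isomorphic ruleset pair and its tasksets."""
    rng = Random(seed)
    rs_a, rs_b = generate_ruleset_pair(
        structure, rng, difficulty, start_lengths=start_lengths
    )
    ts_a = generate_taskset(
        rs_a, difficulty, n_per_length, rng, start_lengths=start_lengths
    )
    ts_b = generate_taskset(
        rs_b, difficulty, n_per_length, rng, start_lengths=start_lengths
    )
    return ts_a, ts_b


def verify_task(
    task: Task, ruleset: Ruleset, difficulty: DifficultySpec = DifficultySpec()
) -> list[str]:
    """Independent re-check of every difficulty criterion; returns violations.

    Re-enumerates the task's state graph from scratch and re-runs all engine
    checks, so it serves as the acceptance oracle for the generator.
    """
    problems: list[str] = []
    graph = task_graph(task, ruleset)
    if graph.truncated:
        problems.append("state graph truncated")
        return problems
    d = graph.distance_to_goal.get(task.start, INFINITY)
    if d == INFINITY:
        problems.append("goal unreachable")
        return problems
    lo, hi = difficulty.min_length_range
    if not lo <= d <= hi:
        problems.append(f"minimal length {d} outside [{lo}, {hi}]")
    if int(d) != task.min_solution_length:
        problems.append(
            f"recorded minimal length {task.min_solution_length} != actual {int(d)}"
        )
    if len(task.goal) < difficulty.goal_min_length:
        problems.append("goal too short")
    nmin = count_minimal_solutions(graph)
    nlo, nhi = difficulty.n_solutions_range
    if not nlo <= nmin <= nhi:
        problems.append(f"{nmin} minimal solutions outside [{nlo}, {nhi}]")
    if nmin != task.n_minimal_solutions:
        problems.append(
            f"recorded {task.n_minimal_solutions} minimal solutions != actual {nmin}"
        )
    if difficulty.require_wrong_turns and not wrong_turn_everywhere(graph):
        problems.append("some on-path state has no wrong turn")
    if difficulty.forbid_commutative and has_commutative_transition(graph):
        problems.append("graph has a commutative transition")
    return problems


def verify_taskset(
    taskset: Taskset,
    difficulty: DifficultySpec = DifficultySpec(),
    n_per_length: int | None = None,
) -> list[str]:
    """Re-check every task plus the taskset-level balance and uniqueness invariants."""
    problems: list[str] = []
    pairs = [(t.start, t.goal) for t in taskset.tasks]
    if len(set(pairs)) != len(pairs):
        problems.append("duplicate (start, goal) pairs")
    if n_per_length is not None:
        lo, hi = difficulty.min_length_range
        expect = {d: n_per_length for d in range(lo, hi + 1)}
        if taskset.balance != expect:
            problems.append(f"balance {taskset.balance} != expected {expect}")
    for i, task in enumerate(taskset.tasks):
        for p in verify_task(task, taskset.ruleset, difficulty):
            problems.append(f"task {i} ({task.start}->{task.goal}): {p}")
    return problems


TRIAL_TIME_LIMIT = 75.0  # seconds per problem-solving trial


def trial_score(remaining_time: float, steps: int) -> int:
    """Score of a solved trial: floor(10 * remaining seconds / steps taken)."""
    if steps < 1:
        raise ValueError("steps must be >= 1")
    if not 0 <= remaining_time <= TRIAL_TIME_LIMIT:
        raise ValueError(f"remaining_time must lie in [0, {TRIAL_TIME_LIMIT}]")
    return math.floor(10.0 * remaining_time / steps)
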