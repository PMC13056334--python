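"""Exact semantics of the string-transformation task and bounded state-space analysis.

A *transformation problem* presents a start string, a goal string, and a small
set of rewrite rules ``lhs -> rhs``.  A rule applied at position ``p`` replaces
``state[p : p + len(lhs)]`` by ``rhs`` when that span equals ``lhs``; otherwise
the application is *invalid* and leaves the state unchanged (in the task this is
a modelled in-task event, not an error).  A solution is any sequence of valid
applications transforming the start into the goal.

Because rewriting systems can grow without bound, all state-space enumeration
here is explicitly capped (search depth, string length, node count) and the
resulting :class:`StateGraph` records whether any cap was hit.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field
from itertools import permutations
from statistics import median
from typing import Iterable, Iterator

INFINITY = float("inf")

__all__ = [
    "INFINITY",
    "Rule",
    "Ruleset",
    "Task",
    "EnumerationCaps",
    "StateGraph",
    "apply_rule",
    "valid_applications",
    "successors",
    "enumerate_state_graph",
    "count_minimal_solutions",
    "count_solutions",
    "enumerate_acyclic_solution_lengths",
    "median_remaining_solution_length",
    "has_commutative_transition",
    "wrong_turn_everywhere",
    "rulesets_isomorphic",
    "ruleset_to_json",
    "ruleset_from_json",
    "taskset_to_json",
    "taskset_from_json",
    "graph_to_edge_tsv",
]


@dataclass(frozen=True)
class Rule:
    """A rewrite rule ``lhs -> rhs`` over a symbol alphabet."""

    id: int
    lhs: str
    rhs: str

    def __post_init__(self) -> None:
        if not self.lhs or not self.rhs:
            raise ValueError("rule sides must be non-empty symbol strings")

    @property
    def delta(self) -> int:
        """Length change of one application."""
        return len(self.rhs) - len(self.lhs)

    def reversed(self) -> "Rule":
        return Rule(self.id, self.rhs, self.lhs)


@dataclass(frozen=True)
class Ruleset:
    """An ordered set of rewrite rules with its symbol alphabet."""

    id: str
    rules: tuple[Rule, ...]
    alphabet: frozenset[str]

    def __post_init__(self) -> None:
        ids = [r.id for r in self.rules]
        if len(set(ids)) != len(ids):
            raise ValueError("rule ids must be unique within a ruleset")
        for r in self.rules:
            if not set(r.lhs) <= self.alphabet or not set(r.rhs) <= self.alphabet:
                raise ValueError(f"rule {r.id} uses symbols outside the alphabet")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]], id: str = "rs") -> "Ruleset":
        rules = tuple(Rule(i, lhs, rhs) for i, (lhs, rhs) in enumerate(pairs))
        alpha = frozenset("".join(r.lhs + r.rhs for r in rules))
        return cls(id, rules, alpha)

    def structure_profile(self) -> tuple[tuple[int, int], ...]:
        """Sorted multiset of (|lhs|, |rhs|) pairs."""
        return tuple(sorted((len(r.lhs), len(r.rhs)) for r in self.rules))


@dataclass(frozen=True)
class Task:
    """A start/goal pair on a ruleset, with its pre-computed difficulty metadata."""

    start: str
    goal: str
    ruleset_id: str
    min_solution_length: int
    n_minimal_solutions: int


INVALID = None  # sentinel returned by apply_rule for an invalid (modelled) application


def apply_rule(state: str, rule: Rule, position: int) -> str | None:
    """Apply ``rule`` at a 0-based ``position``; return the new state or ``None``.

    ``None`` signals an *invalid application* (the in-task "shake" event): the
    left-hand side does not match the equal-length substring of ``state``
    starting at ``position``, or does not fit before the end of the string.
    An out-of-range position is a caller error, not an in-task event.
    """
    if not 0 <= position <= len(state) - 1:
        raise ValueError(f"position {position} out of range for state of length {len(state)}")
    end = position + len(rule.lhs)
    if end > len(state) or state[position:end] != rule.lhs:
        return None
    return state[:position] + rule.rhs + state[end:]


def valid_applications(state: str, ruleset: Ruleset) -> list[tuple[int, int]]:
    """All (rule id, position) pairs that validly apply in ``state``."""
    out = []
    for rule in ruleset.rules:
        n = len(rule.lhs)
        for pos in range(len(state) - n + 1):
            if state[pos : pos + n] == rule.lhs:
                out.append((rule.id, pos))
    return out


def successors(state: str, ruleset: Ruleset) -> list[tuple[int, int, str]]:
    """All (rule id, position, next state) triples reachable in one valid step."""
    by_id = {r.id: r for r in ruleset.rules}
    return [
        (rid, pos, apply_rule(state, by_id[rid], pos))
        for rid, pos in valid_applications(state, ruleset)
    ]


@dataclass(frozen=True)
class EnumerationCaps:
    """Termination bounds for state-space enumeration.

    Defaults are deliberately generous; generators use tighter task-specific
    caps.  ``max_length`` of ``None`` resolves to ``2 * max(|start|, |goal|, 8)``
    at enumeration time.
    """

    max_depth: int = 10
    max_length: int | None = None
    max_nodes: int = 200_000

    def resolve_length(self, start: str, goal: str) -> int:
        if self.max_length is not None:
            return self.max_length
        return 2 * max(len(start), len(goal), 8)


@dataclass
class StateGraph:
    """Bounded reachability graph of a task, with a distance-to-goal map.

    ``edges`` holds (from_state, rule_id, position, to_state) for every valid
    single application between enumerated states.  ``distance_to_goal`` maps
    each node to the length of a shortest valid-application path to the goal
    within the enumerated edge set, or ``inf`` when the goal is unreachable.
    ``truncated`` is True when any enumeration cap bound the search, in which
    case reachability labels are only valid within the caps.
    """

    start: str
    goal: str
    ruleset: Ruleset
    nodes: set[str] = field(default_factory=set)
    edges: list[tuple[str, int, int, str]] = field(default_factory=list)
    distance_to_goal: dict[str, float] = field(default_factory=dict)
    depth_from_start: dict[str, int] = field(default_factory=dict)
    truncated: bool = False

    _adj: dict[str, list[tuple[int, int, str]]] | None = None

    def out_edges(self, state: str) -> list[tuple[int, int, str]]:
        """(rule id, position, to_state) successors of an enumerated state."""
        if self._adj is None:
            adj: dict[str, list[tuple[int, int, str]]] = {n: [] for n in self.nodes}
            for u, rid, pos, v in self.edges:
                adj[u].append((rid, pos, v))
            self._adj = adj
        return self._adj.get(state, [])

    def distance(self, state: str) -> float:
        """Distance to goal, recomputed on demand for states outside the graph."""
        if state in self.distance_to_goal:
            return self.distance_to_goal[state]
        sub = enumerate_state_graph(
            state, self.goal, self.ruleset,
            EnumerationCaps(max_depth=10, max_length=None, max_nodes=50_000),
        )
        return sub.distance_to_goal.get(state, INFINITY)


def enumerate_state_graph(
    start: str,
    goal: str,
    ruleset: Ruleset,
    caps: EnumerationCaps = EnumerationCaps(),
) -> StateGraph:
    """Breadth-first enumeration of all states reachable from ``start`` under caps.

    Edges are recorded between any two enumerated states (including edges
    discovered from states at the depth cap, when the target state was already
    enumerated).  ``distance_to_goal`` comes from a reverse breadth-first search
    from the goal over the recorded edges.
    """
    max_len = caps.resolve_length(start, goal)
    g = StateGraph(start=start, goal=goal, ruleset=ruleset)
    if len(start) > max_len:
        raise ValueError("start string exceeds the length cap")
    g.nodes.add(start)
    g.depth_from_start[start] = 0
    frontier = deque([start])
    while frontier:
        u = frontier.popleft()
        d = g.depth_from_start[u]
        if d >= caps.max_depth:
            g.truncated = True
            continue
        for rid, pos, v in successors(u, ruleset):
            if len(v) > max_len:
                g.truncated = True
                continue
            if v not in g.nodes:
                if len(g.nodes) >= caps.max_nodes:
                    g.truncated = True
                    continue
                g.nodes.add(v)
                g.depth_from_start[v] = d + 1
                frontier.append(v)
            g.edges.append((u, rid, pos, v))

    # reverse BFS from goal over recorded edges
    preds: dict[str, list[str]] = {n: [] for n in g.nodes}
    for u, _rid, _pos, v in g.edges:
        preds[v].append(u)
    dist: dict[str, float] = {n: INFINITY for n in g.nodes}
    if goal in g.nodes:
        dist[goal] = 0
        q = deque([goal])
        while q:
            v = q.popleft()
            for u in preds[v]:
                if dist[u] == INFINITY:
                    dist[u] = dist[v] + 1
                    q.append(u)
    g.distance_to_goal = dist
    return g


def count_minimal_solutions(graph: StateGraph, state: str | None = None) -> int:
    """Number of distinct minimal-length solution sequences from ``state`` (default start).

    Sequences are (rule id, position) paths of length exactly
    ``distance_to_goal(state)``; parallel edges between the same state pair
    count separately.  ``state == goal`` counts one empty solution by
    convention.  Raises for an unreachable goal.
    """
    src = graph.start if state is None else state
    d0 = graph.distance_to_goal.get(src, INFINITY)
    if d0 == INFINITY:
        raise ValueError("goal is not reachable from the given state")
    counts: dict[str, int] = {}

    def n_paths(u: str) -> int:
        if u == graph.goal and graph.distance_to_goal[u] == 0:
            return 1
        if u in counts:
            return counts[u]
        du = graph.distance_to_goal[u]
        total = sum(
            n_paths(v)
            for _rid, _pos, v in graph.out_edges(u)
            if graph.distance_to_goal.get(v, INFINITY) == du - 1
        )
        counts[u] = total
        return total

    return n_paths(src)


def enumerate_acyclic_solution_lengths(
    graph: StateGraph, state: str, path_cap: int
) -> list[int]:
    """Lengths of every acyclic solution path from ``state`` with length <= path_cap."""
    lengths: list[int] = []
    on_path: set[str] = set()

    def dfs(u: str, depth: int) -> None:
        if u == graph.goal:
            lengths.append(depth)
            # the goal may be an intermediate state of a longer solution; the
            # task ends at the goal, so we do not extend past it
            return
        if depth >= path_cap:
            return
        d = graph.distance_to_goal.get(u, INFINITY)
        if d == INFINITY or depth + d > path_cap:
            return
        on_path.add(u)
        for _rid, _pos, v in graph.out_edges(u):
            if v not in on_path:
                dfs(v, depth + 1)
        on_path.discard(u)

    if state in graph.nodes:
        dfs(state, 0)
    return lengths


def count_solutions(graph: StateGraph, length_cap: int, state: str | None = None) -> int:
    """Number of acyclic solution sequences from ``state`` with length <= length_cap.

    The non-minimal counting mode for "distinct solution sequences".
    """
    src = graph.start if state is None else state
    return len(enumerate_acyclic_solution_lengths(graph, src, length_cap))


def median_remaining_solution_length(
    state: str, graph: StateGraph, path_cap: int | None = None
) -> float:
    """Median length of all acyclic action sequences from ``state`` to the goal.

    Returns ``inf`` for states with no path to the goal.  ``path_cap`` defaults
    to ``distance_to_goal(state) + 6``; the set of all unrestricted action
    sequences is infinite, so a cap is required.
    """
    d = graph.distance_to_goal.get(state, INFINITY)
    if d == INFINITY:
        return INFINITY
    cap = path_cap if path_cap is not None else int(d) + 6
    lengths = enumerate_acyclic_solution_lengths(graph, state, cap)
    if not lengths:
        return INFINITY
    return float(median(lengths))


def has_commutative_transition(graph: StateGraph) -> bool:
    """True iff some state is reached by the same two applications in either order.

    Looks for states ``u, w`` with two 2-step edge sequences ``u -> . -> w``
    whose (rule id, position) pairs are the same two applications applied in
    opposite orders.
    """
    for u in graph.nodes:
        # map from the unordered pair of applications to distinct targets
        seen: dict[frozenset, dict[tuple, str]] = {}
        for rid1, pos1, v in graph.out_edges(u):
            for rid2, pos2, w in graph.out_edges(v):
                a1, a2 = (rid1, pos1), (rid2, pos2)
                if a1 == a2:
                    continue
                key = frozenset((a1, a2))
                orders = seen.setdefault(key, {})
                orders[(a1, a2)] = w
                other = orders.get((a2, a1))
                if other is not None and other == w:
                    return True
    return False


def _minimal_path_states(graph: StateGraph) -> set[str]:
    """States lying on at least one minimal solution path from the start."""
    d_goal = graph.distance_to_goal
    d_start = graph.depth_from_start
    total = d_goal.get(graph.start, INFINITY)
    return {
        n
        for n in graph.nodes
        if d_start.get(n, INFINITY) + d_goal.get(n, INFINITY) == total
    }


def wrong_turn_everywhere(graph: StateGraph) -> bool:
    """True iff every on-path state admits a wrong turn.

    "On-path" means lying on a minimal solution path from the start.  A wrong
    turn from state ``u`` is a valid successor that is not on any minimal
    solution path *from u* — i.e. a successor ``v`` with
    ``distance(v) != distance(u) - 1`` (including dead ends).  Vacuously true
    when start equals goal.  Raises for an unreachable goal.
    """
    if graph.distance_to_goal.get(graph.start, INFINITY) == INFINITY:
        raise ValueError("goal is not reachable from start")
    for u in _minimal_path_states(graph):
        if u == graph.goal:
            continue
        du = graph.distance_to_goal[u]
        if not any(
            graph.distance_to_goal.get(v, INFINITY) != du - 1
            for _rid, _pos, v in graph.out_edges(u)
        ):
            return False
    return True


def rulesets_isomorphic(a: Ruleset, b: Ruleset) -> bool:
    """True iff some symbol bijection maps the rule multiset of ``a`` onto ``b``'s.

    The bijection is applied to both sides of each rule (LHS onto LHS, RHS onto
    RHS); rule ids and ordering are ignored.  Checked by exhaustive search over
    alphabet bijections, feasible for task-sized alphabets.
    """
    sa = sorted(a.alphabet)
    sb = sorted(b.alphabet)
    if len(sa) != len(sb) or len(a.rules) != len(b.rules):
        return False
    target = sorted((r.lhs, r.rhs) for r in b.rules)
    for perm in permutations(sb):
        m = dict(zip(sa, perm))
        mapped = sorted(
            ("".join(m[c] for c in r.lhs), "".join(m[c] for c in r.rhs))
            for r in a.rules
        )
        if mapped == target:
            return True
    return False


# ---------------------------------------------------------------------------
# serialisation


def ruleset_to_json(ruleset: Ruleset) -> dict:
    return {
        "id": ruleset.id,
        "alphabet": sorted(ruleset.alphabet),
        "rules": [{"id": r.id, "lhs": r.lhs, "rhs": r.rhs} for r in ruleset.rules],
    }


def ruleset_from_json(obj: dict) -> Ruleset:
    rules = tuple(Rule(r["id"], r["lhs"], r["rhs"]) for r in obj["rules"])
    return Ruleset(obj["id"], rules, frozenset(obj["alphabet"]))


def taskset_to_json(ruleset: Ruleset, tasks: Iterable[Task]) -> dict:
    return {
        "ruleset": ruleset_to_json(ruleset),
        "tasks": [
            {
                "start": t.start,
                "goal": t.goal,
                "min_solution_length": t.min_solution_length,
                "n_minimal_solutions": t.n_minimal_solutions,
            }
            for t in tasks
        ],
    }


def taskset_from_json(obj: dict) -> tuple[Ruleset, list[Task]]:
    rs = ruleset_from_json(obj["ruleset"])
    tasks = [
        Task(
            t["start"],
            t["goal"],
            rs.id,
            t["min_solution_length"],
            t.get("n_minimal_solutions", 0),
        )
        for t in obj["tasks"]
    ]
    return rs, tasks


def graph_to_edge_tsv(graph: StateGraph) -> str:
    """Edge list as TSV (from_state, rule_id, position, to_state) for debugging."""
    lines = ["from_state\trule_id\tposition\tto_state"]
    lines += [f"{u}\t{rid}\t{pos}\t{v}" for u, rid, pos, v in graph.edges]
    return "\n".join(lines) + "\n"


def load_taskset(path: str) -> tuple[Ruleset, list[Task]]:
    """Load a ruleset + taskset from the JSON interchange format."""
    with open(path) as fh:
        return taskset_from_json(json.load(fh))


def save_taskset(path: str, ruleset: Ruleset, tasks: Iterable[Task]) -> None:
    with open(path, "w") as fh:
        json.dump(taskset_to_json(ruleset, tasks), fh, indent=1)
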