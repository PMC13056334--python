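"""Shared fixtures and independent brute-force oracles for the test suite."""

from __future__ import annotations

import itertools
from random import Random

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")

from rewritelab.engine import (
    INFINITY,
    EnumerationCaps,
    Ruleset,
    StateGraph,
    apply_rule,
    enumerate_state_graph,
)

# ---------------------------------------------------------------------------
# brute-force oracles, independent of the engine's BFS/DP implementations


def brute_min_distance(start: str, goal: str, ruleset: Ruleset, max_depth: int,
                       max_length: int) -> float:
    """Minimum solution length by exhaustive depth-first path enumeration."""
    best = [INFINITY]

    def dfs(state: str, depth: int) -> None:
        if state == goal:
            best[0] = min(best[0], depth)
            return
        if depth >= max_depth or depth >= best[0]:
            return
        for rule in ruleset.rules:
            for pos in range(len(state)):
                nxt = apply_rule(state, rule, pos)
                if nxt is not None and len(nxt) <= max_length:
                    dfs(nxt, depth + 1)

    dfs(start, 0)
    return best[0]


def brute_count_minimal(start: str, goal: str, ruleset: Ruleset, d: int,
                        max_length: int) -> int:
    """Number of distinct (rule, position) sequences of length exactly d."""
    count = [0]

    def dfs(state: str, depth: int) -> None:
        if depth == d:
            if state == goal:
                count[0] += 1
            return
        for rule in ruleset.rules:
            for pos in range(len(state)):
                nxt = apply_rule(state, rule, pos)
                if nxt is not None and len(nxt) <= max_length:
                    dfs(nxt, depth + 1)

    dfs(start, 0)
    return count[0]


def brute_commutative(graph: StateGraph) -> bool:
    """Scan all pairs of 2-step paths for same-applications-opposite-order."""
    paths = []
    for u in sorted(graph.nodes):
        for r1, p1, v in graph.out_edges(u):
            for r2, p2, w in graph.out_edges(v):
                paths.append((u, (r1, p1), (r2, p2), w))
    for (u1, a1, b1, w1), (u2, a2, b2, w2) in itertools.product(paths, repeat=2):
        if u1 == u2 and w1 == w2 and a1 == b2 and b1 == a2 and a1 != a2:
            return True
    return False


def brute_lcs(a: str, b: str) -> int:
    """LCS length by enumeration of subsequences of the shorter string."""
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    best = 0
    for r in range(len(short), 0, -1):
        for combo in itertools.combinations(short, r):
            sub = "".join(combo)
            it = iter(long_)
            if all(c in it for c in sub):
                return r
    return best


def random_small_instance(rng: Random):
    """A random rewriting instance with alphabet <= 3 and short strings."""
    alpha = "ABC"[: rng.randint(2, 3)]
    n_rules = rng.randint(1, 3)
    rules = []
    for _ in range(n_rules):
        lhs = "".join(rng.choice(alpha) for _ in range(rng.randint(1, 2)))
        rhs = "".join(rng.choice(alpha) for _ in range(rng.randint(1, 2)))
        rules.append((lhs, rhs))
    ruleset = Ruleset.from_pairs(rules)
    start = "".join(rng.choice(alpha) for _ in range(rng.randint(1, 5)))
    goal = "".join(rng.choice(alpha) for _ in range(rng.randint(1, 5)))
    return start, goal, ruleset


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def ab_ruleset() -> Ruleset:
    """The one-rule system {A -> B}."""
    return Ruleset.from_pairs([("A", "B")])


@pytest.fixture(scope="session")
def ab_graph(ab_ruleset) -> StateGraph:
    """State graph of the AA -> BB task under {A -> B}."""
    return enumerate_state_graph("AA", "BB", ab_ruleset)


@pytest.fixture(scope="session")
def chain_graph() -> StateGraph:
    """A linear chain: ABC -> XBC -> XYC -> XYZ, one applicable move per state."""
    rs = Ruleset.from_pairs([("A", "X"), ("XB", "XY"), ("YC", "YZ")])
    return enumerate_state_graph("ABC", "XYZ", rs)


@pytest.fixture(scope="session")
def small_taskset_pair():
    """A small but study-shaped taskset pair (2 tasks per minimal length)."""
    from rewritelab.taskgen import generate_taskset_pair

    return generate_taskset_pair(seed=7, n_per_length=2)


@pytest.fixture(scope="session")
def full_taskset_pair():
    """A full study-sized taskset pair (72 tasks each), seeded."""
    from rewritelab.taskgen import generate_taskset_pair

    return generate_taskset_pair(seed=1)
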