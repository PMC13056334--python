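"""The 13-feature representation behind the parametric state-value heuristic.

Each feature maps a (state, goal) string pair to a real number.  None of them
refers to any transformation rule, which is what lets a value model built on
them transfer between tasksets with disjoint rules:

- f1   proportion of state symbols matching the goal symbol at the same position
- f2   length(state) - length(goal)
- f3   unique-symbol count of state - unique-symbol count of goal
- f4   longest common subsequence length / length(goal)
- f5   length(state);                f6  length(goal)
- f7   longest run of repeats in state;   f8  same for goal
- f9   shortest run of repeats in state;  f10 same for goal
- f11  length of state with consecutive repeats collapsed; f12 same for goal
- f13  Levenshtein edit distance between state and goal

Unequal-length conventions (the task's strings change length freely): f1 is
computed over the positions of the state, with positions past the end of the
goal counting as mismatches; a lone symbol is a run of length 1, so f9/f10
are typically 1.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "FEATURE_NAMES",
    "STATE_ONLY",
    "GOAL_ONLY",
    "compute_features",
    "feature_matrix",
    "lcs_length",
    "levenshtein",
    "run_lengths",
]

FEATURE_NAMES = tuple(f"f{i}" for i in range(1, 14))

# ablation subsets: features carrying only state or only goal information
STATE_ONLY = ("f5", "f7", "f9", "f11")
GOAL_ONLY = ("f6", "f8", "f10", "f12")


def lcs_length(a: str, b: str) -> int:
    """Length of the longest common subsequence, by dynamic programming."""
    if not a or not b:
        return 0
    prev = np.zeros(len(b) + 1, dtype=np.int64)
    cur = np.zeros(len(b) + 1, dtype=np.int64)
    for ca in a:
        for j, cb in enumerate(b, start=1):
            if ca == cb:
                cur[j] = prev[j - 1] + 1
            else:
                cur[j] = max(prev[j], cur[j - 1])
        prev, cur = cur, prev
    return int(prev[-1])


def levenshtein(a: str, b: str) -> int:
    """Levenshtein edit distance (unit-cost insert/delete/substitute), by DP."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    prev = np.arange(len(b) + 1, dtype=np.int64)
    cur = np.zeros(len(b) + 1, dtype=np.int64)
    for i, ca in enumerate(a, start=1):
        cur[0] = i
        for j, cb in enumerate(b, start=1):
            cur[j] = min(
                prev[j] + 1,
                cur[j - 1] + 1,
                prev[j - 1] + (ca != cb),
            )
        prev, cur = cur.copy(), prev
    return int(prev[-1])


def run_lengths(s: str) -> list[int]:
    """Lengths of maximal runs of repeated symbols; a lone symbol is a run of 1."""
    if not s:
        return []
    runs = [1]
    for prev_c, c in zip(s, s[1:]):
        if c == prev_c:
            runs[-1] += 1
        else:
            runs.append(1)
    return runs


def compute_features(state: str, goal: str) -> dict[str, float]:
    """All 13 features of a (state, goal) pair, keyed ``f1`` .. ``f13``."""
    if not state or not goal:
        raise ValueError("state and goal must be non-empty strings")
    match = sum(
        1 for i, c in enumerate(state) if i < len(goal) and goal[i] == c
    )
    runs_s = run_lengths(state)
    runs_g = run_lengths(goal)
    return {
        "f1": match / len(state),
        "f2": float(len(state) - len(goal)),
        "f3": float(len(set(state)) - len(set(goal))),
        "f4": lcs_length(state, goal) / len(goal),
        "f5": float(len(state)),
        "f6": float(len(goal)),
        "f7": float(max(runs_s)),
        "f8": float(max(runs_g)),
        "f9": float(min(runs_s)),
        "f10": float(min(runs_g)),
        "f11": float(len(runs_s)),
        "f12": float(len(runs_g)),
        "f13": float(levenshtein(state, goal)),
    }


def feature_matrix(
    pairs: list[tuple[str, str]], subset: tuple[str, ...] = FEATURE_NAMES
) -> np.ndarray:
    """Feature design matrix (rows: pairs, columns: ``subset`` in order)."""
    rows = np.empty((len(pairs), len(subset)), dtype=float)
    for i, (s, g) in enumerate(pairs):
        f = compute_features(s, g)
        rows[i] = [f[name] for name in subset]
    return rows
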