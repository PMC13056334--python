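"""Engine semantics: rule application, enumeration, solution counting."""

from random import Random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import (
    brute_commutative,
    brute_count_minimal,
    brute_min_distance,
    random_small_instance,
)
from rewritelab.engine import (
    INFINITY,
    EnumerationCaps,
    Rule,
    Ruleset,
    apply_rule,
    count_minimal_solutions,
    enumerate_state_graph,
    has_commutative_transition,
    median_remaining_solution_length,
    ruleset_from_json,
    ruleset_to_json,
    rulesets_isomorphic,
    wrong_turn_everywhere,
)


class TestApplyRule:
    @pytest.mark.parametrize(
        "state, lhs, rhs, pos, expected",
        [
            ("XABY", "AB", "C", 1, "XCY"),
            ("XABY", "AB", "C", 0, None),
            ("AA", "A", "AA", 0, "AAA"),
            ("AB", "AB", "C", 0, "C"),
            ("AB", "B", "A", 1, "AA"),
            ("AB", "AB", "C", 1, None),  # lhs does not fit before the end
        ],
    )
    def test_substitution_semantics(self, state, lhs, rhs, pos, expected):
        assert apply_rule(state, Rule(0, lhs, rhs), pos) == expected

    def test_out_of_range_position_is_an_error_not_an_invalid_application(self):
        with pytest.raises(ValueError):
            apply_rule("AB", Rule(0, "A", "B"), 2)
        with pytest.raises(ValueError):
            apply_rule("AB", Rule(0, "A", "B"), -1)

    @given(st.data())
    @settings(max_examples=100, deadline=None)
    def test_untouched_outside_span_and_reverse_restores(self, data):
        rng = Random(data.draw(st.integers(0, 10_000)))
        alpha = "ABC"
        state = "".join(rng.choice(alpha) for _ in range(rng.randint(1, 6)))
        lhs = "".join(rng.choice(alpha) for _ in range(rng.randint(1, 2)))
        rhs = "".join(rng.choice(alpha) for _ in range(rng.randint(1, 2)))
        pos = rng.randrange(len(state))
        rule = Rule(0, lhs, rhs)
        out = apply_rule(state, rule, pos)
        if out is None:
            return
        assert out[:pos] == state[:pos]
        assert out[pos + len(rhs):] == state[pos + len(lhs):]
        assert apply_rule(out, rule.reversed(), pos) == state


class TestEnumeration:
    def test_two_symbol_flip_graph(self, ab_graph):
        assert ab_graph.nodes == {"AA", "AB", "BA", "BB"}
        assert ab_graph.distance_to_goal["AA"] == 2
        assert not ab_graph.truncated

    def test_start_equals_goal(self, ab_ruleset):
        g = enumerate_state_graph("AA", "AA", ab_ruleset)
        assert g.distance_to_goal["AA"] == 0
        assert "AA" in g.nodes

    def test_unreachable_goal_distance_infinite(self):
        rs = Ruleset.from_pairs([("B", "A")])
        g = enumerate_state_graph("A", "B", rs)
        assert g.distance_to_goal["A"] == INFINITY

    def test_truncation_flag_set_by_length_cap(self):
        rs = Ruleset.from_pairs([("A", "AA")])
        g = enumerate_state_graph(
            "A", "AAAA", rs, EnumerationCaps(max_depth=50, max_length=3)
        )
        assert g.truncated
        assert max(len(n) for n in g.nodes) <= 3

    def test_edges_are_exactly_the_valid_applications(self):
        rng = Random(5)
        for _ in range(30):
            start, goal, rs = random_small_instance(rng)
            caps = EnumerationCaps(max_depth=4, max_length=6, max_nodes=2000)
            g = enumerate_state_graph(start, goal, rs, caps)
            if g.truncated:
                continue
            for u in g.nodes:
                expected = {
                    (u, r.id, pos, out)
                    for r in rs.rules
                    for pos in range(len(u))
                    if (out := apply_rule(u, r, pos)) is not None
                }
                actual = {(u, rid, pos, v) for rid, pos, v in g.out_edges(u)}
                assert actual == expected

    def test_bfs_distance_matches_exhaustive_dfs(self):
        """Breadth-first distances agree with brute-force path enumeration."""
        rng = Random(11)
        checked = 0
        while checked < 60:
            start, goal, rs = random_small_instance(rng)
            caps = EnumerationCaps(max_depth=5, max_length=5, max_nodes=5000)
            g = enumerate_state_graph(start, goal, rs, caps)
            if g.truncated:
                continue
            d_bfs = g.distance_to_goal.get(start, INFINITY)
            d_dfs = brute_min_distance(start, goal, rs, 5, 5)
            assert d_bfs == d_dfs, (start, goal, rs.rules)
            checked += 1


class TestSolutionCounting:
    def test_two_orderings_of_independent_flips(self, ab_graph):
        assert count_minimal_solutions(ab_graph) == 2

    def test_single_path_chain(self, chain_graph):
        assert count_minimal_solutions(chain_graph) == 1

    def test_empty_solution_convention(self, ab_ruleset):
        g = enumerate_state_graph("AA", "AA", ab_ruleset)
        assert count_minimal_solutions(g) == 1

    def test_unreachable_goal_raises(self):
        rs = Ruleset.from_pairs([("B", "A")])
        g = enumerate_state_graph("A", "B", rs)
        with pytest.raises(ValueError):
            count_minimal_solutions(g)

    def test_counts_match_brute_force_on_random_instances(self):
        rng = Random(23)
        checked = 0
        while checked < 40:
            start, goal, rs = random_small_instance(rng)
            caps = EnumerationCaps(max_depth=5, max_length=5, max_nodes=5000)
            g = enumerate_state_graph(start, goal, rs, caps)
            d = g.distance_to_goal.get(start, INFINITY)
            if g.truncated or d == INFINITY or d == 0:
                continue
            assert count_minimal_solutions(g) == brute_count_minimal(
                start, goal, rs, int(d), 5
            )
            checked += 1


class TestMedianRemainingLength:
    def test_unique_path_median_is_its_length(self, chain_graph):
        assert median_remaining_solution_length("ABC", chain_graph) == 3

    def test_two_paths_of_two_and_four(self):
        # S -> G directly in 2 steps, or around in 4: built from a diamond
        rs = Ruleset.from_pairs(
            [("S", "M"), ("M", "G"), ("S", "P"), ("P", "Q"), ("Q", "R"), ("R", "G")]
        )
        g = enumerate_state_graph("S", "G", rs)
        assert median_remaining_solution_length("S", g, path_cap=6) == 3

    def test_dead_end_is_infinite(self, ab_graph):
        # BB is the goal; from BA the goal is reachable, but from "BB" with a
        # different goal nothing applies.  Use a state that cannot reach goal.
        rs = Ruleset.from_pairs([("A", "B")])
        g = enumerate_state_graph("AB", "AA", rs)
        assert median_remaining_solution_length("BB", g) == INFINITY


class TestCommutativeTransitions:
    def test_independent_positions_commute(self, ab_graph):
        assert has_commutative_transition(ab_graph)

    def test_linear_chain_does_not(self, chain_graph):
        assert not has_commutative_transition(chain_graph)

    def test_convergence_via_different_rule_pairs_is_not_commutative(self):
        # two 2-step routes meet at the same state but use different rules
        rs = Ruleset.from_pairs(
            [("S", "A"), ("A", "G"), ("S", "B"), ("B", "G")]
        )
        g = enumerate_state_graph("S", "G", rs)
        assert not has_commutative_transition(g)

    def test_agrees_with_brute_force_scan(self):
        rng = Random(37)
        checked = 0
        while checked < 40:
            start, goal, rs = random_small_instance(rng)
            caps = EnumerationCaps(max_depth=4, max_length=5, max_nodes=2000)
            g = enumerate_state_graph(start, goal, rs, caps)
            if g.truncated:
                continue
            assert has_commutative_transition(g) == brute_commutative(g)
            checked += 1


class TestWrongTurns:
    def test_linear_chain_has_no_wrong_turns(self, chain_graph):
        assert not wrong_turn_everywhere(chain_graph)

    def test_chain_with_dead_end_everywhere(self):
        # each on-path state also admits a move into a dead end (X is inert)
        rs = Ruleset.from_pairs([("A", "B"), ("B", "C"), ("A", "X"), ("B", "X")])
        g = enumerate_state_graph("A", "C", rs)
        assert wrong_turn_everywhere(g)

    def test_start_equals_goal_vacuously_true(self, ab_ruleset):
        g = enumerate_state_graph("AA", "AA", ab_ruleset)
        assert wrong_turn_everywhere(g)

    def test_unreachable_goal_raises(self):
        rs = Ruleset.from_pairs([("B", "A")])
        g = enumerate_state_graph("A", "B", rs)
        with pytest.raises(ValueError):
            wrong_turn_everywhere(g)


class TestRulesetIsomorphism:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ([("A", "B")], [("C", "D")], True),
            ([("A", "B")], [("C", "C")], False),
            ([("AB", "A"), ("B", "AB")], [("XY", "X"), ("Y", "YX")], False),
            ([("AB", "A"), ("B", "AB")], [("YX", "Y"), ("X", "YX")], True),
        ],
    )
    def test_examples(self, a, b, expected):
        ra = Ruleset.from_pairs(a, "a")
        rb = Ruleset.from_pairs(b, "b")
        assert rulesets_isomorphic(ra, rb) is expected

    def test_symmetry(self):
        rng = Random(3)
        for _ in range(20):
            _, _, ra = random_small_instance(rng)
            _, _, rb = random_small_instance(rng)
            assert rulesets_isomorphic(ra, rb) == rulesets_isomorphic(rb, ra)


def test_ruleset_json_round_trip():
    rs = Ruleset.from_pairs([("AB", "C"), ("C", "AB")], "demo")
    assert ruleset_from_json(ruleset_to_json(rs)) == rs
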