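"""Rule application and bounded state-space analysis of a tiny task.

Builds the one-rule system {A -> B}, enumerates every state reachable from
"AA", and reports the quantities that drive task difficulty: distance to
goal, the number of distinct minimal solutions, and whether the graph
contains commutative transitions (the same two rule applications reaching
one state in either order).
"""

from rewritelab import (
    Rule,
    Ruleset,
    apply_rule,
    count_minimal_solutions,
    enumerate_state_graph,
    has_commutative_transition,
    wrong_turn_everywhere,
)

rule = Rule(0, "A", "B")
print('apply A->B to "XABY" at 1:', apply_rule("XABY", Rule(0, "AB", "C"), 1))
print('apply A->B to "XABY" at 0:', apply_rule("XABY", Rule(0, "AB", "C"), 0))

ruleset = Ruleset.from_pairs([("A", "B")], id="demo")
graph = enumerate_state_graph("AA", "BB", ruleset)
print("\nreachable states:", sorted(graph.nodes))
print("distance from AA to BB:", graph.distance_to_goal["AA"])
print("distinct minimal solutions:", count_minimal_solutions(graph))
print("commutative transition present:", has_commutative_transition(graph))
print("wrong turn available everywhere:", wrong_turn_everywhere(graph))

# The two minimal solutions flip the two A's in either order, which is
# exactly a commutative transition — a task like this would be rejected by
# the study-grade difficulty filter.  No state offers a wrong turn (every
# move stays on a shortest path), its second disqualification.
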