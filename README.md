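# rewritelab

A Python workbench for **string-transformation problem-solving experiments**
and the analysis of **transfer of learning** between tasksets that share no
transformation rules.

In a transformation problem, a solver turns a start string into a goal
string by repeatedly applying rewrite rules `lhs -> rhs` at chosen
positions.  Two broad mechanism classes are thought to underlie skill on
such tasks: *pattern-recognition and association* (learned mappings from
recognised state patterns to specific rules — inherently rule-bound) and
*heuristic search* guided by a **state-value function**

```
v(s, g) = expit( β₀ + Σᵢ βᵢ · fᵢ(s, g) )        i = 1..13
```

where the `fᵢ` are features of the state/goal pair only (positional match
proportion, length difference, longest common subsequence, symbol runs,
Levenshtein distance, ...).  Because no `fᵢ` mentions any rule, a learned
`v` can in principle be reused on a taskset with entirely different rules —
heuristic search predicts transfer where pattern-association does not.
`rewritelab` implements everything needed to study this contrast end to end:

- **`rewritelab.engine`** — exact task semantics: rule application, capped
  breadth-first state-space enumeration, distance-to-goal maps, minimal
  solution counting, commutative-transition and wrong-turn analysis,
  ruleset isomorphism (symbol-relabelling) testing.
- **`rewritelab.taskgen`** — generation of non-isomorphic 5-rule ruleset
  pairs and balanced 72-task tasksets meeting printed difficulty criteria
  (2–4 distinct minimal solutions; minimal lengths 4/5/6 in equal counts;
  goals ≥ 3 symbols; a possible wrong turn at every on-path state; no
  commutative transitions), with an independent verifier; trial scoring
  `floor(10 · remaining_seconds / steps)`.
- **`rewritelab.features` / `rewritelab.transfer`** — the 13-feature
  representation, binary reachability ground truth, balanced sampling
  (400/400), and 30-fold cross-validated logistic fits reporting held-out
  *test* accuracy and whole-other-taskset *generalisation* accuracy, with
  `state_only` / `goal_only` ablations.
- **`rewritelab.metrics`** — behavioural measures from timestamped event
  logs: attempt extraction, between-rule (decision) times, action-sequence
  optimality and efficiency, paired-comparison strategy-weight conversion,
  running-span working-memory scoring, cursor speeds, exclusion filters.
- **`rewritelab.cohort`** — a synthetic participant simulator producing the
  full four-session study dataset (event logs, strategy surveys, span
  trials) under either mechanism, with transfer switched on or off.
- **`rewritelab.stats`** — participant-level percentile-bootstrap tests,
  per-participant logistic learning-rate contrasts, and model-ready block
  tables.

## Worked example

`examples/05_cohort_pipeline.py` simulates two 30-agent cohorts on the same
generated taskset pair and asks whether the post-training probe improvement
exceeds what direct practice alone provides:

```
heuristic agents (transfer on):
  solution rate by block: p1=0.13  t1=0.16  t2=0.20  t3=0.26  t4=0.25  t5=0.38  t6=0.35  p2=0.37
  excess probe gain (p2-p1)-(t2-t1) = +0.200, p = 0.0002 -> transfer FLAGGED

associative agents (transfer off):
  solution rate by block: p1=0.12  t1=0.09  t2=0.12  t3=0.12  t4=0.15  t5=0.24  t6=0.20  p2=0.14
  excess probe gain (p2-p1)-(t2-t1) = -0.019, p = 0.5783 -> transfer not flagged
```

`p1`/`p2` are the pre/post-training probe blocks on the *untrained*
ruleset; `t1..t6` the training blocks.  The heuristic cohort carries its
learned value model into `p2` and jumps far above its `p1` baseline; the
associative cohort improves only on the trained material, and the
participant-level bootstrap contrast stays at zero.

`examples/03_state_value_transfer.py` shows the transfer analysis itself
(chance = 0.50 on class-balanced samples):

```
all         test median 0.846   generalisation median 0.917
state_only  test median 0.692   generalisation median 0.755
goal_only   test median 0.538   generalisation median 0.545
```

The full model keeps its accuracy on the unseen taskset; the goal-only
ablation collapses toward chance, because reachability is a property of the
state–goal *combination*.

The other examples cover the engine (`01`), taskset generation and
verification (`02`), and the behavioural measures on a hand-traceable
three-participant fixture log (`04`).

## Scope

The two rulesets used in the original behavioural study are not available
in machine-readable form, so generated stand-in rulesets (same structure,
verified non-isomorphic) are used throughout; a JSON loader accepts
transcribed rulesets should they be available.  Hierarchical Bayesian
trial-level models are out of scope — the block/trial tables are exported
for external fitting, and a simpler two-stage learning-rate contrast is
provided in-repo.  See `docs/methods.md` for the model details, parameter
choices and limitations.
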