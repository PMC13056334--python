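# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `rewritelab`.  Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Task semantics and state-space analysis

A rule `lhs -> rhs` applied at 0-based position `p` of state `s` succeeds
iff `p + |lhs| <= |s|` and `s[p : p+|lhs|] == lhs`; the span is replaced by
`rhs`.  A failed match is an *invalid application* — a modelled in-task
event (the interface plays a "shake" animation) — whereas an out-of-range
position is a programming error and raises.

State graphs are built by breadth-first enumeration from the start string
under explicit caps (search depth, string length, node count), because
rewriting systems can grow without bound.  The graph records every valid
application between enumerated states, the BFS depth of each state, and a
distance-to-goal map obtained by reverse BFS over the enumerated edges.  A
`truncated` flag marks any cap hit; labels from truncated graphs are never
used for ground truth.

Derived analyses:

- **Minimal solution counting** — dynamic programming over the shortest-path
  DAG; sequences are distinct if they differ in any (rule, position) step,
  so parallel edges count separately.  `start == goal` counts one empty
  solution (a documented convention for degenerate fixtures).
- **Median remaining solution length** — the median length of all *acyclic*
  solution paths from a state, capped at `distance + 6` by default (the
  unrestricted set is infinite); states with no path score infinity.
- **Commutative transitions** — a state pair `u, w` connected by the same
  two (rule, position) applications in both orders.  Checked exactly over
  all length-2 path pairs.
- **Wrong turns** — "on-path" means on a minimal solution path from the
  start; a wrong turn from `u` is a successor `v` with
  `distance(v) != distance(u) − 1` (including dead ends).  The alternative
  reading (successor with *no* path to the goal at all) would make the
  difficulty criterion far more restrictive than example task graphs
  suggest.
- **Ruleset isomorphism** — exhaustive search over alphabet bijections
  mapping one rule multiset onto the other (LHS→LHS, RHS→RHS); exact and
  fast at task-scale alphabets.

## Taskset generation

Study-grade materials are two 5-rule rulesets with identical `(|lhs|,
|rhs|)` structure profiles, verified non-isomorphic, each carrying 72 tasks
balanced 24/24/24 over minimal lengths {4, 5, 6}, every task satisfying:
2–4 distinct minimal solutions, goal length ≥ 3, a wrong turn available at
every on-path state, and no commutative transitions.

The default structure profile is **strictly length-decreasing**:
`(2,1) ×3, (3,1) ×2` on a 3-symbol alphabet (disjoint alphabets for the two
rulesets; a shared-alphabet mode exists).  This choice has three
consequences that make generation sound and fast:

1. every reachable state is no longer than the start, so the state space is
   finite and enumeration is *exact* — generated difficulty metadata never
   depends on a truncation cap;
2. two applications at disjoint positions shift each other's positions
   (each application changes the length), so commutative transitions are
   rare by construction rather than by heavy rejection;
3. dead ends (states shrunk past recoverability) are plentiful, giving both
   the wrong-turn property and a rich supply of negative reachability
   labels.

Start strings are sampled with lengths 11–15 (a shrink-only system needs
`|start| ≥ |goal| + distance`; the length range is otherwise unstated in
the study materials).  Goals are chosen among enumerated states at the
target distance, which guarantees solvability and exact minimal length.
Candidate rulesets are screened for viability (able to produce at least one
task per required length) before taskset generation, and generation fails
loudly after an attempt budget rather than relaxing any criterion.  An
independent verifier re-enumerates every emitted task from scratch and
re-checks every criterion; it is the generator's acceptance oracle.

Trial scores follow the task's scoring rule,
`floor(10 · remaining_seconds / steps)`, with a 75 s trial limit.

## The state-value heuristic and transfer

Ground-truth state value is binary reachability: 1 iff the task's goal is
reachable from the state.  Every enumerable state of every task is
labelled, de-duplicated on (state, goal), and sampled class-balanced
(400/400 in study-emulation mode).  The value model is an unpenalised
binomial GLM on the 13 features; on perfect separation it falls back to an
L2 penalty of 10⁻⁶ and flags the fit (no Wald p-values are reported for
flagged folds).  Evaluation uses label-stratified 30-fold cross-validation:
per fold, accuracy at threshold 0.5 on the held-out fold (*test*) and on
the entire other-taskset sample (*generalisation*); medians and quartiles
are reported across folds.  Ablations: `state_only` = {f5, f7, f9, f11},
`goal_only` = {f6, f8, f10, f12}.

Feature conventions where string lengths differ (the field definition is
positional): f1's denominator is the length of the current state, and
positions past the end of the goal count as mismatches; a lone symbol is a
run of length 1, so the shortest-run features are typically 1.  f13 is
implemented as the standard unit-cost Levenshtein dynamic program and is
cross-checked against an external alignment library in tests.

On generated materials the goal-only ablation can sit somewhat above
chance (goal length correlates with a task's label base rate); the
qualitative ordering all ≥ state-only ≥ goal-only, with goal-only near
chance in median, is the property the package asserts.  The exact
accuracies reported for the original study's materials are not reproducible
here because those two rulesets are not available in machine-readable form;
a JSON loader accepts them if transcribed.

## Behavioural measures

Event logs are JSON-Lines, one trial per line, with timestamped
`rule_activate` / `symbol_activate` / `state_change` / `undo` / `reset` /
`click` events.  An *attempt* is a maximal rule + symbol activation pair in
either order; a following `state_change` marks it valid.  Re-selections
(two same-kind activations) discard the earlier event with a warning.

- **Between-rule time** uses the gap convention — start of attempt *k+1*
  minus end of attempt *k*, i.e. idle/decision time between completed
  attempts; an end-to-end convention is available by switch, as the
  phrasing of the measure admits both.
- **Optimality** (`minimal_distance` mode, solved trials only): a visited
  state scores optimal iff the number of successful applications remaining
  equals its distance to goal.  **Efficiency** (`median_group` mode):
  states are grouped by their median remaining solution length; the
  observed length counts valid *and* invalid attempts, ignoring undo/reset;
  unsolved trials count every visited state as a failure.  The two modes
  answer different questions and are never conflated.
- **Strategy weights** convert the three pairwise preferences via
  `w_t = xy/(1−x+xy)`, `w_w = w_t(1−x)/x`, `w_i = w_w(1−y)/y`; the weights
  sum to 1 identically and are invariant to the third preference `z`
  (which functions as a consistency check in the survey).  Inputs of
  exactly 0/1 are clamped to 0.01/0.99, as the conversion assumes
  non-extreme values.
- **Working-memory score**: per-offset correctness (offset 0 = final
  digit; the typed response is right-aligned against the sequence tail,
  since response alignment is otherwise undefined) is fitted with a
  binomial GLM on offset; the score is the offset where the curve crosses
  chance (1/9), clamped to [0, max offset], plus one.  Degenerate cases are
  flagged: non-decreasing curves and all-correct responders score
  `max offset + 1`; all-wrong responders score 1.
- **Exclusions**: a participant is kept iff every session has ≥ 1 solved
  trial and a fitted offset-0 recall probability above 1/9.
- **Cursor speed**: straight-line distance between an attempt's two click
  coordinates over their time difference; zero time deltas are skipped with
  a warning.

## Synthetic cohorts

The simulator emulates the study schedule exactly: four sessions × two
12-trial problem-solving blocks + one 20-trial span block; p1 = first block
of session 1 (untrained taskset), t1..t6 = the six training blocks covering
all 72 trained tasks once, p2 = final block (untrained tasks not shown in
p1).  Agents alternate counterbalance groups A/B.

Two mechanisms:

- **Associative** — strengths over (rule id, flanking symbols) patterns,
  reinforced along realised solution paths by a delta rule
  (`q += α(1 − q)`, α = 0.5, softmax temperature 0.25).  Keying on local
  patterns rather than whole states lets learning generalise across tasks
  *within* a ruleset while remaining meaningless for a different ruleset —
  the defining property of the mechanism class.
- **Heuristic** — successors scored by the 13-feature value model with a
  2-step lookahead (the score of a candidate is the best value in its
  shallow search cone, minus a small per-step penalty), softmax temperature
  0.3.  After each trial the coefficients take logistic SGD steps
  (α = 0.7, three replay passes) toward each visited state's realised
  outcome: on a solved trial, states on the final post-reset trajectory
  segment are labelled 1 and earlier explored states 0; on a failed trial
  everything visited is 0.  When transfer is enabled the learned
  coefficients are carried into the post-training probe; otherwise probe
  blocks start from naive coefficients.

Decision times are log-normal (location log 2.2 s, scale 0.45) with a
location that declines 0.0004 per cumulative attempt **on that ruleset**,
compounding to roughly the 40–50 % preparation-time practice effect the
study design targets.  The per-ruleset counter matters: with a global
counter the late-study speed-up mechanically inflates post-training probe
solution rates (more attempts fit into 75 s) and masquerades as transfer.
Occasional invalid applications occur at rate 0.08; dead ends trigger a
reset.  Click coordinates come from a fixed screen layout plus Gaussian
jitter.  Mechanism learning rates and temperatures were set so that
training-block solution curves rise steadily from a baseline near 0.15,
the novice regime the study design targets, and then frozen.

Span sequences (12–21 digits from 1–9) enforce the three design
constraints — no digit more than three times, no digit more than twice in
any window of six, no numerically consecutive neighbours — and are checked
by an independent validator.  Simulated recall follows
`1/9 + 8/9 · expit(capacity − offset)` with errors drawn from the eight
wrong digits, so offset-0 accuracy exceeds chance for any positive
capacity.

What the simulator does *not* emulate: fatigue/boredom dynamics, strategy
switching within participants, working-memory load interacting with task
difficulty, cursor trajectories between clicks (only endpoints), and any
fitting of agent parameters to human data.  Passing pipeline tests on
simulated cohorts therefore demonstrates the *internal consistency and
discriminative power* of the analysis chain, not the behaviour of human
participants.

## Inference

Block contrasts use participant-level percentile bootstrap tests:
resampling participants with replacement (paired differences, or the two
groups independently in unpaired mode), two-sided
`p = 2 · min(P(θ* ≤ 0), P(θ* ≥ 0))` with the add-one finite-resample
correction, 10,000 resamples by default.  This construction is mildly
anti-conservative at n = 30 (measured type-I error ≈ 0.06 at nominal 0.05);
the calibration is itself asserted in the acceptance suite.

The trial-level probe-vs-training comparison is a deliberately simple
two-stage surrogate for hierarchical modelling: per participant and
condition, a logistic slope of success on cumulative trial number
(all-success/all-failure cells get a small-ridge fit via direct penalised
likelihood and are flagged), then a participant-level bootstrap interval on
the mean probe − training slope difference.  Transfer detection asks
whether the per-participant (p2 − p1) − (t2 − t1) difference in solved
proportion — probe improvement in excess of early-training direct
practice — is positive and significant.  Hierarchical Bayesian models are
intentionally out of scope; `build_block_table` exports the model-ready
tables (block codes 0/1 for probes, 2–7 for training; strategy weights;
per-session WM scores; block × strategy interactions) for external tools.

## Numerical and degenerate-input choices

- GLM fits: statsmodels binomial GLM (IRLS); perfect separation (warning or
  divergence) triggers a flagged ridge refit (scikit-learn L2 for value
  models, direct penalised Newton/BFGS for one-class slope cells).
- Accuracy threshold fixed at 0.5 — canonical for class-balanced samples.
- Fold assignment, sampling and simulation are all driven by explicit
  seeded generators; identical seeds give byte-identical tasksets and
  datasets (collections are iterated in sorted order before shuffling, so
  results do not depend on Python's per-process hash randomisation).
- Enumeration caps default to depth 10, length `2·max(|start|, |goal|, 8)`,
  200,000 nodes; generators use tighter task-shaped caps and *reject*
  truncated graphs.

## Problem sizes used by the packaged checks

The test suite and acceptance script run on sizes chosen to exercise the
full design while completing comfortably on one CPU: 200 random instances
for engine/brute-force agreement, one full 72 + 72 task pair for generator
verification, ten seeded pairs with 400/400 samples and 30-fold CV for the
transfer pattern, 1,000 sequences and 30 simulated responders for the span
components, 2,000 null replications for bootstrap calibration, 20 seeded
slope cohorts (30 participants × 72 trials per condition) for sign
recovery, and two 30-agent cohorts for the end-to-end discrimination.
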