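"""Behavioural measures from a hand-traceable event log.

Loads the packaged three-participant fixture log (one minimal solver, one
solver who takes a recoverable wrong turn plus an invalid attempt, one
participant who times out) and computes the measures the analysis pipeline
uses: between-rule decision times, cursor speeds, action-sequence
optimality by distance, strategy weights, and the working-memory score.
"""

from rewritelab import between_rule_times, cursor_speed, optimality_stats
from rewritelab.fixtures import fixture_graph, three_participant_trials
from rewritelab.metrics import WMOutcome, strategy_weights, wm_score

trials = three_participant_trials()
graphs = {("ABC", "XYZ"): fixture_graph()}

for tr in trials:
    times = between_rule_times(tr)
    print(f"{tr.participant}: solved={tr.solved} steps={tr.steps} "
          f"score={tr.score} between-rule times={times} "
          f"cursor speed={cursor_speed(tr):.0f} px/s")

print("\noptimality by distance (solved trials, minimal-length criterion):")
print(optimality_stats(trials, graphs, "minimal_distance").to_string(index=False))

rep = strategy_weights(x=0.5, y=0.5, z=0.5)
print(f"\nstrategy weights for indifferent pairwise reports: "
      f"try-and-see={rep.w_t:.3f} work-it-out={rep.w_w:.3f} "
      f"intuition={rep.w_i:.3f} (sum {rep.w_t + rep.w_w + rep.w_i:.0f})")

seq = "124961245793"
score, _ = wm_score([WMOutcome(sequence=seq, response=seq[-5:])] * 10)
print(f"working-memory score of a perfect final-5 responder: {score:.2f}")
# The score is the offset (from the end of the digit sequence) at which the
# fitted recall curve drops below chance (1/9), plus one.
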