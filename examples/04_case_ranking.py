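"""Full ZE-MABAC ranking of the bundled medicinal-plant-extraction case.

Runs the published 30-failure-mode decision matrix through normalization,
weighting, border-approximation, distances and scoring, and prints the five
most and least critical failure modes.  Rank 1 is the highest risk.
"""

from zefmea import load_case_study, run_ze_pipeline

case = load_case_study()
weights = case.mean_weights()  # mean of the three experts' fuzzy BWM weights

audit: dict = {}
result = run_ze_pipeline(case.initial_matrix, weights, collect=audit)

desc = {fm.id: fm.description for fm in case.session.failure_modes}
frame = result.to_frame().sort_values("rank")

print("Top 5 risks (largest distance above the border approximation area):")
for r in frame.head(5).itertuples(index=False):
    print(f"  rank {r.rank:2d}  {r.alternative:<4} score={r.score:+.3f}  {desc[r.alternative][:60]}")

print("\nBottom 5 risks:")
for r in frame.tail(5).itertuples(index=False):
    print(f"  rank {r.rank:2d}  {r.alternative:<4} score={r.score:+.3f}  {desc[r.alternative][:60]}")

# the fuzzy score of an alternative sitting exactly on the border would have
# centroid 0; positive scores are above-border (critical), negative below
baa = audit["baa"]
print("\nborder approximation area per criterion:")
for c in case.initial_matrix.criteria:
    g = baa[c]
    print(f"  {c}: ({g.l:.3f}, {g.m:.3f}, {g.u:.3f})")
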