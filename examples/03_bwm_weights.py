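"""Fuzzy Best-Worst criterion weights from linguistic comparison vectors.

Solves the fuzzy BWM program for each decision-maker of the bundled case
study (Severity / Occurrence / Detection) and aggregates the three weight
vectors into the mean weights used by the ranking pipeline.
"""

from zefmea import aggregate_expert_weights, importance_scale, load_case_study, solve_fuzzy_bwm

case = load_case_study()
scale = importance_scale()

solutions = []
for expert, cv in case.session.comparisons.items():
    sol = solve_fuzzy_bwm(cv, scale, n_starts=32, seed=0)
    solutions.append(sol)
    g = sol.defuzzified()
    order = " > ".join(sorted(g, key=g.get, reverse=True))
    print(f"{expert}: best={cv.best} worst={cv.worst}  "
          f"weights={{{', '.join(f'{c}: {v:.3f}' for c, v in g.items())}}}  "
          f"xi*={sol.xi_star:.3f}  CR={sol.cr:.3f} "
          f"({'consistent' if sol.acceptable else 'inconsistent'})  [{order}]")

# each expert's defuzzified weights sum to 1; the consensus ratio flags
# how far the weights are from exactly reproducing the stated comparisons
mean = aggregate_expert_weights(solutions)
print("\nmean fuzzy weights (GMIR-renormalised):")
for c, w in mean.items():
    print(f"  {c}: ({w.l:.3f}, {w.m:.3f}, {w.u:.3f})  gmir={w.gmir():.3f}")
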