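"""Synthetic expert panels: dominance planting and Z- vs ZE-variant agreement.

Generates a seeded synthetic elicitation session with one planted dominant
failure mode, converts the judgments under both the Z (individual
reliability only) and ZE (consensus-adjusted) variants, and compares the
resulting rankings by Spearman correlation.
"""

from zefmea import (
    assemble_matrix,
    compare_rankings,
    generate_synthetic_panel,
    load_case_study,
    run_ze_pipeline,
    session_to_matrices,
)

session = generate_synthetic_panel(
    n_alternatives=12, n_experts=3, panel_size=12, seed=7,
    profile="dominant-alternative",
)
weights = load_case_study().mean_weights()

rankings = {}
for variant in ("ze", "z"):
    per_expert = session_to_matrices(session, variant=variant)
    initial = assemble_matrix(list(per_expert.values()))
    rankings[variant] = run_ze_pipeline(initial, weights)
    print(f"{variant.upper():>2} variant: planted dominant alternative A1 "
          f"ranked {rankings[variant].rank_of('A1')} of {len(session.failure_modes)}")

rho = compare_rankings(rankings["ze"], rankings["z"])
print(f"\nSpearman correlation between ZE and Z rankings: {rho:.3f}")
print("consensus adjustment reshuffles mid-field alternatives but the planted")
print("dominant mode stays on top under both variants")
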