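"""Generate a random instance, corrupt it, and measure repair + recovery.

A random 6-node model produces a consistent synchronous trajectory; 5% of
cells are then flipped and, separately, 20% deleted.  The search reports the
minimal number of repairs explaining the corrupted data, and the witness
completion is scored against the original values of the deleted cells.
"""

from boolrepair import (
    GenConfig,
    check_consistency,
    delete_values,
    generate_series,
    perturb,
    prediction_rate,
    random_model,
    repair_minimal,
)

cfg = GenConfig(n_nodes=6, arity_lambda=2.0, seed=21)
model = random_model(cfg)
series = generate_series(model, "sync", steps=5, seed=22)
print("clean series: k* =", repair_minimal(model, series, "sync").cardinality)

noisy, flips = perturb(series, 0.05, seed=23)
result = repair_minimal(model, noisy, "sync", max_cardinality=2)
if result.status == "optimal":
    print(f"after flipping {len(flips)} cells: k* = {result.cardinality}, "
          f"{len(result.solutions)} minimal solution(s)")
    for sol in result.solutions:
        print("  ", "; ".join(str(r) for r in sol.sorted_repairs()))
else:
    # a flip can demand behaviour no monotone edit of the target's function
    # realizes — with complete data that is a genuine infeasibility
    print(f"after flipping {len(flips)} cells: {result.status}")

thin, mask = delete_values(series, 0.2, seed=24)
report = check_consistency(model, thin, "sync")
completion = report.experiments[thin.experiment].completion
rate = prediction_rate(series, completion, mask)
print(f"deleted {len(mask)} cells; recompletion error = {rate:.1f}% of deleted cells")

# A clean trajectory needs no repairs (k* = 0).  Flipped cells force the
# search to edit functions; deleted cells are recompleted by the dynamics,
# and the error rate counts only the deleted positions, not the whole matrix.
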