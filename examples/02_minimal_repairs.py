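"""Enumerate all cardinality-minimal repairs of an inconsistent model.

At steady state with b=1, c=0, d=1, the function d = b & c cannot explain
d's value.  Exactly three single repairs fix it: negate c, remove c, or turn
the conjunction into a disjunction.
"""

from boolrepair import (
    common_repairs,
    parse_model,
    parse_timeseries,
    repair_minimal,
    write_model,
)

model = parse_model("d = b & c\n")
series = parse_timeseries("comp\t0\nb\t1\nc\t0\nd\t1\n", experiment="e1")

result = repair_minimal(model, series, "steady", kinds="nsr")
print(f"status: {result.status}; minimal cardinality k* = {result.cardinality}")
for sol in result.solutions:
    repairs = "; ".join(str(r) for r in sol.sorted_repairs())
    print(f"  repair set [{repairs}] ->", write_model(sol.model).splitlines()[-1])

print(common_repairs(result.solutions).to_string(index=False))

# Each line shows one minimal repair set and the repaired function it
# produces (unminimized, as exported).  The frequency table reports how
# often each atomic repair appears across the solutions — here each of the
# three repairs occurs in exactly one of three solutions (33.33%).
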