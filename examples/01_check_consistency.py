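"""Check a small Boolean model against a time series under each scheme.

The model is a two-gene chain b = a.  The first series follows the dynamics
(b at step 1 equals a at step 0); the second contradicts it at (b, 1).
"""

from boolrepair import check_consistency, parse_model, parse_timeseries

model = parse_model("b = a\n")
good = parse_timeseries("comp\t0\t1\na\t1\t1\nb\t0\t1\n", experiment="good")
bad = parse_timeseries("comp\t0\t1\na\t1\t1\nb\t0\t0\n", experiment="bad")

for ts in (good, bad):
    report = check_consistency(model, ts, "sync")
    print(report.summary())

# The 'good' run prints "consistent": b's observed value at step 1 equals
# K_b applied to column 0.  The 'bad' run localizes the contradiction to
# the single observation (b, t=1) that no completion can explain.
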