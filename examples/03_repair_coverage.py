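"""Which Boolean functions can repairs reach from a two-input conjunction?

Starting from f = A & B and combining sign negation (n), operator
substitution (s) and regulator removal (r), twelve distinct functions are
reachable.  xor, nxor and the two constants are not: the repairs preserve
monotonicity and never empty a function.
"""

from boolrepair import reachable_functions, truth_table_diff
from boolrepair.boolean_core import DNFFunction, RegulatorLiteral as L

AB = DNFFunction("f", (frozenset({L("A"), L("B")}),))

for kinds in ("", "r", "s", "n", "nsr"):
    reach = reachable_functions(AB, kinds)
    print(f"kinds={kinds or '(none)':5s} -> {len(reach):2d} reachable functions")

# Impact of one removal on the truth table: dropping a from
# K_d = (!a & b) | (!a & !c) leaves b | !c, which differs on 3 of the
# 8 assignments of {a, b, c}.
KD = DNFFunction(
    "d",
    (frozenset({L("a", False), L("b")}), frozenset({L("a", False), L("c", False)})),
)
reduced = DNFFunction("d", (frozenset({L("b")}), frozenset({L("c", False)})))
print("rows changed by removing a:", truth_table_diff(KD, reduced), "of 8")
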