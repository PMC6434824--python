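# boolrepair

Consistency checking and cardinality-minimal repair of Boolean logical
models of signalling-regulatory networks against time-series data.

Boolean models describe each regulatory component `g_i` by a logical
function `K_i` of its regulators, written in disjunctive normal form over
signed literals (an activator appears plain, an inhibitor negated).  As new
time-series observations arrive, a curated model may no longer explain
them.  `boolrepair` localizes such inconsistencies and enumerates **all**
minimal sets of *atomic repairs* that restore consistency, under a
steady-state, synchronous, or asynchronous updating scheme:

- **n** — negate a regulator: flip the sign of all its occurrences in one
  function (inhibitor ↔ activator);
- **s** — substitute an operator: toggle one `and`/`or` node;
- **r** — remove a regulator: delete all its occurrences (removing the last
  regulator is forbidden — the component would degenerate into an input).

The network structure is never extended, and the search space is restricted
to monotone non-degenerate functions: every regulator keeps a single sign
and affects the output in at least one state.  Functions are normalized on
load to their complete prime-implicant set (the Blake canonical form, via
Quine–McCluskey), so equivalent functions share the same repairs.  The best
repair is the one with the fewest operations (cardinality-minimal), not the
one with the smallest truth-table impact; all minimal solutions are
reported.  Missing observations are completed existentially by the chosen
dynamics, and under the asynchronous scheme the search interleaves repair
choice with the *visit schedule* — the order in which each component is
validated once per time step.

Intended users: systems-biology modellers revising logical models against
new expression data, and method developers who need a reference
implementation of model revision with exhaustive minimal-solution
enumeration.

## Worked example

A component `d` governed by `d = b & c` is observed at steady state with
`b=1, c=0, d=1` — the conjunction cannot explain `d`.  Running

```bash
python examples/02_minimal_repairs.py
```

prints

```
status: optimal; minimal cardinality k* = 1
  repair set [n d c] -> d = (b & !c)
  repair set [r d c] -> d = b
  repair set [s d n0] -> d = b | c
kind target locus   percent
   n      d     c 33.333333
   r      d     c 33.333333
   s      d    n0 33.333333
```

One repair suffices (`k* = 1`) and exactly three single repairs work:
negating `c`, removing `c`, or turning the `and` into an `or`.  Each line
shows the repaired function as it is exported (unminimized).  The frequency
table — useful when many solutions exist — reports how often each atomic
repair occurs across solutions.

The same workflow is available from the shell:

```bash
boolrepair check model.txt series.tsv --scheme steady
boolrepair repair model.txt series.tsv --scheme steady --out solutions/
boolrepair generate --nodes 10 --lam 1 --steps 3 --seed 7 --out fixtures/
```

`check` exits 0/1/2 for consistent/inconsistent/undecided; `repair` writes
every minimal solution as a model file, a repair log and witness series.
The other examples cover consistency checking (`01`), the reachable-function
coverage of the repair operations (`03`), and a synthetic corruption /
recovery benchmark (`04`).

## Model and data formats

Models are line-oriented DNF (boolSim-style): `target = (!a & b) | (!a & !c)`,
with `#` comments; components never appearing on a left-hand side are
inputs (constant values), or can be declared with `input x`.  Time series
are tab/comma-separated matrices, one row per component, header `0..T`,
blank or `?` for missing values; one file per experiment.

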