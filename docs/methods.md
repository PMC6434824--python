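# Methods

## Model class

A Boolean logical regulatory graph has components `G = {g_1..g_n}`, signed
edges derived from function literals, and one logical function `K_i` per
non-input component.  Components without regulators are *inputs* and hold a
constant value per experiment.  Functions live in the monotone
non-degenerate fragment: each regulator occurs with a single sign and is
essential (flipping it changes the output in at least one state).  This
restriction cuts the 2^(2^n) function space down to the biologically
interpretable unate functions; xor-like behaviour is excluded by
construction, and the three repair operations preserve the fragment.

Internally every function is an operator tree (`or` / `and` / `identity`
over signed literals) so that operator-substitution repairs have an
addressable locus; DNF is the I/O form.  Operator nodes carry stable
preorder ids (`n0, n1, ...`), which keeps repair loci valid across
transformations.

## Normalization

Structurally different but equivalent functions must receive identical
repairs, so parsing normalizes every function to the disjunction of **all**
its prime implicants (Blake canonical form, computed with the
Quine–McCluskey combination step) with clauses and literals in lexicographic
order.  The complete prime-implicant set is used rather than a minimal
cover because covering is non-unique — canonicality requires the full set.
Syntactic dual-sign input (complementation such as `(!a & b) | (!a & !b)`)
is tolerated and resolves during normalization; a function whose prime
implicants still carry both signs of a regulator is genuinely non-monotone
and rejected, as are constant functions.  Repaired functions are **not**
re-minimized on export: exact duplicate clauses are pruned during
flattening, absorbed clauses are kept verbatim.

## Consistency semantics

Column 0 of a time series is the initial condition; observed values at
steps `t >= 1` are checked.  Missing cells are completed existentially —
the checker searches for the completion (and schedule) with the fewest
inconsistent observation points and returns it as a witness.

- **Steady state**: each column must be completable to a stable state
  (every function returns its component's current value).  Columns are
  independent.
- **Synchronous**: free choices are the missing column-0 cells and the
  constants of unobserved inputs; everything else propagates
  deterministically, with observed values kept as ground truth during
  propagation so each mismatch is localized to the single observation it
  contradicts.  With complete data the check is a single forward pass and
  never undecided.
- **Asynchronous**: a *visit schedule* validates every component exactly
  once per step `1..T`, one visit per iteration, per-component visits in
  step order (`n × T` visits in total; the 4-component, 3-step example
  yields 12).  At a visit the component's value at that step must equal its
  function evaluated on the current regulator values — each regulator's
  most recently assigned value, initialized from column 0.  The schedule's
  very first visit is exempt, since nothing is known about its regulators
  yet.  The search is depth-first over iterations with memoization on
  (pending steps, current values), never materializing the state transition
  graph.  Unobserved visited values are forced to the computed value;
  observed mismatches cost one violation.  A satisfiability-only mode
  prunes any violating branch immediately (used inside the repair loop);
  the default mode minimizes the violation count to localize
  inconsistencies.

All searches are budgeted by node expansions.  An exhausted budget yields
an explicit *undecided* status — never a silent answer — with the best
witness found so far.

## Repair search

Candidate repairs are enumerated per repairable target: one `s` per
`and`/`or` operator node (identity nodes are no-ops and excluded), one `n`
per regulator (all occurrences flip together, mirroring the edge-sign
semantics), one `r` per regulator unless it is the only one.  A repair set
is applied order-independently: operator toggles on the original structure,
then sign flips, then removals with pruning of emptied clauses; a set whose
`s` locus is emptied by one of its own removals is invalid.

The search is iterative deepening on cardinality `k = 0, 1, 2, ...`,
exhaustively testing every candidate subset of size `k` against all
experiments jointly, and returning **all** solutions at the first feasible
`k`.  Two solutions are equal iff their repair sets are equal; witness
schedules and completions are attached but not part of solution identity.
Solutions are reported in lexicographic (target, kind, locus) order.  The
enumeration is anytime: a subset budget or keyboard interrupt returns
best-so-far solutions flagged non-optimal.  A completed enumeration with no
solution is an explicit infeasibility — under the tool's constraint that
the network structure can only be edited, never extended, infeasibility is
a real outcome (see limitations).

An exhausted enumeration over subsets is exponential in `k`; a constraint
solver could slot in behind the same contract, but the default
implementation keeps the all-minimal guarantee trivially auditable and is
comfortably fast at the problem sizes used here.

## Synthetic instances

The generator mirrors the evaluation protocol the method is assessed
under: arity per non-input drawn from Poisson(λ), λ ∈ {1, 2, 4} typical,
resampled into `1..n` (a zero-arity non-input would be an input); regulators
drawn uniformly without replacement, self-regulation allowed; signs
uniform; each function a single uniformly chosen `and` or `or` over its
literals (`identity` at arity 1).  The sign distribution and input
fraction (default 0: every component gets a function) are free choices of
the generator, exposed as knobs.  Trajectories of 2–15 columns are produced
by running the model itself — synchronously from a random initial state, or
asynchronously by visiting components in random order within each step — so
generated data is consistent by construction (`k* = 0`, verified
round-trip).  Noise flips exactly round(5% of cells) (round-half-up, for
determinism); missingness deletes 10–30% of cells uniformly.  Recovery is
scored as the percentage of *deleted* cells whose recompleted value differs
from the original — relative to the deletion mask, not the whole matrix.

What the generator does not emulate: real expression data's correlated
noise, unequal sampling intervals, dosage effects, or the topology of
curated biological networks (hubs, feed-forward motifs).  Passing tests
demonstrate correctness of the semantics and search, not biological
fidelity of any particular repair.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `scheme` | — | steady / synchronous / asynchronous semantics |
| `kinds` | `nsr` | enabled repair operations |
| `repairable` | all non-inputs | components whose functions may be edited |
| `budget` (check) | 200 000 node expansions | per-experiment search cap |
| `budget` (repair) | unlimited | candidate subsets tried (anytime) |
| `max_cardinality` | #candidates | cap on repair-set size |
| `arity_lambda` | 1.0 | Poisson parameter for generated arity |
| `perturb_fraction` | 0.05 | fraction of cells flipped |
| `delete_fraction` | 0.0 | fraction of cells deleted |

## Numerical and design choices

- Truth-table comparisons (equivalence, impact counts) are taken over the
  union of the two regulator sets, so a 3-variable function compared with
  its 2-variable repair is scored over all 8 assignments.
- Visit counting: `n × T` with column 0 as unchecked initial condition —
  the worked 4-node, 4-column example has 12 visits.
- Input components take their observed value per experiment; an unobserved
  input's constant is an existential choice of the search.  Experiments
  never share completions.
- Tie-breaks are lexicographic everywhere (clause order, candidate order,
  solution order), making every artifact byte-deterministic under a seed.
- Problem sizes in the test suite and acceptance script (≤ 8 components,
  ≤ 5 columns, repair subsets to cardinality ~3) were chosen so that the
  exhaustive brute-force oracles remain exact cross-checks; the search
  itself handles larger instances with budgets.

## Known limitations

- Regulator removal is not invertible: once `r` deletes a regulator the
  structure can never be re-extended, so a model damaged by a removal may
  be unrepairable (measured: roughly one in ten uniformly planted removals
  on random 5-node instances).  Sign flips and operator swaps are
  involutions and always recoverable with one repair.
- With complete synchronous data the repair space per component is the
  reachable-function set of its current structure; a single flipped cell
  can demand behaviour outside it, making instances infeasible — reported
  explicitly, never papered over.
- The asynchronous search is exponential in components × steps; memoization
  keeps small instances (≤ ~8 components, ≤ 5 columns) interactive, but
  proving inconsistency is markedly slower than finding a witness.
- Multivalued logic, SBML-qual import, and edge additions are out of scope;
  external format conversion is expected upstream.
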