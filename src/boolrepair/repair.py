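"""Atomic repair operations and the all-cardinality-minimal repair search.

Three atomic repairs act on a target component's function structure:

``n`` (negate)
    flip the sign of *all* occurrences of a regulator — an inhibitor becomes
    an activator and vice versa;

``s`` (substitute)
    toggle one ``and``/``or`` operator node;

``r`` (remove)
    delete all occurrences of a regulator, dropping emptied clauses.
    Removing the last regulator is forbidden — that would turn the component
    into an input.

The network structure is never extended: repairs only edit existing
functions, and repaired functions are *not* re-minimized.

The search enumerates repair subsets in order of increasing cardinality and
returns **all** repair sets of the smallest size that render the model
consistent with every experiment simultaneously.  The enumeration is anytime:
on an exhausted budget or an interrupt the best solutions found so far are
returned flagged non-optimal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

from .boolean_core import (
    OP_AND,
    OP_IDENTITY,
    OP_OR,
    FunctionTree,
    RegulatorLiteral,
    regulators_of,
    truth_table,
    dnf_to_tree,
    DNFFunction,
)
from .dynamics import ConsistencyReport, check_consistency, canonical_scheme
from .model_io import BooleanModel, TimeSeries

__all__ = [
    "REPAIR_KINDS",
    "AtomicRepair",
    "RepairSolution",
    "RepairResult",
    "RepairError",
    "LastRegulatorError",
    "InvalidRepairError",
    "candidate_repairs",
    "apply_repair",
    "apply_repairs",
    "reachable_functions",
    "repair_minimal",
    "common_repairs",
]

REPAIR_KINDS = ("n", "s", "r")


class RepairError(ValueError):
    """A repair cannot be applied to the model as specified."""


class LastRegulatorError(RepairError):
    """Removing this regulator would leave the function without regulators."""


class InvalidRepairError(RepairError):
    """The repair's locus does not exist (or no longer exists) in the target."""


@dataclass(frozen=True)
class AtomicRepair:
    """A single edit: ``kind`` in {n, s, r}, applied to ``target``'s function.

    ``locus`` is a regulator name for kinds ``n``/``r`` and an operator node
    id for kind ``s``.
    """

    kind: str
    target: str
    locus: str

    def __post_init__(self) -> None:
        if self.kind not in REPAIR_KINDS:
            raise ValueError(f"unknown repair kind {self.kind!r}")

    def sort_key(self) -> tuple:
        return (self.target, self.kind, self.locus)

    def __str__(self) -> str:
        return f"{self.kind} {self.target} {self.locus}"


@dataclass(frozen=True)
class RepairSolution:
    """A set of atomic repairs plus the repaired model and its witnesses."""

    repairs: frozenset
    model: BooleanModel
    report: ConsistencyReport

    @property
    def cardinality(self) -> int:
        return len(self.repairs)

    def sorted_repairs(self) -> tuple:
        return tuple(sorted(self.repairs, key=AtomicRepair.sort_key))


@dataclass
class RepairResult:
    """Outcome of :func:`repair_minimal`.

    ``status``:
        ``optimal``     — ``solutions`` is the complete set of minimal repairs;
        ``infeasible``  — no repair subset over the allowed kinds/repairable
                          list restores consistency;
        ``nonoptimal``  — interrupted/budget-exhausted after finding solutions
                          (best-so-far, completeness not guaranteed);
        ``undecided``   — interrupted/budget-exhausted before finding any.
    """

    status: str
    solutions: list = field(default_factory=list)
    cardinality: int | None = None

    @property
    def feasible(self) -> bool:
        return self.status in ("optimal", "nonoptimal") and bool(self.solutions)


def _operator_nodes(tree: FunctionTree) -> list[FunctionTree]:
    return [
        node
        for node in tree.iter_operator_nodes()
        if node.op in (OP_AND, OP_OR) and len(node.children) >= 2
    ]


def candidate_repairs(
    m: BooleanModel,
    kinds: Iterable[str] = REPAIR_KINDS,
    repairable: Iterable[str] | None = None,
) -> list[AtomicRepair]:
    """All applicable atomic repairs, sorted by (target, kind, locus).

    ``repairable`` restricts the targets (``None`` or empty means every
    non-input is repairable).  Kind ``s`` is offered for every ``and``/``or``
    operator node (identity nodes are no-ops and excluded), ``n`` for every
    regulator, ``r`` for every regulator unless it is the only one.
    """
    kinds = set(kinds)
    unknown = kinds - set(REPAIR_KINDS)
    if unknown:
        raise ValueError(f"unknown repair kind(s): {sorted(unknown)}")
    if repairable:
        repairable = set(repairable)
        bad = repairable - set(m.components)
        if bad:
            raise ValueError(f"repairable list names unknown component(s): {sorted(bad)}")
        targets = sorted(repairable & set(m.functions))
    else:
        targets = sorted(m.functions)
    out: list[AtomicRepair] = []
    for target in targets:
        tree = m.functions[target]
        regs = regulators_of(tree)
        if "s" in kinds:
            for node in _operator_nodes(tree):
                out.append(AtomicRepair("s", target, node.node_id or ""))
        if "n" in kinds:
            for r in regs:
                out.append(AtomicRepair("n", target, r))
        if "r" in kinds and len(regs) >= 2:
            for r in regs:
                out.append(AtomicRepair("r", target, r))
    out.sort(key=AtomicRepair.sort_key)
    return out


def _toggle_ops(node, loci: set, found: set):
    if isinstance(node, RegulatorLiteral):
        return node
    children = tuple(_toggle_ops(c, loci, found) for c in node.children)
    op = node.op
    if node.node_id in loci:
        found.add(node.node_id)
        if op == OP_AND:
            op = OP_OR
        elif op == OP_OR:
            op = OP_AND
        else:
            raise InvalidRepairError(
                f"operator substitution on identity node {node.node_id!r}"
            )
    return FunctionTree(op, children, node.output, node.node_id)


def _flip_signs(node, regs: set):
    if isinstance(node, RegulatorLiteral):
        return node.negated() if node.regulator in regs else node
    return FunctionTree(
        node.op,
        tuple(_flip_signs(c, regs) for c in node.children),
        node.output,
        node.node_id,
    )


def _remove_regs(node, regs: set):
    """Delete literals of ``regs``; prune operator nodes left childless."""
    if isinstance(node, RegulatorLiteral):
        return None if node.regulator in regs else node
    children = tuple(
        c2 for c2 in (_remove_regs(c, regs) for c in node.children)
        if c2 is not None
    )
    if not children:
        return None
    if node.op == OP_IDENTITY and len(children) != 1:
        return None
    return FunctionTree(node.op, children, node.output, node.node_id)


def apply_repairs(m: BooleanModel, repairs: Iterable[AtomicRepair]) -> BooleanModel:
    """Apply a *set* of repairs; the result is order-independent.

    Per target function: operator toggles are applied on the original
    structure, then sign flips, then regulator removals with pruning of
    emptied clauses.  Raises :class:`LastRegulatorError` when removals would
    leave a function empty and :class:`InvalidRepairError` when a locus does
    not exist or an ``s`` locus is pruned away by a removal in the same set.
    """
    repairs = list(repairs)
    by_target: dict[str, list[AtomicRepair]] = {}
    for rep in repairs:
        by_target.setdefault(rep.target, []).append(rep)
    new_model = m
    for target in sorted(by_target):
        reps = by_target[target]
        if target not in m.functions:
            raise InvalidRepairError(
                f"{target!r} has no function (input or unknown component)"
            )
        tree = m.functions[target]
        regs = set(regulators_of(tree))
        node_ids = {n.node_id for n in tree.iter_operator_nodes()}
        s_loci = {r.locus for r in reps if r.kind == "s"}
        n_regs = {r.locus for r in reps if r.kind == "n"}
        r_regs = {r.locus for r in reps if r.kind == "r"}
        for locus in (n_regs | r_regs) - regs:
            raise InvalidRepairError(
                f"{target!r} has no regulator {locus!r}"
            )
        for locus in s_loci - node_ids:
            raise InvalidRepairError(
                f"{target!r} has no operator node {locus!r}"
            )
        if r_regs:
            if len(regs) == 1:
                raise LastRegulatorError(
                    f"cannot remove the last regulator of {target!r}"
                )
            if r_regs >= regs:
                raise LastRegulatorError(
                    f"removals would delete every regulator of {target!r}"
                )
        found: set = set()
        tree = _toggle_ops(tree, s_loci, found)
        if found != s_loci:
            raise InvalidRepairError(
                f"operator node(s) {sorted(s_loci - found)} not found in "
                f"{target!r}"
            )
        tree = _flip_signs(tree, n_regs)
        if r_regs:
            tree = _remove_regs(tree, r_regs)
            if tree is None:
                raise LastRegulatorError(
                    f"removals emptied the function of {target!r}"
                )
            if isinstance(tree, RegulatorLiteral):
                tree = FunctionTree(OP_IDENTITY, (tree,), output=target)
            surviving = {n.node_id for n in tree.iter_operator_nodes()}
            if s_loci - surviving:
                raise InvalidRepairError(
                    f"operator node(s) {sorted(s_loci - surviving)} of "
                    f"{target!r} were emptied by a removal in the same set"
                )
        new_model = new_model.with_function(target, tree)
    return new_model


def apply_repair(m: BooleanModel, rep: AtomicRepair) -> BooleanModel:
    """Apply one atomic repair (see :func:`apply_repairs`)."""
    return apply_repairs(m, [rep])


def _tree_candidates_local(tree: FunctionTree, kinds: set) -> list[FunctionTree]:
    """Single-repair neighbours of a bare tree (used by reachability)."""
    out = []
    regs = regulators_of(tree)
    if "s" in kinds:
        for node in _operator_nodes(tree):
            if node.node_id is not None:
                found: set = set()
                out.append(_toggle_ops(tree, {node.node_id}, found))
    if "n" in kinds:
        for r in regs:
            out.append(_flip_signs(tree, {r}))
    if "r" in kinds and len(regs) >= 2:
        for r in regs:
            t2 = _remove_regs(tree, {r})
            if t2 is None:
                continue
            if isinstance(t2, RegulatorLiteral):
                t2 = FunctionTree(OP_IDENTITY, (t2,), output=tree.output)
            out.append(t2)
    return out


def reachable_functions(
    f: DNFFunction | FunctionTree,
    kinds: Iterable[str] = REPAIR_KINDS,
) -> frozenset:
    """Distinct Boolean functions reachable by finite repair combinations.

    Returns a frozenset of truth-table output tuples over the *original*
    regulator set (sorted), including the unrepaired function itself (the
    empty combination).  Distinctness is by truth-table equivalence, so
    structurally different repairs of the same function count once.
    """
    kinds = set(kinds)
    if isinstance(f, DNFFunction):
        tree0 = dnf_to_tree(f)
    else:
        tree0 = f
        if not any(n.node_id for n in tree0.iter_operator_nodes()):
            # ensure s-repairs are addressable
            from .boolean_core import flatten

            tree0 = dnf_to_tree(flatten(tree0))
    variables = regulators_of(tree0)

    def key(tree) -> tuple:
        return truth_table(tree, variables).outputs

    seen_structs = {tree0.structural_key()}
    tables = {key(tree0)}
    frontier = [tree0]
    while frontier:
        tree = frontier.pop()
        for t2 in _tree_candidates_local(tree, kinds):
            sk = t2.structural_key()
            if sk in seen_structs:
                continue
            seen_structs.add(sk)
            tables.add(key(t2))
            frontier.append(t2)
    return frozenset(tables)


def repair_minimal(
    m: BooleanModel,
    ts_list: Iterable[TimeSeries] | TimeSeries,
    scheme: str,
    kinds: Iterable[str] = REPAIR_KINDS,
    repairable: Iterable[str] | None = None,
    budget: int | None = None,
    max_cardinality: int | None = None,
    check_budget: int | None = None,
) -> RepairResult:
    """Enumerate **all** cardinality-minimal repair sets.

    Iterative deepening on the number of repairs ``k = 0, 1, 2, ...``: at
    each ``k`` every subset of the candidate repairs is applied and the
    repaired model checked against all experiments jointly under ``scheme``.
    The first ``k`` with solutions is the minimal cardinality ``k*`` and all
    its solutions are returned; ``k* = 0`` (a single empty solution) means
    the model was already consistent.

    ``budget`` caps the number of subsets tried; ``check_budget`` is passed
    to each consistency check.  On an exhausted budget or a keyboard
    interrupt the result carries the best-so-far solutions with status
    ``nonoptimal`` (or ``undecided`` if none were found) — the anytime
    contract.  A completed enumeration with no solution is ``infeasible``.
    """
    if isinstance(ts_list, TimeSeries):
        ts_list = [ts_list]
    ts_list = list(ts_list)
    scheme = canonical_scheme(scheme)
    cands = candidate_repairs(m, kinds, repairable)
    max_k = len(cands) if max_cardinality is None else min(max_cardinality, len(cands))
    tried = 0
    solutions: list[RepairSolution] = []
    any_undecided_check = False
    try:
        for k in range(0, max_k + 1):
            for combo in combinations(cands, k):
                if budget is not None and tried >= budget:
                    status = "nonoptimal" if solutions else "undecided"
                    return RepairResult(
                        status, solutions, solutions[0].cardinality if solutions else None
                    )
                tried += 1
                try:
                    m2 = apply_repairs(m, combo)
                except RepairError:
                    continue
                rep = check_consistency(
                    m2, ts_list, scheme, budget=check_budget, sat_only=True
                )
                if rep.undecided:
                    any_undecided_check = True
                    continue
                if rep.consistent:
                    solutions.append(
                        RepairSolution(frozenset(combo), m2, rep)
                    )
            if solutions:
                solutions.sort(
                    key=lambda s: tuple(r.sort_key() for r in s.sorted_repairs())
                )
                return RepairResult("optimal", solutions, k)
    except KeyboardInterrupt:
        status = "nonoptimal" if solutions else "undecided"
        return RepairResult(
            status, solutions, solutions[0].cardinality if solutions else None
        )
    if any_undecided_check:
        return RepairResult("undecided", [], None)
    return RepairResult("infeasible", [], None)


def common_repairs(solutions: Sequence[RepairSolution]):
    """Frequency table of atomic repairs across solutions.

    Returns a :class:`pandas.DataFrame` with columns ``kind``, ``target``,
    ``locus`` and ``percent`` (share of solutions containing the repair),
    sorted by descending percentage then lexicographically.  An empty-repair
    solution set yields an empty table.
    """
    import pandas as pd

    solutions = list(solutions)
    if not solutions:
        raise ValueError("common_repairs needs at least one solution")
    counts: dict[AtomicRepair, int] = {}
    for sol in solutions:
        for rep in sol.repairs:
            counts[rep] = counts.get(rep, 0) + 1
    rows = [
        {
            "kind": rep.kind,
            "target": rep.target,
            "locus": rep.locus,
            "percent": 100.0 * cnt / len(solutions),
        }
        for rep, cnt in counts.items()
    ]
    df = pd.DataFrame(rows, columns=["kind", "target", "locus", "percent"])
    if not df.empty:
        df = df.sort_values(
            ["percent", "target", "kind", "locus"],
            ascending=[False, True, True, True],
        ).reset_index(drop=True)
    return df
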