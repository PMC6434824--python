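"""Representation, evaluation and normalization of Boolean regulatory functions.

A regulatory function combines the activities of a component's regulators with
``and``, ``or`` and negated/plain literals.  Throughout the package functions
are restricted to the *monotone non-degenerate* fragment: every regulator
appears with a single sign (a regulator is either an activator or an inhibitor
of a target, never both) and every regulator is essential (flipping it changes
the output in at least one state).

Two representations coexist:

``FunctionTree``
    an operator tree (``or`` / ``and`` / ``identity`` over signed literals).
    This is the structure repair operations act on — operator substitution
    needs an addressable operator node.

``DNFFunction``
    a disjunction of conjunctive clauses of signed literals.  This is the I/O
    and normalization form.

Normalization computes the *complete* set of prime implicants (the Blake
canonical form).  Unlike a minimal Quine–McCluskey cover, the complete
prime-implicant set is unique, so truth-table-equivalent functions map to the
identical normalized object — a prerequisite for equivalent functions sharing
the same repairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Iterator, Mapping, Union

__all__ = [
    "RegulatorLiteral",
    "FunctionTree",
    "DNFFunction",
    "TruthTable",
    "MonotonicityReport",
    "BooleanFunctionError",
    "MissingValueError",
    "DegenerateFunctionError",
    "MonotonicityError",
    "OP_OR",
    "OP_AND",
    "OP_IDENTITY",
    "evaluate",
    "truth_table",
    "normalize",
    "flatten",
    "equivalent",
    "truth_table_diff",
    "check_monotone_nondegenerate",
    "regulators_of",
    "signs_of",
    "dnf_to_tree",
    "clause_sort_key",
]


class BooleanFunctionError(ValueError):
    """Base class for errors raised by function operations."""


class MissingValueError(BooleanFunctionError):
    """A regulator referenced by a function has no value in the given state."""


class DegenerateFunctionError(BooleanFunctionError):
    """The function is constant (or has no regulators) over its regulator set."""


class MonotonicityError(BooleanFunctionError):
    """A regulator occurs with both signs — outside the monotone fragment."""


OP_OR = "or"
OP_AND = "and"
OP_IDENTITY = "identity"
_OPS = (OP_OR, OP_AND, OP_IDENTITY)


@dataclass(frozen=True)
class RegulatorLiteral:
    """A possibly-negated regulator: the leaf of every function.

    ``positive=True`` denotes an activating occurrence, ``False`` an
    inhibiting (negated) one.
    """

    regulator: str
    positive: bool = True

    def __post_init__(self) -> None:
        if not self.regulator:
            raise ValueError("regulator name must be a non-empty identifier")

    def negated(self) -> "RegulatorLiteral":
        return RegulatorLiteral(self.regulator, not self.positive)

    def sort_key(self) -> tuple:
        # lexicographic by name; positive occurrence sorts before negative
        return (self.regulator, not self.positive)

    def __str__(self) -> str:
        return self.regulator if self.positive else "!" + self.regulator


TreeNode = Union["FunctionTree", RegulatorLiteral]


@dataclass(frozen=True)
class FunctionTree:
    """Operator tree over signed literals.

    ``identity`` wraps exactly one child; ``and``/``or`` take one or more
    children (a one-child operator node can arise transiently during repair
    and evaluates as its single child).  ``node_id`` labels operator nodes so
    that repairs can address them stably across transformations; ``output``
    optionally records the component the function drives.
    """

    op: str
    children: tuple[TreeNode, ...]
    output: str | None = None
    node_id: str | None = None

    def __post_init__(self) -> None:
        if self.op not in _OPS:
            raise ValueError(f"unknown operator {self.op!r}")
        object.__setattr__(self, "children", tuple(self.children))
        if not self.children:
            raise ValueError("operator node needs at least one child")
        if self.op == OP_IDENTITY and len(self.children) != 1:
            raise ValueError("identity takes exactly one child")

    def iter_operator_nodes(self) -> Iterator["FunctionTree"]:
        """Preorder traversal of the operator nodes."""
        yield self
        for child in self.children:
            if isinstance(child, FunctionTree):
                yield from child.iter_operator_nodes()

    def iter_literals(self) -> Iterator[RegulatorLiteral]:
        for child in self.children:
            if isinstance(child, FunctionTree):
                yield from child.iter_literals()
            else:
                yield child

    def structural_key(self) -> tuple:
        """Hashable key ignoring node ids (structure + literals only)."""
        parts = []
        for child in self.children:
            if isinstance(child, FunctionTree):
                parts.append(child.structural_key())
            else:
                parts.append(("lit", child.regulator, child.positive))
        return (self.op, tuple(parts))


@dataclass(frozen=True)
class DNFFunction:
    """A disjunction of conjunctive clauses of signed literals.

    Clause order is preserved as given (flattening a repaired tree keeps the
    distributed clause order verbatim; normalization sorts canonically).
    Exact duplicate clauses are dropped on construction.
    """

    target: str
    clauses: tuple[frozenset, ...]

    def __post_init__(self) -> None:
        seen: list[frozenset] = []
        for clause in self.clauses:
            fs = frozenset(clause)
            if not fs:
                raise ValueError("empty clause in DNF")
            for lit in fs:
                if not isinstance(lit, RegulatorLiteral):
                    raise TypeError("clauses must contain RegulatorLiteral")
            if fs not in seen:
                seen.append(fs)
        if not seen:
            raise ValueError("DNF must have at least one clause")
        object.__setattr__(self, "clauses", tuple(seen))

    def sorted_clauses(self) -> tuple[frozenset, ...]:
        return tuple(sorted(self.clauses, key=clause_sort_key))

    def __str__(self) -> str:
        parts = []
        for clause in self.clauses:
            lits = sorted(clause, key=RegulatorLiteral.sort_key)
            body = " & ".join(str(l) for l in lits)
            parts.append(f"({body})" if len(lits) > 1 else body)
        return " | ".join(parts)


def clause_sort_key(clause: frozenset) -> tuple:
    return tuple(sorted(lit.sort_key() for lit in clause))


Function = Union[DNFFunction, FunctionTree, RegulatorLiteral]


def _iter_literals(f: Function) -> Iterator[RegulatorLiteral]:
    if isinstance(f, RegulatorLiteral):
        yield f
    elif isinstance(f, FunctionTree):
        yield from f.iter_literals()
    elif isinstance(f, DNFFunction):
        for clause in f.clauses:
            yield from clause
    else:
        raise TypeError(f"not a Boolean function: {type(f).__name__}")


def regulators_of(f: Function) -> tuple[str, ...]:
    """Sorted distinct regulator names appearing in ``f``."""
    return tuple(sorted({lit.regulator for lit in _iter_literals(f)}))


def signs_of(f: Function) -> dict[str, set]:
    """Map regulator -> set of signs (True/False) it occurs with."""
    out: dict[str, set] = {}
    for lit in _iter_literals(f):
        out.setdefault(lit.regulator, set()).add(lit.positive)
    return out


def evaluate(f: Function, state: Mapping[str, object]) -> bool:
    """Evaluate ``f`` under ``state`` (component -> truth value / 0 / 1).

    ``or`` is true when any child is, ``and`` when all children are,
    ``identity`` passes its single child through; a negative literal
    contributes the negation of its regulator's value.

    Raises :class:`MissingValueError` naming the regulator when a referenced
    regulator is unassigned.
    """
    if isinstance(f, RegulatorLiteral):
        try:
            value = state[f.regulator]
        except KeyError:
            raise MissingValueError(
                f"no value for regulator {f.regulator!r}"
            ) from None
        if value is None:
            raise MissingValueError(f"no value for regulator {f.regulator!r}")
        return bool(value) if f.positive else not bool(value)
    if isinstance(f, FunctionTree):
        # no short-circuit: an unassigned regulator anywhere must surface
        values = [evaluate(c, state) for c in f.children]
        if f.op == OP_AND:
            return all(values)
        if f.op == OP_OR:
            return any(values)
        return values[0]  # identity
    if isinstance(f, DNFFunction):
        return any(
            [
                all([evaluate(lit, state) for lit in clause])
                for clause in f.clauses
            ]
        )
    raise TypeError(f"not a Boolean function: {type(f).__name__}")


@dataclass(frozen=True)
class TruthTable:
    """Complete truth table of a function over an ordered variable tuple.

    Row ``i`` assigns ``variables[j]`` the bit ``(i >> (n-1-j)) & 1`` —
    i.e. rows are ordered as binary counting with the first variable as the
    most significant bit.
    """

    variables: tuple[str, ...]
    outputs: tuple[bool, ...]

    def __post_init__(self) -> None:
        n = len(self.variables)
        if len(set(self.variables)) != n:
            raise ValueError("truth table variables must be distinct")
        if len(self.outputs) != 2**n:
            raise ValueError("truth table must have exactly 2^n rows")

    @property
    def n(self) -> int:
        return len(self.variables)

    def assignment(self, index: int) -> dict[str, bool]:
        n = self.n
        return {
            v: bool((index >> (n - 1 - j)) & 1)
            for j, v in enumerate(self.variables)
        }

    def rows(self) -> Iterator[tuple[dict[str, bool], bool]]:
        for i, out in enumerate(self.outputs):
            yield self.assignment(i), out


def truth_table(f: Function, variables: Iterable[str] | None = None) -> TruthTable:
    """Enumerate ``f`` over its regulator set (or an explicit superset)."""
    if variables is None:
        variables = regulators_of(f)
    variables = tuple(variables)
    missing = set(regulators_of(f)) - set(variables)
    if missing:
        raise ValueError(f"variables must cover all regulators; missing {missing}")
    if not variables:
        raise ValueError("truth table needs at least one variable")
    n = len(variables)
    outputs = []
    for i in range(2**n):
        state = {v: bool((i >> (n - 1 - j)) & 1) for j, v in enumerate(variables)}
        outputs.append(evaluate(f, state))
    return TruthTable(variables, tuple(outputs))


def _prime_implicant_cubes(n: int, minterms: set[int]) -> set[tuple[int, int]]:
    """All prime implicants of the function with the given true rows.

    Quine–McCluskey combination phase only (no covering step): cubes are
    ``(bits, mask)`` pairs where ``mask`` has a 1 for each fixed variable and
    ``bits`` holds the fixed values.  Returning every unmerged cube yields the
    complete prime-implicant set.
    """
    full = (1 << n) - 1
    current = {(m, full) for m in minterms}
    primes: set[tuple[int, int]] = set()
    while current:
        merged: set[tuple[int, int]] = set()
        nxt: set[tuple[int, int]] = set()
        cur = sorted(current)
        by_mask: dict[int, list[int]] = {}
        for bits, mask in cur:
            by_mask.setdefault(mask, []).append(bits)
        for mask, group in by_mask.items():
            gset = set(group)
            for bits in group:
                for j in range(n):
                    bit = 1 << j
                    if not (mask & bit):
                        continue
                    other = bits ^ bit
                    if other in gset and bits < other:
                        nxt.add((bits & ~bit, mask & ~bit))
                        merged.add((bits, mask))
                        merged.add((other, mask))
        primes |= current - merged
        current = nxt
    return primes


def normalize(f: Function, target: str | None = None) -> DNFFunction:
    """Blake canonical form: the disjunction of *all* prime implicants.

    Clauses and literals come out in a fixed lexicographic order, so
    ``normalize`` is idempotent and truth-table-equivalent inputs map to the
    identical object.  Regulators that turn out to be inessential vanish
    (they occur in no prime implicant).

    A dual-sign *syntactic* occurrence is tolerated when the underlying
    function is still unate — complementation such as
    ``(!a & b) | (!a & !b)`` normalizes to ``!a``.  Only a genuinely
    non-monotone function (a regulator keeps both signs in its prime
    implicants, as in xor) is rejected.

    Raises
    ------
    MonotonicityError
        if some regulator occurs with both signs in the prime implicants.
    DegenerateFunctionError
        if the function is constant over its regulators.
    """
    if target is None:
        if isinstance(f, DNFFunction):
            target = f.target
        elif isinstance(f, FunctionTree) and f.output:
            target = f.output
        else:
            target = "f"
    sign_map = signs_of(f)
    regs = tuple(sorted(sign_map))
    if not regs:
        raise DegenerateFunctionError("function has no regulators")
    n = len(regs)
    tt = truth_table(f, regs)
    minterms = {i for i, out in enumerate(tt.outputs) if out}
    if not minterms or len(minterms) == 2**n:
        raise DegenerateFunctionError(
            f"function for {target!r} is constant "
            f"{'true' if minterms else 'false'}"
        )
    cubes = _prime_implicant_cubes(n, minterms)
    clauses = []
    prime_signs: dict[str, set] = {}
    for bits, mask in cubes:
        lits = []
        for j, reg in enumerate(regs):
            bit = 1 << (n - 1 - j)
            if mask & bit:
                positive = bool(bits & bit)
                prime_signs.setdefault(reg, set()).add(positive)
                lits.append(RegulatorLiteral(reg, positive))
        clauses.append(frozenset(lits))
    dual = sorted(r for r, s in prime_signs.items() if len(s) > 1)
    if dual:
        raise MonotonicityError(
            f"non-monotone function for {target!r}: regulator(s) with both "
            f"signs in the prime implicants: {', '.join(dual)}"
        )
    clauses.sort(key=clause_sort_key)
    return DNFFunction(target, tuple(clauses))


def flatten(f: FunctionTree | DNFFunction, target: str | None = None) -> DNFFunction:
    """Distribute ``and`` over ``or`` to obtain a DNF — without minimization.

    Duplicate literals within a clause and exact duplicate clauses are
    removed; absorbed clauses are deliberately retained (repaired models are
    exported unminimized).

    Raises :class:`MonotonicityError` if distribution puts both signs of a
    regulator into one clause.
    """
    if isinstance(f, DNFFunction):
        return f
    if target is None:
        target = f.output if (isinstance(f, FunctionTree) and f.output) else "f"
    clauses = _flatten_node(f)
    return DNFFunction(target, tuple(clauses))


def _flatten_node(node: TreeNode) -> list[frozenset]:
    if isinstance(node, RegulatorLiteral):
        return [frozenset([node])]
    if node.op == OP_IDENTITY:
        return _flatten_node(node.children[0])
    if node.op == OP_OR:
        out: list[frozenset] = []
        for child in node.children:
            for clause in _flatten_node(child):
                if clause not in out:
                    out.append(clause)
        return out
    # and: cross-product merge of child clause lists
    acc: list[frozenset] = [frozenset()]
    for child in node.children:
        child_clauses = _flatten_node(child)
        nxt: list[frozenset] = []
        for left in acc:
            for right in child_clauses:
                merged = left | right
                names = {}
                for lit in merged:
                    if names.setdefault(lit.regulator, lit.positive) != lit.positive:
                        raise MonotonicityError(
                            f"regulator {lit.regulator!r} occurs with both "
                            "signs inside one clause"
                        )
                if merged not in nxt:
                    nxt.append(merged)
        acc = nxt
    return acc


def _union_variables(f: Function, g: Function) -> tuple[str, ...]:
    return tuple(sorted(set(regulators_of(f)) | set(regulators_of(g))))


def equivalent(f: Function, g: Function) -> bool:
    """Truth-table equality over the union of both regulator sets."""
    variables = _union_variables(f, g)
    if not variables:
        return True
    return truth_table(f, variables).outputs == truth_table(g, variables).outputs


def truth_table_diff(f: Function, g: Function) -> int:
    """Number of assignments (over the union of regulator sets) where f != g."""
    variables = _union_variables(f, g)
    if not variables:
        return 0
    a = truth_table(f, variables).outputs
    b = truth_table(g, variables).outputs
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class MonotonicityReport:
    """Diagnostics from :func:`check_monotone_nondegenerate`."""

    dual_sign: frozenset
    inessential: frozenset

    @property
    def ok(self) -> bool:
        return not self.dual_sign and not self.inessential


def check_monotone_nondegenerate(f: Function) -> MonotonicityReport:
    """Report regulators with both signs and regulators the output ignores.

    A regulator is essential when flipping it changes the output in at least
    one state; the probe enumerates the full truth table, so this is intended
    for functions with a handful of regulators.
    """
    sign_map = signs_of(f)
    dual = frozenset(r for r, s in sign_map.items() if len(s) > 1)
    regs = tuple(sorted(sign_map))
    inessential = set()
    if regs:
        n = len(regs)
        for r in regs:
            essential = False
            for i in range(2**n):
                state = {
                    v: bool((i >> (n - 1 - j)) & 1) for j, v in enumerate(regs)
                }
                flipped = dict(state)
                flipped[r] = not flipped[r]
                if evaluate(f, state) != evaluate(f, flipped):
                    essential = True
                    break
            if not essential:
                inessential.add(r)
    return MonotonicityReport(dual, frozenset(inessential))


def dnf_to_tree(dnf: DNFFunction, assign_ids: bool = True) -> FunctionTree:
    """Build the canonical operator tree for a DNF.

    A multi-clause DNF becomes an ``or`` node whose multi-literal clauses are
    ``and`` nodes and single-literal clauses are direct literal children; a
    single multi-literal clause becomes a bare ``and``; a single literal is
    wrapped in ``identity``.  Operator nodes get preorder ids ``n0, n1, ...``
    when ``assign_ids`` is set.
    """
    counter = [0]

    def next_id() -> str | None:
        if not assign_ids:
            return None
        nid = f"n{counter[0]}"
        counter[0] += 1
        return nid

    clauses = dnf.clauses

    def clause_node(clause: frozenset) -> TreeNode:
        lits = tuple(sorted(clause, key=RegulatorLiteral.sort_key))
        if len(lits) == 1:
            return lits[0]
        return FunctionTree(OP_AND, lits, node_id=next_id())

    if len(clauses) == 1:
        clause = clauses[0]
        lits = tuple(sorted(clause, key=RegulatorLiteral.sort_key))
        if len(lits) == 1:
            return FunctionTree(
                OP_IDENTITY, lits, output=dnf.target, node_id=next_id()
            )
        return FunctionTree(OP_AND, lits, output=dnf.target, node_id=next_id())
    root_id = next_id()
    children = tuple(clause_node(c) for c in clauses)
    return FunctionTree(OP_OR, children, output=dnf.target, node_id=root_id)
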