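"""Independent oracles used across the test suite.

Everything here deliberately avoids the implementation paths it checks:
prime implicants come from exhaustive cube enumeration, schedule validity
from a literal transcription of the visiting rules, minimal repairs from
flat subset enumeration with sequential single-repair application, and
function equivalence from sympy's SAT check.
"""

from __future__ import annotations

from itertools import combinations, product

from boolrepair.boolean_core import evaluate, regulators_of
from boolrepair.dynamics import check_consistency
from boolrepair.repair import RepairError, apply_repair, candidate_repairs


def brute_force_prime_implicants(f) -> set:
    """All prime implicants by exhaustive cube enumeration.

    A cube fixes a subset of the variables; it is an implicant when every
    state satisfying it satisfies ``f``, and prime when dropping any fixed
    variable breaks that.  Returns a set of frozensets of ``(var, value)``.
    """
    variables = regulators_of(f)
    n = len(variables)

    def states_of(cube: dict):
        free = [v for v in variables if v not in cube]
        for bits in product((False, True), repeat=len(free)):
            state = dict(cube)
            state.update(zip(free, bits))
            yield state

    def is_implicant(cube: dict) -> bool:
        return all(evaluate(f, s) for s in states_of(cube))

    primes = set()
    for r in range(1, n + 1):
        for vs in combinations(variables, r):
            for bits in product((False, True), repeat=r):
                cube = dict(zip(vs, bits))
                if not is_implicant(cube):
                    continue
                prime = all(
                    not is_implicant({k: v for k, v in cube.items() if k != drop})
                    for drop in cube
                )
                if prime:
                    primes.add(frozenset(cube.items()))
    return primes


def normalized_clause_set(dnf) -> set:
    """A DNFFunction's clauses as frozensets of (regulator, positive)."""
    return {
        frozenset((lit.regulator, lit.positive) for lit in clause)
        for clause in dnf.clauses
    }


def validate_schedule(m, ts, schedule) -> list[str]:
    """Literal check of the five visiting rules; returns violation messages.

    (1) exactly one visit per iteration, iterations contiguous from 1;
    (2) every component visited at every step 1..T; (3) a visit at step ts
    needs the same component visited at ts-1 in an earlier iteration;
    (4) no component visited twice at one step; (5) at a component's first
    visit every regulator already has a current value — a column-0
    observation or an earlier visit — except for the schedule's very first
    visit.
    """
    errors = []
    visits = list(schedule)
    iterations = [v.iteration for v in visits]
    if sorted(iterations) != list(range(1, len(visits) + 1)):
        errors.append(f"iterations not contiguous 1..{len(visits)}: {iterations}")
    visits.sort(key=lambda v: v.iteration)
    T = ts.steps
    comps = sorted(m.components)
    expected = {(c, t) for c in comps for t in range(1, T + 1)}
    seen = [(v.component, v.step) for v in visits]
    if len(set(seen)) != len(seen):
        errors.append("a (component, step) pair visited twice")
    if set(seen) != expected:
        errors.append(
            f"coverage mismatch: missing {expected - set(seen)}, "
            f"extra {set(seen) - expected}"
        )
    visited_at: dict = {}
    for v in visits:
        if v.step > 1 and visited_at.get((v.component, v.step - 1), 10**9) >= v.iteration:
            errors.append(
                f"{v.component} visited at step {v.step} before step {v.step-1}"
            )
        visited_at[(v.component, v.step)] = v.iteration
    first_step: dict = {}
    ever_visited: set = set()
    for k, v in enumerate(visits):
        if v.component not in first_step:
            first_step[v.component] = v.step
            if k > 0 and v.component in m.functions:
                for reg in regulators_of(m.functions[v.component]):
                    if reg not in ever_visited and ts.get(reg, 0) is None:
                        errors.append(
                            f"regulator {reg} of {v.component} has no current "
                            f"value at iteration {v.iteration}"
                        )
        ever_visited.add(v.component)
    return errors


def brute_force_minimal_repairs(
    m, ts_list, scheme, kinds, repairable=None, max_k=3, check_budget=None
):
    """Exhaustive repair search: flat enumeration of subsets by size,
    applying repairs one at a time in sorted order.

    Returns ``(k*, set-of-frozensets)`` or ``(None, empty set)`` when no
    subset of size <= max_k works.
    """
    cands = candidate_repairs(m, kinds, repairable)
    for k in range(0, max_k + 1):
        found = set()
        for combo in combinations(cands, k):
            model = m
            try:
                for rep in combo:
                    model = apply_repair(model, rep)
            except RepairError:
                continue
            report = check_consistency(model, ts_list, scheme, budget=check_budget)
            if not report.undecided and report.consistent:
                found.add(frozenset(combo))
        if found:
            return k, found
    return None, set()


def sympy_equivalent(f, g) -> bool:
    """Equivalence via SAT on the XOR of the two sympy translations."""
    import sympy
    from sympy.logic.inference import satisfiable

    def to_sympy(h):
        from boolrepair.boolean_core import (
            DNFFunction,
            FunctionTree,
            RegulatorLiteral,
        )

        if isinstance(h, RegulatorLiteral):
            sym = sympy.Symbol(h.regulator)
            return sym if h.positive else ~sym
        if isinstance(h, DNFFunction):
            return sympy.Or(
                *[sympy.And(*[to_sympy(l) for l in clause]) for clause in h.clauses]
            )
        if isinstance(h, FunctionTree):
            parts = [to_sympy(c) for c in h.children]
            if h.op == "and":
                return sympy.And(*parts)
            if h.op == "or":
                return sympy.Or(*parts)
            return parts[0]
        raise TypeError(type(h))

    return satisfiable(sympy.Xor(to_sympy(f), to_sympy(g))) is False
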