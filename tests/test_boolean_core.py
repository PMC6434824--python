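"""Function representation, evaluation and Blake-canonical normalization."""

import pytest
from hypothesis import given, settings, strategies as st

from boolrepair.boolean_core import (
    DNFFunction,
    FunctionTree,
    MissingValueError,
    DegenerateFunctionError,
    MonotonicityError,
    RegulatorLiteral as L,
    check_monotone_nondegenerate,
    dnf_to_tree,
    equivalent,
    evaluate,
    flatten,
    normalize,
    truth_table,
    truth_table_diff,
)
from helpers import (
    brute_force_prime_implicants,
    normalized_clause_set,
    sympy_equivalent,
)


def dnf(*clauses, target="f"):
    return DNFFunction(target, tuple(frozenset(c) for c in clauses))


KD = dnf({L("a", False), L("b")}, {L("a", False), L("c", False)}, target="d")


class TestEvaluate:
    @pytest.mark.parametrize(
        "state,expected",
        [
            ({"a": 1, "b": 1, "c": 0}, False),
            ({"a": 0, "b": 1, "c": 1}, True),
            ({"a": 0, "b": 0, "c": 0}, True),
            ({"a": 1, "b": 0, "c": 1}, False),
        ],
    )
    def test_dnf_evaluation(self, state, expected):
        assert evaluate(KD, state) is expected

    def test_identity_of_positive_literal(self):
        f = FunctionTree("identity", (L("b"),))
        assert evaluate(f, {"b": 0}) is False
        assert evaluate(f, {"b": 1}) is True

    def test_missing_regulator_is_reported_by_name(self):
        with pytest.raises(MissingValueError, match="'c'"):
            evaluate(KD, {"a": 0, "b": 1})

    def test_tree_operators(self):
        tree = FunctionTree(
            "and", (L("a"), FunctionTree("or", (L("b"), L("c"))))
        )
        assert evaluate(tree, {"a": 1, "b": 0, "c": 1})
        assert not evaluate(tree, {"a": 1, "b": 0, "c": 0})


class TestTruthTable:
    def test_and_gate(self):
        tt = truth_table(dnf({L("A"), L("B")}))
        assert tt.outputs == (False, False, False, True)

    def test_kd_true_rows(self):
        tt = truth_table(KD)
        # true exactly on {a=0,b=1,c=*} plus {a=0,b=0,c=0}
        truth = {
            i for i, (assign, out) in enumerate(tt.rows()) if out
        }
        expected = set()
        for i in range(8):
            a, b, c = (i >> 2) & 1, (i >> 1) & 1, i & 1
            if (not a and b) or (not a and not c):
                expected.add(i)
        assert truth == expected

    def test_or_with_negation(self):
        tt = truth_table(dnf({L("b")}, {L("c", False)}))
        # false only at b=0, c=1 (row index 0b01)
        assert tt.outputs == (True, False, True, True)


class TestNormalize:
    def test_complementation(self):
        f = dnf({L("a", False), L("b")}, {L("a", False), L("b", False)})
        assert normalized_clause_set(normalize(f)) == {frozenset({("a", False)})}

    def test_absorption(self):
        f = dnf({L("b")}, {L("b"), L("c")})
        assert normalized_clause_set(normalize(f)) == {frozenset({("b", True)})}

    def test_kd_is_its_own_prime_implicant_set(self):
        assert normalized_clause_set(normalize(KD)) == {
            frozenset({("a", False), ("b", True)}),
            frozenset({("a", False), ("c", False)}),
        }

    def test_matches_brute_force_enumerator(self):
        for f in [
            KD,
            dnf({L("a")}, {L("b"), L("c", False)}),
            dnf({L("a"), L("b")}, {L("b"), L("c")}, {L("a"), L("c")}),
        ]:
            expected = {
                frozenset((v, val) for v, val in cube)
                for cube in brute_force_prime_implicants(f)
            }
            assert normalized_clause_set(normalize(f)) == expected

    def test_constant_function_rejected(self):
        with pytest.raises(DegenerateFunctionError):
            normalize(dnf({L("a")}, {L("a", False)}))

    def test_dual_sign_rejected(self):
        with pytest.raises(MonotonicityError, match="a"):
            normalize(dnf({L("a"), L("b")}, {L("a", False), L("c")}))


class TestFlatten:
    def test_distribution(self):
        tree = FunctionTree("and", (L("a"), FunctionTree("or", (L("b"), L("c")))))
        assert normalized_clause_set(flatten(tree)) == {
            frozenset({("a", True), ("b", True)}),
            frozenset({("a", True), ("c", True)}),
        }

    def test_single_literal_or(self):
        assert normalized_clause_set(flatten(FunctionTree("or", (L("a"),)))) == {
            frozenset({("a", True)})
        }

    def test_distribution_keeps_absorbed_clauses(self):
        tree = FunctionTree(
            "and",
            (
                FunctionTree("or", (L("a"), L("b"))),
                FunctionTree("or", (L("a"), L("c", False))),
            ),
        )
        flat = flatten(tree)
        assert normalized_clause_set(flat) == {
            frozenset({("a", True)}),
            frozenset({("a", True), ("c", False)}),
            frozenset({("a", True), ("b", True)}),
            frozenset({("b", True), ("c", False)}),
        }

    def test_dual_sign_in_one_clause_rejected(self):
        tree = FunctionTree("and", (L("a"), L("a", False)))
        with pytest.raises(MonotonicityError):
            flatten(tree)


class TestEquivalenceAndDiff:
    def test_complement_pair_equivalent_to_single_literal(self):
        f = dnf({L("a", False), L("b")}, {L("a", False), L("b", False)})
        assert equivalent(f, dnf({L("a", False)}))

    def test_and_vs_or(self):
        assert not equivalent(dnf({L("A"), L("B")}), dnf({L("A")}, {L("B")}))

    def test_removal_changes_three_of_eight_rows(self):
        reduced = dnf({L("b")}, {L("c", False)})
        assert not equivalent(KD, reduced)
        assert truth_table_diff(KD, reduced) == 3

    def test_diff_identity_and_negation(self):
        assert truth_table_diff(KD, KD) == 0
        assert truth_table_diff(dnf({L("a")}), dnf({L("a", False)})) == 2


class TestMonotoneNondegenerateReport:
    def test_dual_sign_detected(self):
        rep = check_monotone_nondegenerate(
            dnf({L("a"), L("b")}, {L("a", False), L("c")})
        )
        assert rep.dual_sign == {"a"}

    def test_inessential_detected(self):
        rep = check_monotone_nondegenerate(
            dnf({L("a"), L("b")}, {L("a"), L("b", False)})
        )
        assert "b" in rep.inessential

    def test_clean_function(self):
        rep = check_monotone_nondegenerate(dnf({L("b")}, {L("c", False)}))
        assert rep.ok


# --- property tests -------------------------------------------------------

_VARS = ("a", "b", "c", "d")


@st.composite
def monotone_dnfs(draw):
    """Random monotone DNFs: a global sign per variable, 1-4 clauses."""
    n = draw(st.integers(1, 4))
    variables = _VARS[:n]
    signs = {v: draw(st.booleans()) for v in variables}
    n_clauses = draw(st.integers(1, 4))
    clauses = []
    for _ in range(n_clauses):
        size = draw(st.integers(1, n))
        members = draw(
            st.sets(st.sampled_from(variables), min_size=size, max_size=size)
        )
        clauses.append(frozenset(L(v, signs[v]) for v in members))
    return DNFFunction("f", tuple(clauses))


@settings(max_examples=150, derandomize=True, deadline=None)
@given(monotone_dnfs())
def test_normalize_idempotent_and_equivalent(f):
    try:
        g = normalize(f)
    except DegenerateFunctionError:
        return
    assert normalize(g) == g
    assert equivalent(f, g)


@settings(max_examples=100, derandomize=True, deadline=None)
@given(monotone_dnfs(), monotone_dnfs())
def test_normal_forms_coincide_iff_equivalent(f, g):
    try:
        nf, ng = normalize(f), normalize(g)
    except DegenerateFunctionError:
        return
    same = normalized_clause_set(nf) == normalized_clause_set(ng)
    assert same == equivalent(f, g)
    assert (truth_table_diff(f, g) == 0) == equivalent(f, g)


@settings(max_examples=75, derandomize=True, deadline=None)
@given(monotone_dnfs())
def test_flatten_of_tree_preserves_equivalence(f):
    tree = dnf_to_tree(f)
    assert equivalent(tree, flatten(tree))


@settings(max_examples=40, derandomize=True, deadline=None)
@given(monotone_dnfs(), monotone_dnfs())
def test_equivalence_agrees_with_sat_oracle(f, g):
    assert equivalent(f, g) == sympy_equivalent(f, g)
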