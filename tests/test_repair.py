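"""Atomic repairs, reachability of functions, and the minimal-repair search."""

import itertools

import pytest

from boolrepair import (
    AtomicRepair,
    GenConfig,
    apply_repair,
    apply_repairs,
    candidate_repairs,
    check_consistency,
    common_repairs,
    generate_series,
    parse_model,
    parse_timeseries,
    perturb,
    random_model,
    reachable_functions,
    repair_minimal,
    truth_table,
)
from boolrepair.boolean_core import DNFFunction, RegulatorLiteral as L
from boolrepair.repair import LastRegulatorError
from helpers import brute_force_minimal_repairs


def tt_key(expr_text: str, variables: tuple):
    """Truth-table tuple of a DNF given as model-dialect text."""
    m = parse_model(f"f = {expr_text}\n")
    return truth_table(m.functions["f"], variables).outputs


class TestCandidates:
    def test_and_gate_has_five_loci(self, and_gate_model):
        cands = candidate_repairs(and_gate_model, "nsr")
        assert [(c.kind, c.locus) for c in cands] == [
            ("n", "b"), ("n", "c"), ("r", "b"), ("r", "c"), ("s", "n0"),
        ]

    def test_last_regulator_removal_not_offered(self):
        m = parse_model("d = b\n")
        kinds = {c.kind for c in candidate_repairs(m, "nsr")}
        assert "r" not in kinds
        # identity operator is a no-op for s and not offered either
        assert "s" not in kinds

    def test_repairable_list_restricts_targets(self):
        m = parse_model("d = b & c\ne = d\n")
        cands = candidate_repairs(m, "nsr", repairable=["d"])
        assert {c.target for c in cands} == {"d"}


class TestApplyRepair:
    def test_removal_of_a_from_kd(self, table2_model):
        m2 = apply_repair(table2_model, AtomicRepair("r", "d", "a"))
        assert str(m2.function_dnf("d")) == "b | !c"

    def test_operator_substitution_and_to_or(self, and_gate_model):
        m2 = apply_repair(and_gate_model, AtomicRepair("s", "d", "n0"))
        assert str(m2.function_dnf("d")) == "b | c"

    def test_negation_flips_all_occurrences(self, table2_model):
        m2 = apply_repair(table2_model, AtomicRepair("n", "d", "a"))
        assert str(m2.function_dnf("d")) == "(a & b) | (a & !c)"

    def test_last_regulator_guard(self):
        m = parse_model("d = b\n")
        with pytest.raises(LastRegulatorError):
            apply_repair(m, AtomicRepair("r", "d", "b"))

    def test_removing_every_regulator_guarded(self, and_gate_model):
        with pytest.raises(LastRegulatorError):
            apply_repairs(
                and_gate_model,
                [AtomicRepair("r", "d", "b"), AtomicRepair("r", "d", "c")],
            )

    def test_set_application_is_order_independent(self, table2_model):
        reps = [
            AtomicRepair("n", "d", "a"),
            AtomicRepair("r", "d", "c"),
            AtomicRepair("s", "d", "n0"),
        ]
        expected = apply_repairs(table2_model, reps)
        for perm in itertools.permutations(reps):
            model = table2_model
            for rep in perm:
                model = apply_repair(model, rep)
            assert model.function_dnf("d") == expected.function_dnf("d")


class TestReachableFunctions:
    VARS = ("A", "B")

    def test_and_gate_covers_twelve_functions(self):
        f = DNFFunction("f", (frozenset({L("A"), L("B")}),))
        reach = reachable_functions(f, "nsr")
        assert len(reach) == 12
        assert tt_key("A & B", self.VARS) in reach
        assert tt_key("!A | B", self.VARS) in reach  # implication
        xor = (False, True, True, False)
        nxor = (True, False, False, True)
        const_true = (True,) * 4
        const_false = (False,) * 4
        assert {xor, nxor, const_true, const_false} & reach == set()

    def test_empty_kind_set_reaches_only_itself(self):
        f = DNFFunction("f", (frozenset({L("A"), L("B")}),))
        assert reachable_functions(f, "") == {tt_key("A & B", self.VARS)}

    def test_removal_only_reaches_projections(self):
        f = DNFFunction("f", (frozenset({L("A"), L("B")}),))
        assert reachable_functions(f, "r") == {
            tt_key("A & B", self.VARS),
            tt_key("A", self.VARS),
            tt_key("B", self.VARS),
        }

    @pytest.mark.parametrize(
        "target_expr,kinds",
        [
            ("!A & !B", "n"),
            ("!A & B", "n"),
            ("A & !B", "n"),
            ("A | B", "s"),
            ("!A | B", "sn"),
            ("A | !B", "sn"),
            ("!A | !B", "sn"),
            ("A", "r"),
            ("B", "r"),
            ("!A", "rn"),
            ("!B", "rn"),
        ],
    )
    def test_listed_repair_kinds_suffice_per_target(self, target_expr, kinds):
        f = DNFFunction("f", (frozenset({L("A"), L("B")}),))
        assert tt_key(target_expr, self.VARS) in reachable_functions(f, kinds)

    def test_all_reachable_functions_are_monotone(self):
        f = DNFFunction("f", (frozenset({L("A"), L("B")}),))
        for outputs in reachable_functions(f, "nsr"):
            # unate check per variable over the 2-var table (A,B) rows 00,01,10,11
            a_incr = outputs[0] <= outputs[2] and outputs[1] <= outputs[3]
            a_decr = outputs[0] >= outputs[2] and outputs[1] >= outputs[3]
            b_incr = outputs[0] <= outputs[1] and outputs[2] <= outputs[3]
            b_decr = outputs[0] >= outputs[1] and outputs[2] >= outputs[3]
            assert (a_incr or a_decr) and (b_incr or b_decr)


class TestRepairMinimal:
    def test_toy_steady_instance_three_solutions(
        self, and_gate_model, steady_conflict_series
    ):
        res = repair_minimal(and_gate_model, steady_conflict_series, "steady", "nsr")
        assert res.status == "optimal"
        assert res.cardinality == 1
        assert {s.sorted_repairs() for s in res.solutions} == {
            (AtomicRepair("n", "d", "c"),),
            (AtomicRepair("r", "d", "c"),),
            (AtomicRepair("s", "d", "n0"),),
        }

    def test_consistent_instance_yields_empty_solution(self, and_gate_model):
        ts = parse_timeseries("comp\t0\nb\t1\nc\t1\nd\t1\n", "e1")
        res = repair_minimal(and_gate_model, ts, "steady", "nsr")
        assert res.status == "optimal"
        assert res.cardinality == 0
        assert len(res.solutions) == 1
        assert res.solutions[0].repairs == frozenset()

    def test_removal_only_kind_restriction(
        self, and_gate_model, steady_conflict_series
    ):
        res = repair_minimal(and_gate_model, steady_conflict_series, "steady", "r")
        assert res.cardinality == 1
        assert [s.sorted_repairs() for s in res.solutions] == [
            (AtomicRepair("r", "d", "c"),)
        ]

    def test_repairable_list_excluding_culprit_is_infeasible(
        self, and_gate_model, steady_conflict_series
    ):
        res = repair_minimal(
            and_gate_model, steady_conflict_series, "steady", "nsr",
            repairable=["b"],
        )
        assert res.status == "infeasible"
        assert res.solutions == []

    def test_solutions_are_sound_and_minimal(
        self, and_gate_model, steady_conflict_series
    ):
        res = repair_minimal(and_gate_model, steady_conflict_series, "steady", "nsr")
        for sol in res.solutions:
            rep = check_consistency(sol.model, steady_conflict_series, "steady")
            assert rep.consistent
            for drop in sol.repairs:
                smaller = apply_repairs(
                    and_gate_model, sol.repairs - {drop}
                )
                assert not check_consistency(
                    smaller, steady_conflict_series, "steady"
                ).consistent

    def test_budget_exhaustion_is_anytime(
        self, and_gate_model, steady_conflict_series
    ):
        res = repair_minimal(
            and_gate_model, steady_conflict_series, "steady", "nsr", budget=1
        )
        assert res.status == "undecided"

    def test_matches_brute_force_on_random_instances(self):
        for seed in range(8):
            m = random_model(GenConfig(n_nodes=4, arity_lambda=1.5, seed=seed))
            ts = generate_series(m, "sync", 3, seed=seed + 50)
            noisy, _ = perturb(ts, 0.1, seed=seed + 90)
            res = repair_minimal(m, noisy, "sync", "nsr", max_cardinality=2)
            k_bf, sols_bf = brute_force_minimal_repairs(
                m, noisy, "sync", "nsr", max_k=2
            )
            if res.status == "infeasible":
                assert k_bf is None
            else:
                assert res.cardinality == k_bf
                assert {s.repairs for s in res.solutions} == sols_bf

    def test_invertible_plants_always_recovered(self):
        """Sign flips and operator swaps are involutions: a model damaged by
        one n/s repair is always within one repair of consistency."""
        import numpy as np

        for seed in range(30):
            rng = np.random.default_rng(seed)
            m = random_model(GenConfig(n_nodes=5, arity_lambda=1.5, seed=seed))
            ts = generate_series(m, "sync", 4, seed=seed + 500)
            cands = [
                c for c in candidate_repairs(m, "ns") if c.kind in ("n", "s")
            ]
            rep = cands[int(rng.integers(0, len(cands)))]
            damaged = apply_repair(m, rep)
            res = repair_minimal(damaged, ts, "sync", "nsr", max_cardinality=1)
            assert res.status == "optimal" and res.cardinality <= 1

    def test_multiple_experiments_must_hold_jointly(self):
        m = parse_model("b = a\n")
        ts1 = parse_timeseries("comp\t0\t1\na\t1\t1\nb\t0\t1\n", "e1")
        ts2 = parse_timeseries("comp\t0\t1\na\t0\t0\nb\t1\t0\n", "e2")
        # e1 wants b to follow a; e2 (a=0 -> b=0) agrees: consistent
        res = repair_minimal(m, [ts1, ts2], "sync", "nsr")
        assert res.cardinality == 0
        ts3 = parse_timeseries("comp\t0\t1\na\t1\t1\nb\t0\t0\n", "e3")
        # e3 contradicts e1's demand under any single model? n-repair breaks e1
        res2 = repair_minimal(m, [ts1, ts3], "sync", "nsr")
        assert res2.status == "infeasible"


class TestCommonRepairs:
    def test_repair_in_all_solutions_is_100_percent(
        self, and_gate_model, steady_conflict_series
    ):
        res = repair_minimal(and_gate_model, steady_conflict_series, "steady", "r")
        df = common_repairs(res.solutions)
        assert df.iloc[0]["percent"] == 100.0

    def test_toy_instance_each_repair_one_third(
        self, and_gate_model, steady_conflict_series
    ):
        res = repair_minimal(and_gate_model, steady_conflict_series, "steady", "nsr")
        df = common_repairs(res.solutions)
        assert len(df) == 3
        assert all(abs(p - 100.0 / 3) < 1e-9 for p in df["percent"])

    def test_empty_solution_yields_empty_table(self, and_gate_model):
        ts = parse_timeseries("comp\t0\nb\t1\nc\t1\nd\t1\n", "e1")
        res = repair_minimal(and_gate_model, ts, "steady", "nsr")
        assert common_repairs(res.solutions).empty
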