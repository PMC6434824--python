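"""Updating-scheme semantics and model-vs-time-series consistency checking.

Three updating schemes are supported:

``steady_state``
    every observed column must be completable to a stable state (a state in
    which every function returns its component's current value);

``synchronous``
    all components update simultaneously: an observed value at step ``t >= 1``
    must equal the function applied to the (completed) column ``t-1``;

``asynchronous``
    one component is validated per iteration, following a *visit schedule*:
    every component is visited exactly once at every step ``1..T``, a
    component's visits occur in step order, and the value checked at a visit
    is the function evaluated on the *current* values of the regulators (each
    regulator's most recently assigned value).  The very first visit of a
    schedule is exempt — nothing is yet known about its regulators.

Missing observations are completed existentially: the checker searches for a
completion (and, asynchronously, a schedule) with the fewest inconsistent
observation points, returning it as a witness.  The search is budgeted; an
exhausted budget yields an explicit *undecided* status, never a silent
answer.  Column 0 is the initial condition and is never checked against the
functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Iterator, Mapping

from .boolean_core import evaluate
from .model_io import BooleanModel, TimeSeries, validate

__all__ = [
    "SCHEMES",
    "canonical_scheme",
    "BudgetExhaustedError",
    "Visit",
    "VisitSchedule",
    "ExperimentResult",
    "ConsistencyReport",
    "sync_step",
    "simulate",
    "is_stable",
    "check_consistency",
    "async_value_rule",
    "enumerate_schedules",
]

SCHEMES = ("steady_state", "synchronous", "asynchronous")
_ALIASES = {
    "steady": "steady_state",
    "steady_state": "steady_state",
    "sync": "synchronous",
    "synchronous": "synchronous",
    "async": "asynchronous",
    "asynchronous": "asynchronous",
}

#: default cap on search-node expansions per experiment
DEFAULT_BUDGET = 200_000


def canonical_scheme(scheme: str) -> str:
    try:
        return _ALIASES[scheme.lower()]
    except KeyError:
        raise ValueError(
            f"unknown updating scheme {scheme!r}; expected one of "
            f"{sorted(set(_ALIASES))}"
        ) from None


class BudgetExhaustedError(RuntimeError):
    """The search budget ran out before the enumeration completed."""


@dataclass(frozen=True)
class Visit:
    """One validation event: component ``component`` at step ``step``,
    performed as iteration ``iteration`` (1-based) of the schedule."""

    experiment: str
    component: str
    step: int
    iteration: int


@dataclass(frozen=True)
class VisitSchedule:
    """An interleaved visiting order covering every component at every step
    ``1..T`` exactly once, one visit per iteration."""

    visits: tuple[Visit, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "visits", tuple(self.visits))

    def __len__(self) -> int:
        return len(self.visits)

    def __iter__(self) -> Iterator[Visit]:
        return iter(self.visits)


@dataclass
class ExperimentResult:
    """Per-experiment outcome of a consistency check."""

    experiment: str
    inconsistent_points: frozenset
    completion: dict | None = None
    schedule: VisitSchedule | None = None
    undecided: bool = False

    @property
    def violations(self) -> int:
        return len(self.inconsistent_points)

    @property
    def consistent(self) -> bool:
        return not self.inconsistent_points and not self.undecided


@dataclass
class ConsistencyReport:
    """Aggregate of :class:`ExperimentResult` across experiments."""

    scheme: str
    experiments: dict

    @property
    def consistent(self) -> bool:
        return all(r.consistent for r in self.experiments.values())

    @property
    def undecided(self) -> bool:
        return any(r.undecided for r in self.experiments.values())

    @property
    def inconsistent_points(self) -> frozenset:
        out = set()
        for r in self.experiments.values():
            out |= {(r.experiment, c, t) for (c, t) in r.inconsistent_points}
        return frozenset(out)

    @property
    def inconsistent_components(self) -> frozenset:
        return frozenset(c for (_, c, _) in self.inconsistent_points)

    def summary(self) -> str:
        lines = [f"scheme: {self.scheme}"]
        for name in sorted(self.experiments):
            r = self.experiments[name]
            if r.consistent:
                lines.append(f"{name}: consistent")
            elif r.undecided:
                lines.append(
                    f"{name}: undecided (budget exhausted; best found has "
                    f"{r.violations} inconsistent point(s))"
                )
            else:
                pts = ", ".join(
                    f"({c}, t={t})" for c, t in sorted(r.inconsistent_points)
                )
                lines.append(f"{name}: inconsistent at {pts}")
        return "\n".join(lines)


def sync_step(m: BooleanModel, state: Mapping[str, int]) -> dict:
    """One synchronous update: every non-input is replaced by its function's
    value on ``state``; inputs keep their value."""
    nxt = {}
    for c in m.components:
        if c in m.inputs:
            nxt[c] = int(bool(state[c]))
        else:
            nxt[c] = int(evaluate(m.functions[c], state))
    return nxt


def simulate(m: BooleanModel, state: Mapping[str, int], steps: int) -> list[dict]:
    """Synchronous trajectory of ``steps + 1`` states starting from ``state``."""
    cur = {c: int(bool(state[c])) for c in m.components}
    out = [cur]
    for _ in range(steps):
        cur = sync_step(m, cur)
        out.append(cur)
    return out


def is_stable(m: BooleanModel, state: Mapping[str, int]) -> frozenset:
    """Components whose function disagrees with their current value.

    An empty set means ``state`` is a stable state (no component is called
    to update).  Inputs never violate stability.
    """
    bad = set()
    for c, tree in m.functions.items():
        if int(evaluate(tree, state)) != int(bool(state[c])):
            bad.add(c)
    return frozenset(bad)


def check_consistency(
    m: BooleanModel,
    ts_list: Iterable[TimeSeries] | TimeSeries,
    scheme: str,
    budget: int | None = None,
    sat_only: bool = False,
) -> ConsistencyReport:
    """Check ``m`` against one or more experiments under ``scheme``.

    Returns a report with, per experiment, the observation points that no
    completion (and schedule, asynchronously) can satisfy, together with a
    witness completion/schedule minimizing the number of violations.

    With ``sat_only`` the asynchronous search stops as soon as any visit
    fails instead of minimizing the violation count — much faster for a
    yes/no answer (the repair search uses this); inconsistent reports then
    list the observation points that blocked the explored branches rather
    than a minimum-violation witness.
    """
    if isinstance(ts_list, TimeSeries):
        ts_list = [ts_list]
    ts_list = list(ts_list)
    scheme = canonical_scheme(scheme)
    report = validate(m, ts_list)
    if not report.ok:
        raise ValueError(
            "model/time-series validation failed:\n" + "\n".join(report.messages)
        )
    if budget is None:
        budget = DEFAULT_BUDGET
    results = {}
    for ts in ts_list:
        if scheme == "steady_state":
            results[ts.experiment] = _check_steady(m, ts, budget)
        elif scheme == "synchronous":
            results[ts.experiment] = _check_sync(m, ts, budget)
        else:
            results[ts.experiment] = _check_async(m, ts, budget, sat_only)
    return ConsistencyReport(scheme, results)


def _assignments(names: list, budget_box: list) -> Iterator[dict]:
    """All 0/1 assignments over ``names``, charging one budget unit each."""
    for values in product((0, 1), repeat=len(names)):
        budget_box[0] -= 1
        if budget_box[0] < 0:
            raise BudgetExhaustedError
        yield dict(zip(names, values))


def _input_constants(m: BooleanModel, ts: TimeSeries) -> tuple[dict, list]:
    """Observed constant values of inputs, and the unobserved (free) inputs."""
    const: dict = {}
    free: list = []
    for i in sorted(m.inputs):
        values = [ts.get(i, t) for t in range(ts.steps + 1)]
        seen = [v for v in values if v is not None]
        if seen:
            const[i] = seen[0]  # validate() guarantees agreement
        else:
            free.append(i)
    return const, free


def _check_steady(m: BooleanModel, ts: TimeSeries, budget: int) -> ExperimentResult:
    """Each column independently completable to a stable state."""
    budget_box = [budget]
    all_points: set = set()
    completion: dict = {}
    undecided = False
    for t in range(ts.steps + 1):
        observed = {c: ts.get(c, t) for c in m.components}
        free = sorted(c for c, v in observed.items() if v is None)
        best: tuple[frozenset, dict] | None = None
        try:
            for fill in _assignments(free, budget_box):
                state = {c: (observed[c] if observed[c] is not None else fill[c])
                         for c in m.components}
                bad = is_stable(m, state)
                if best is None or len(bad) < len(best[0]):
                    best = (bad, state)
                if not bad:
                    break
        except BudgetExhaustedError:
            undecided = True
        if best is None:
            undecided = True
            continue
        bad, state = best
        if bad:
            all_points |= {(c, t) for c in bad}
        completion.update({(c, t): state[c] for c in m.components})
    return ExperimentResult(
        ts.experiment,
        frozenset(all_points),
        completion or None,
        None,
        undecided and bool(all_points),
    )


def _check_sync(m: BooleanModel, ts: TimeSeries, budget: int) -> ExperimentResult:
    """Existential completion of column 0 (and unobserved input constants),
    then deterministic forward propagation.

    Observed values are kept as ground truth during propagation, so each
    mismatch is localized to the single observation it contradicts.
    """
    const, free_inputs = _input_constants(m, ts)
    free_cells = sorted(
        c
        for c in m.components
        if c not in m.inputs and ts.get(c, 0) is None
    )
    names = [("cell", c) for c in free_cells] + [("input", i) for i in free_inputs]
    budget_box = [budget]
    best: tuple[list, dict] | None = None
    undecided = False
    try:
        for fill in _assignments(names, budget_box):
            inputs = dict(const)
            inputs.update({i: fill[("input", i)] for i in free_inputs})
            col = {}
            for c in m.components:
                if c in m.inputs:
                    col[c] = inputs[c]
                else:
                    v = ts.get(c, 0)
                    col[c] = v if v is not None else fill[("cell", c)]
            violations: list = []
            completion = {(c, 0): col[c] for c in m.components}
            prev = col
            for t in range(1, ts.steps + 1):
                cur = {}
                for c in m.components:
                    if c in m.inputs:
                        pred = inputs[c]
                    else:
                        pred = int(evaluate(m.functions[c], prev))
                    obs = ts.get(c, t)
                    if obs is not None and obs != pred:
                        violations.append((c, t))
                    cur[c] = obs if obs is not None else pred
                    completion[(c, t)] = cur[c]
                prev = cur
            if best is None or len(violations) < len(best[0]):
                best = (violations, completion)
            if not violations:
                break
    except BudgetExhaustedError:
        undecided = True
    if best is None:
        return ExperimentResult(ts.experiment, frozenset(), None, None, True)
    violations, completion = best
    return ExperimentResult(
        ts.experiment,
        frozenset(violations),
        completion,
        None,
        undecided and bool(violations),
    )


def _check_async(
    m: BooleanModel, ts: TimeSeries, budget: int, sat_only: bool = False
) -> ExperimentResult:
    """Joint search over visit schedules and missing-value completions.

    Depth-first over iterations with memoization on (pending-steps, current
    values); the cost of a branch is the number of visits whose observed
    value contradicts the function on the current regulator values.  The
    first visit of a schedule carries no constraint.  In ``sat_only`` mode
    any violating visit prunes its branch immediately (the blocked points
    are collected for the report).
    """
    comps = tuple(sorted(m.components))
    T = ts.steps
    const, free_inputs = _input_constants(m, ts)
    col0_free = sorted(
        c for c in comps if c not in m.inputs and ts.get(c, 0) is None
    )
    budget_box = [budget]
    best: dict = {"cost": None, "trail": None, "bad": None, "start": None}
    blocked: set = set()
    cost_limit = 1 if sat_only else None

    n = len(comps)
    idx = {c: i for i, c in enumerate(comps)}

    def dfs(pending, current, first_done, cost, trail, bad, memo, start):
        if cost_limit is not None and cost >= cost_limit:
            return
        if best["cost"] is not None and cost >= best["cost"]:
            return
        key = (pending, current, first_done)
        prev = memo.get(key)
        if prev is not None and prev <= cost:
            return
        memo[key] = cost
        budget_box[0] -= 1
        if budget_box[0] < 0:
            raise BudgetExhaustedError
        if all(p > T for p in pending):
            best.update(
                cost=cost, trail=list(trail), bad=set(bad), start=start
            )
            return
        for i, c in enumerate(comps):
            step = pending[i]
            if step > T:
                continue
            obs = ts.get(c, step)
            if c in m.inputs:
                computed = current[i]
            else:
                state = {comps[j]: current[j] for j in range(n)}
                computed = int(evaluate(m.functions[c], state))
            if not first_done:
                # first visit of the schedule: consistent by definition
                choices = [obs] if obs is not None else [0, 1]
                for v in choices:
                    descend(pending, current, i, step, v, cost, trail, bad,
                            memo, start)
            elif obs is not None:
                if obs == computed:
                    descend(pending, current, i, step, obs, cost, trail,
                            bad, memo, start)
                elif sat_only:
                    blocked.add((c, step))
                else:
                    bad.append((c, step))
                    descend(pending, current, i, step, obs, cost + 1, trail,
                            bad, memo, start)
                    bad.pop()
            else:
                descend(pending, current, i, step, computed, cost, trail,
                        bad, memo, start)

    def descend(pending, current, i, step, value, cost, trail, bad, memo,
                start):
        p2 = list(pending)
        p2[i] += 1
        c2 = list(current)
        c2[i] = value
        trail.append((comps[i], step, value))
        dfs(tuple(p2), tuple(c2), True, cost, trail, bad, memo, start)
        trail.pop()

    undecided = False
    free_idx = [idx[i] for i in free_inputs]
    try:
        for fill in _assignments(col0_free, budget_box):
            initial = []
            for c in comps:
                if c in m.inputs:
                    initial.append(const.get(c, 0))
                else:
                    v = ts.get(c, 0)
                    initial.append(v if v is not None else fill[c])
            for input_fill in product((0, 1), repeat=len(free_idx)):
                start = list(initial)
                for j, v in zip(free_idx, input_fill):
                    start[j] = v
                start = tuple(start)
                dfs(tuple([1] * n), start, False, 0, [], [], {}, start)
                if best["cost"] == 0:
                    break
            if best["cost"] == 0:
                break
    except BudgetExhaustedError:
        undecided = True

    if best["cost"] is None:
        if sat_only and not undecided:
            # exhausted the zero-violation search space: inconsistent, with
            # the observation points that blocked the explored branches
            return ExperimentResult(
                ts.experiment, frozenset(blocked), None, None, False
            )
        return ExperimentResult(ts.experiment, frozenset(), None, None, True)
    visits = tuple(
        Visit(ts.experiment, c, step, k + 1)
        for k, (c, step, _) in enumerate(best["trail"])
    )
    completion = {(c, 0): best["start"][idx[c]] for c in comps}
    for c, step, v in best["trail"]:
        completion[(c, step)] = v
    return ExperimentResult(
        ts.experiment,
        frozenset(best["bad"]),
        completion,
        VisitSchedule(visits),
        undecided and best["cost"] > 0,
    )


def async_value_rule(
    m: BooleanModel,
    ts: TimeSeries,
    schedule: VisitSchedule,
    completion: Mapping[tuple, int],
) -> bool:
    """The per-visit consistency predicate for a given schedule/completion.

    ``completion`` must assign a value to every ``(component, step)`` cell
    (column 0 included) and agree with the observed cells.  Returns True iff
    for every visit except the schedule's first, the value of the visited
    component at its step equals its function evaluated on the current
    regulator values (most recently assigned value of each regulator,
    initialized from column 0); inputs must hold their current value.
    """
    comps = tuple(sorted(m.components))
    for c in comps:
        if (c, 0) not in completion:
            raise ValueError(f"completion missing initial value for {c!r}")
    for (c, t), v in ts.observations.items():
        if completion.get((c, t)) != v:
            raise ValueError(
                f"completion disagrees with the observation at ({c}, {t})"
            )
    current = {c: completion[(c, 0)] for c in comps}
    first = True
    for visit in schedule:
        value = completion[(visit.component, visit.step)]
        if not first:
            if visit.component in m.inputs:
                expected = current[visit.component]
            else:
                expected = int(evaluate(m.functions[visit.component], current))
            if value != expected:
                return False
        current[visit.component] = value
        first = False
    return True


def enumerate_schedules(
    m: BooleanModel,
    ts: TimeSeries,
    budget: int | None = None,
) -> Iterator[VisitSchedule]:
    """Lazily yield all visit schedules for ``m`` against ``ts``.

    Each schedule visits every component exactly once at every step
    ``1..T`` (``|components| * T`` visits), per-component visits in step
    order, one visit per iteration — the full STG is never materialized.
    Components are tried in sorted order at each iteration, so the stream is
    deterministic.  When ``budget`` node expansions are exhausted a
    :class:`BudgetExhaustedError` is raised from the generator.
    """
    comps = tuple(sorted(m.components))
    T = ts.steps
    n = len(comps)
    budget_box = [budget if budget is not None else float("inf")]

    def rec(pending, it):
        budget_box[0] -= 1
        if budget_box[0] < 0:
            raise BudgetExhaustedError(
                "schedule enumeration budget exhausted"
            )
        if all(p > T for p in pending):
            yield ()
            return
        for i, c in enumerate(comps):
            step = pending[i]
            if step > T:
                continue
            p2 = list(pending)
            p2[i] += 1
            for rest in rec(tuple(p2), it + 1):
                yield ((c, step, it),) + rest

    for flat in rec(tuple([1] * n), 1):
        visits = tuple(
            Visit(ts.experiment, c, step, it) for (c, step, it) in flat
        )
        yield VisitSchedule(visits)
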