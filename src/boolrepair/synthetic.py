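"""Random instance generation mirroring the evaluation protocol.

Random models draw each non-input function's arity from a Poisson
distribution (lambda 1, 2 or 4; zero draws resampled, since a zero-arity
non-input would be an input), regulators uniformly without replacement
(self-regulation allowed), signs uniformly, and the function type — a single
``and`` or a single ``or`` over the drawn literals — uniformly.  Time series
are produced by running the model itself, so they are consistent by
construction; noise is injected by flipping a fixed fraction of cells
(5% typical) and missingness by deleting 10–30% of cells, both uniformly at
random.  All draws go through a seeded :class:`numpy.random.Generator`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .boolean_core import (
    OP_AND,
    OP_OR,
    DNFFunction,
    RegulatorLiteral,
    dnf_to_tree,
)
from .dynamics import simulate, sync_step, is_stable
from .model_io import BooleanModel, TimeSeries

__all__ = [
    "GenConfig",
    "random_model",
    "generate_series",
    "perturb",
    "delete_values",
    "default_activation_model",
    "prediction_rate",
]


@dataclass(frozen=True)
class GenConfig:
    """Generation parameters.

    ``n_nodes``            components in the model;
    ``arity_lambda``       Poisson parameter for function arity;
    ``steps``              number of time-series columns (>= 2 typical);
    ``perturb_fraction``   fraction of observed cells flipped (0.05 typical);
    ``delete_fraction``    fraction of observed cells deleted (0.1–0.3);
    ``input_fraction``     fraction of components left without a function;
    ``seed``               RNG seed.
    """

    n_nodes: int
    arity_lambda: float = 1.0
    steps: int = 3
    perturb_fraction: float = 0.05
    delete_fraction: float = 0.0
    input_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("n_nodes must be >= 2")
        if self.arity_lambda <= 0:
            raise ValueError("arity_lambda must be positive")
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        for name in ("perturb_fraction", "delete_fraction", "input_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")


def _component_names(n: int) -> tuple[str, ...]:
    width = len(str(n))
    return tuple(f"g{i:0{width}d}" for i in range(1, n + 1))


def random_model(cfg: GenConfig) -> BooleanModel:
    """Draw a random Boolean model; deterministic under ``cfg.seed``.

    Every non-input gets arity ``a ~ Poisson(arity_lambda)`` resampled into
    ``1 <= a <= n_nodes``, distinct uniformly drawn regulators, uniform
    signs, and a uniformly chosen single-operator function (``and``/``or``;
    ``identity`` when the arity is 1).
    """
    rng = np.random.default_rng(cfg.seed)
    names = _component_names(cfg.n_nodes)
    n_inputs = int(round(cfg.input_fraction * cfg.n_nodes))
    n_inputs = min(n_inputs, cfg.n_nodes - 1)
    input_idx = set(
        rng.choice(cfg.n_nodes, size=n_inputs, replace=False).tolist()
    ) if n_inputs else set()
    functions = {}
    for i, name in enumerate(names):
        if i in input_idx:
            continue
        arity = 0
        while not (1 <= arity <= cfg.n_nodes):
            arity = int(rng.poisson(cfg.arity_lambda))
        reg_idx = rng.choice(cfg.n_nodes, size=arity, replace=False)
        signs = rng.integers(0, 2, size=arity)
        literals = [
            RegulatorLiteral(names[int(j)], bool(s))
            for j, s in zip(reg_idx, signs)
        ]
        use_and = bool(rng.integers(0, 2))
        if use_and:
            clauses = (frozenset(literals),)
        else:
            clauses = tuple(frozenset([lit]) for lit in literals)
        functions[name] = dnf_to_tree(DNFFunction(name, clauses))
    inputs = frozenset(names[i] for i in input_idx)
    return BooleanModel(names, inputs, functions)


def generate_series(
    m: BooleanModel,
    scheme: str,
    steps: int,
    seed: int,
    experiment: str = "ts1",
) -> TimeSeries:
    """A complete trajectory of ``steps`` columns consistent with ``m``.

    Synchronous: iterate the update from a random initial state.
    Asynchronous: visit components in a random order within each step,
    assigning each the value of its function on the current values — an
    admissible schedule by construction.  Steady state: search for a stable
    state (random restarts followed by synchronous iteration, exhaustive for
    small models) and repeat it in every column; raises ``ValueError`` when
    none is found.
    """
    from .dynamics import canonical_scheme

    scheme = canonical_scheme(scheme)
    if steps < 1:
        raise ValueError("steps must be >= 1")
    rng = np.random.default_rng(seed)
    comps = tuple(sorted(m.components))
    T = steps - 1
    if scheme == "synchronous":
        init = {c: int(rng.integers(0, 2)) for c in comps}
        traj = simulate(m, init, T)
        obs = {(c, t): traj[t][c] for t in range(steps) for c in comps}
        return TimeSeries(experiment, comps, T, obs)
    if scheme == "asynchronous":
        current = {c: int(rng.integers(0, 2)) for c in comps}
        columns = [dict(current)]
        from .boolean_core import evaluate

        for _ in range(T):
            order = [comps[int(i)] for i in rng.permutation(len(comps))]
            for c in order:
                if c not in m.inputs:
                    current[c] = int(evaluate(m.functions[c], current))
            columns.append(dict(current))
        obs = {(c, t): columns[t][c] for t in range(steps) for c in comps}
        return TimeSeries(experiment, comps, T, obs)
    # steady state
    state = _find_stable_state(m, rng)
    if state is None:
        raise ValueError("no stable state found for this model")
    obs = {(c, t): state[c] for t in range(steps) for c in comps}
    return TimeSeries(experiment, comps, T, obs)


def _find_stable_state(m: BooleanModel, rng, restarts: int = 200):
    comps = tuple(sorted(m.components))
    n = len(comps)
    if n <= 12:
        for i in range(2**n):
            state = {c: (i >> (n - 1 - j)) & 1 for j, c in enumerate(comps)}
            if not is_stable(m, state):
                return state
        return None
    for _ in range(restarts):
        state = {c: int(rng.integers(0, 2)) for c in comps}
        for _ in range(4 * n):
            nxt = sync_step(m, state)
            if nxt == state:
                return state
            state = nxt
        if not is_stable(m, state):
            return state
    return None


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def perturb(ts: TimeSeries, fraction: float, seed: int):
    """Flip exactly ``round(fraction * #observed-cells)`` observed values.

    Cells are chosen uniformly without replacement; returns the perturbed
    series and the tuple of flipped ``(component, step)`` positions.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must be in [0, 1]")
    cells = ts.cells()
    k = _round_half_up(fraction * len(cells))
    rng = np.random.default_rng(seed)
    chosen_idx = rng.choice(len(cells), size=k, replace=False) if k else []
    flipped = tuple(sorted(cells[int(i)] for i in chosen_idx))
    updates = {cell: 1 - ts.observations[cell] for cell in flipped}
    return ts.with_values(updates), flipped


def delete_values(ts: TimeSeries, fraction: float, seed: int):
    """Delete (set missing) a uniform random fraction of observed cells.

    Exactly ``round(fraction * #observed-cells)`` cells are removed; returns
    the thinned series and the deleted-cell mask.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must be in [0, 1]")
    cells = ts.cells()
    k = _round_half_up(fraction * len(cells))
    rng = np.random.default_rng(seed)
    chosen_idx = rng.choice(len(cells), size=k, replace=False) if k else []
    mask = tuple(sorted(cells[int(i)] for i in chosen_idx))
    return ts.without_cells(mask), mask


def default_activation_model(graph) -> BooleanModel:
    """Build functions from a signed interaction graph by the default
    activation rule: a component is active when at least one activator is
    present and no inhibitor is — including that a component with only
    inactive activators becomes inactive.

    ``graph`` is an iterable of ``(regulator, target, sign)`` triples (sign
    ``'+'``/``'-'`` or True/False) or a :class:`networkx.DiGraph` with a
    ``sign`` edge attribute.  The function is ``(or of activators) and (and
    of negated inhibitors)``; with only inhibitors it is the conjunction of
    their negations.
    """
    try:
        import networkx as nx

        if isinstance(graph, nx.DiGraph):
            graph = [
                (u, v, d.get("sign", "+")) for u, v, d in graph.edges(data=True)
            ]
    except ImportError:  # pragma: no cover
        pass
    edges = []
    for reg, target, sign in graph:
        positive = sign in ("+", True, 1, "1", "positive")
        edges.append((str(reg), str(target), positive))
    nodes = sorted({e[0] for e in edges} | {e[1] for e in edges})
    by_target: dict[str, list] = {}
    for reg, target, positive in edges:
        by_target.setdefault(target, []).append((reg, positive))
    functions = {}
    for target, regs in sorted(by_target.items()):
        activators = sorted({r for r, p in regs if p})
        inhibitors = sorted({r for r, p in regs if not p})
        neg = [RegulatorLiteral(i, False) for i in inhibitors]
        if activators:
            clauses = tuple(
                frozenset([RegulatorLiteral(a, True), *neg])
                for a in activators
            )
        else:
            clauses = (frozenset(neg),)
        functions[target] = dnf_to_tree(DNFFunction(target, clauses))
    inputs = frozenset(set(nodes) - set(functions))
    return BooleanModel(tuple(nodes), inputs, functions)


def prediction_rate(
    original_ts: TimeSeries,
    recovered: Mapping[tuple, int] | TimeSeries,
    mask: Iterable[tuple],
) -> float:
    """Percentage of deleted cells recovered *incorrectly*.

    ``recovered`` is a witness completion (cell -> value) or a completed
    series; ``mask`` the deleted cells.  The rate is relative to the number
    of deleted values, not the whole matrix.  Raises ``ValueError`` on an
    empty mask (the rate is undefined).
    """
    mask = list(mask)
    if not mask:
        raise ValueError("prediction rate undefined for an empty mask")
    if isinstance(recovered, TimeSeries):
        values = {cell: recovered.get(*cell) for cell in mask}
    else:
        values = {cell: recovered.get(cell) for cell in mask}
    wrong = 0
    for cell in mask:
        truth = original_ts.get(*cell)
        if truth is None:
            raise ValueError(f"mask cell {cell} not observed in the original series")
        if values[cell] != truth:
            wrong += 1
    return 100.0 * wrong / len(mask)
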