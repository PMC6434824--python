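"""Parsing and serialization of Boolean models and time-series matrices.

Model dialect (boolSim-style DNF, one statement per line)::

    # comment
    input a
    d = (!a & b) | (!a & !c)

A statement ``target = clause | clause | ...`` gives the regulatory function
of ``target``; a clause is ``lit & lit & ...`` with ``!`` for negation and
identifiers over ``[A-Za-z0-9_]``.  Parentheses around a clause are optional.
Components that never appear on a left-hand side are *inputs* (constant
value); an explicit ``input x`` line is also accepted.  Functions are
normalized on load (Blake canonical form), so structurally different but
equivalent inputs produce the same in-memory model.

Time-series format: tab- or comma-separated matrix, first column the
component name, header row the time steps ``0..T``; a blank cell or ``?``
marks a missing observation.  One file holds one experiment.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .boolean_core import (
    DNFFunction,
    FunctionTree,
    RegulatorLiteral,
    dnf_to_tree,
    flatten,
    normalize,
)

__all__ = [
    "BooleanModel",
    "TimeSeries",
    "ValidationReport",
    "ModelParseError",
    "TimeSeriesParseError",
    "parse_model",
    "write_model",
    "parse_timeseries",
    "write_timeseries",
    "validate",
]


class ModelParseError(ValueError):
    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class TimeSeriesParseError(ValueError):
    pass


_IDENT = re.compile(r"[A-Za-z0-9_]+\Z")
_RESERVED = {"input"}


@dataclass(frozen=True)
class BooleanModel:
    """A Boolean logical regulatory graph.

    ``components`` is the sorted tuple of component names, ``inputs`` the
    subset without regulators (constant value), and ``functions`` maps every
    non-input to its operator tree.  The signed edge set is derived from the
    function literals, so there are never dangling regulations.
    """

    components: tuple[str, ...]
    inputs: frozenset
    functions: Mapping[str, FunctionTree] = field(default_factory=dict)

    def __post_init__(self) -> None:
        comps = set(self.components)
        if len(self.components) != len(comps):
            raise ValueError("duplicate component names")
        if not comps:
            raise ValueError("model has no components")
        non_inputs = comps - self.inputs
        if set(self.functions) != non_inputs:
            missing = non_inputs - set(self.functions)
            extra = set(self.functions) - non_inputs
            raise ValueError(
                f"every non-input needs exactly one function "
                f"(missing: {sorted(missing)}, unexpected: {sorted(extra)})"
            )

    @property
    def edges(self) -> frozenset:
        """Signed edges ``(regulator, target, positive)`` derived from functions."""
        out = set()
        for target, tree in self.functions.items():
            for lit in tree.iter_literals():
                out.add((lit.regulator, target, lit.positive))
        return frozenset(out)

    def function_dnf(self, component: str) -> DNFFunction:
        return flatten(self.functions[component], target=component)

    def with_function(self, component: str, tree: FunctionTree) -> "BooleanModel":
        funcs = dict(self.functions)
        funcs[component] = tree
        return BooleanModel(self.components, self.inputs, funcs)

    def normalized(self) -> "BooleanModel":
        funcs = {
            c: dnf_to_tree(normalize(flatten(t, target=c)))
            for c, t in self.functions.items()
        }
        return BooleanModel(self.components, self.inputs, funcs)

    def to_networkx(self):
        """Interaction graph as a :class:`networkx.DiGraph` with 'sign' edges."""
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.components)
        for reg, target, positive in sorted(self.edges):
            g.add_edge(reg, target, sign="+" if positive else "-")
        return g


def _parse_literal(token: str, line_no: int) -> RegulatorLiteral:
    token = token.strip()
    positive = True
    while token.startswith("!"):
        positive = not positive
        token = token[1:].strip()
    if not _IDENT.match(token):
        raise ModelParseError(f"bad literal {token!r}", line_no)
    if token in _RESERVED:
        raise ModelParseError(f"{token!r} is a reserved word", line_no)
    return RegulatorLiteral(token, positive)


def _parse_clause(text: str, line_no: int) -> frozenset:
    text = text.strip()
    if text.startswith("(") and text.endswith(")"):
        text = text[1:-1].strip()
    if "(" in text or ")" in text:
        raise ModelParseError(
            f"unexpected parenthesis inside clause {text!r} "
            "(only DNF clauses are supported)",
            line_no,
        )
    if not text:
        raise ModelParseError("empty clause", line_no)
    return frozenset(_parse_literal(t, line_no) for t in text.split("&"))


def parse_model(text: str) -> BooleanModel:
    """Parse a model file; functions are normalized on load.

    Raises :class:`ModelParseError` (with line number) on syntax errors,
    duplicate target definitions, an explicit input that also has a function,
    or functions outside the monotone non-degenerate fragment.
    """
    declared_inputs: set = set()
    functions: dict[str, DNFFunction] = {}
    def_lines: dict[str, int] = {}
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        head = line.split(None, 1)
        if head[0] == "input":
            if len(head) < 2:
                raise ModelParseError("'input' needs a component name", line_no)
            for name in head[1].replace(",", " ").split():
                if not _IDENT.match(name):
                    raise ModelParseError(f"bad component name {name!r}", line_no)
                declared_inputs.add(name)
            continue
        if "=" not in line:
            raise ModelParseError(f"expected 'target = function': {line!r}", line_no)
        lhs, rhs = line.split("=", 1)
        target = lhs.strip()
        if not _IDENT.match(target):
            raise ModelParseError(f"bad target name {target!r}", line_no)
        if target in _RESERVED:
            raise ModelParseError(f"{target!r} is a reserved word", line_no)
        if target in functions:
            raise ModelParseError(
                f"duplicate definition of {target!r} "
                f"(first defined on line {def_lines[target]})",
                line_no,
            )
        clauses = tuple(_parse_clause(c, line_no) for c in rhs.split("|"))
        dnf = DNFFunction(target, clauses)
        try:
            dnf = normalize(dnf)
        except ValueError as exc:
            raise ModelParseError(str(exc), line_no) from exc
        functions[target] = dnf
        def_lines[target] = line_no
    if not functions and not declared_inputs:
        raise ModelParseError("empty model: no functions or input declarations")
    overlap = declared_inputs & set(functions)
    if overlap:
        raise ModelParseError(
            f"component(s) declared 'input' but given a function: "
            f"{sorted(overlap)}"
        )
    regulators = {
        lit.regulator for dnf in functions.values() for c in dnf.clauses for lit in c
    }
    components = tuple(sorted(set(functions) | regulators | declared_inputs))
    inputs = frozenset(set(components) - set(functions))
    trees = {t: dnf_to_tree(dnf) for t, dnf in functions.items()}
    return BooleanModel(components, inputs, trees)


def write_model(m: BooleanModel) -> str:
    """Serialize deterministically in the model dialect.

    Clauses are written verbatim in their stored order — a repaired function
    is exported unminimized.  ``parse_model(write_model(m))`` equals ``m``
    after normalization.
    """
    lines = [f"input {name}" for name in sorted(m.inputs)]
    for target in sorted(m.functions):
        dnf = m.function_dnf(target)
        lines.append(f"{target} = {dnf}")
    return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class TimeSeries:
    """One experiment's observation matrix.

    ``observations`` maps ``(component, step)`` to 0/1 for the non-missing
    cells; ``steps`` is T (columns are ``0..T``).
    """

    experiment: str
    components: tuple[str, ...]
    steps: int
    observations: Mapping[tuple, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.steps < 0:
            raise ValueError("steps must be >= 0")
        if len(set(self.components)) != len(self.components):
            raise ValueError("duplicate component rows")
        if not self.observations:
            raise ValueError("time series needs at least one observed cell")
        comps = set(self.components)
        for (c, t), v in self.observations.items():
            if c not in comps:
                raise ValueError(f"observation for unknown row {c!r}")
            if not (0 <= t <= self.steps):
                raise ValueError(f"observation at step {t} outside 0..{self.steps}")
            if v not in (0, 1):
                raise ValueError(f"non-binary value {v!r} for ({c}, {t})")

    def get(self, component: str, step: int):
        """Observed value or ``None`` when the cell is missing."""
        return self.observations.get((component, step))

    def cells(self) -> tuple:
        """Sorted non-missing cell coordinates."""
        return tuple(sorted(self.observations))

    @property
    def n_cells(self) -> int:
        return len(self.components) * (self.steps + 1)

    def with_values(self, updates: Mapping[tuple, int]) -> "TimeSeries":
        obs = dict(self.observations)
        obs.update(updates)
        return TimeSeries(self.experiment, self.components, self.steps, obs)

    def without_cells(self, cells: Iterable[tuple]) -> "TimeSeries":
        drop = set(cells)
        obs = {k: v for k, v in self.observations.items() if k not in drop}
        return TimeSeries(self.experiment, self.components, self.steps, obs)

    def to_frame(self) -> pd.DataFrame:
        data = {
            t: [self.get(c, t) for c in self.components]
            for t in range(self.steps + 1)
        }
        return pd.DataFrame(data, index=list(self.components), dtype="object")


_MISSING_TOKENS = {"", "?", "na", "nan", "none"}


def parse_timeseries(text: str, experiment: str = "ts1") -> TimeSeries:
    """Parse a time-series matrix (tab- or comma-separated).

    The header row labels the time steps; when numeric it must be the
    contiguous range ``0..T``.  Blank cells and ``?`` are missing values;
    anything other than 0/1 is an error, as is a duplicated component row.
    """
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    try:
        df = pd.read_csv(
            io.StringIO(text),
            sep=sep,
            dtype=str,
            keep_default_na=False,
            index_col=0,
        )
    except Exception as exc:
        raise TimeSeriesParseError(f"cannot read matrix: {exc}") from exc
    if df.shape[1] == 0:
        raise TimeSeriesParseError("no time-step columns found")
    headers = [str(h).strip() for h in df.columns]
    if all(re.fullmatch(r"-?\d+", h) for h in headers):
        nums = [int(h) for h in headers]
        if nums != list(range(len(nums))):
            raise TimeSeriesParseError(
                f"time-step header must be contiguous 0..T, got {nums}"
            )
    components = [str(c).strip() for c in df.index]
    dupes = {c for c in components if components.count(c) > 1}
    if dupes:
        raise TimeSeriesParseError(f"duplicated component row(s): {sorted(dupes)}")
    observations: dict[tuple, int] = {}
    for row_idx, comp in enumerate(components):
        for t in range(df.shape[1]):
            token = str(df.iat[row_idx, t]).strip()
            if token.lower() in _MISSING_TOKENS:
                continue
            if token not in ("0", "1"):
                raise TimeSeriesParseError(
                    f"non-binary value {token!r} for component {comp!r} "
                    f"at step {t}"
                )
            observations[(comp, t)] = int(token)
    if not observations:
        raise TimeSeriesParseError("time series has no observed values")
    return TimeSeries(experiment, tuple(components), df.shape[1] - 1, observations)


def write_timeseries(ts: TimeSeries, sep: str = "\t") -> str:
    """Serialize a matrix; missing cells are written as ``?``."""
    header = ["component"] + [str(t) for t in range(ts.steps + 1)]
    lines = [sep.join(header)]
    for c in ts.components:
        row = [c]
        for t in range(ts.steps + 1):
            v = ts.get(c, t)
            row.append("?" if v is None else str(v))
        lines.append(sep.join(row))
    return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class ValidationReport:
    """Structural cross-checks between a model and its time-series data."""

    unknown_components: Mapping[str, frozenset]
    input_conflicts: Mapping[str, frozenset]
    messages: tuple[str, ...]

    @property
    def ok(self) -> bool:
        return not self.messages


def validate(m: BooleanModel, ts_list: Iterable[TimeSeries]) -> ValidationReport:
    """Report series rows absent from the model and non-constant inputs.

    Inputs hold constant values, so an input observed with two different
    values in one experiment can never be explained by any repair of the
    regulatory functions.
    """
    unknown: dict[str, frozenset] = {}
    conflicts: dict[str, frozenset] = {}
    messages: list[str] = []
    comps = set(m.components)
    for ts in ts_list:
        missing = frozenset(set(ts.components) - comps)
        if missing:
            unknown[ts.experiment] = missing
            messages.append(
                f"{ts.experiment}: component(s) not in the model: "
                f"{sorted(missing)}"
            )
        bad_inputs = set()
        for i in m.inputs:
            values = {
                v for (c, t), v in ts.observations.items() if c == i
            }
            if len(values) > 1:
                bad_inputs.add(i)
        if bad_inputs:
            conflicts[ts.experiment] = frozenset(bad_inputs)
            messages.append(
                f"{ts.experiment}: input(s) observed with conflicting values "
                f"(inputs are constant): {sorted(bad_inputs)}"
            )
    return ValidationReport(unknown, conflicts, tuple(messages))
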