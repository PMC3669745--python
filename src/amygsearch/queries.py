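"""Terminal-state predicates and reproduction of the published count tables.

Each search condition filters the enumerated terminal set with a conjunction
of pure predicates: whether a tracked inhibitory weight underwent LTD during
extinction (final magnitude strictly below its post-conditioning record),
whether two weights ended equal, and how circuit elements respond to the cue
at the final weights (excited = strictly positive CS response, inhibited =
strictly negative; a response of exactly zero is neither).
"""

from __future__ import annotations

import pandas as pd

from .models import Experiment, experiment, registry_rows
from .search import SearchState, TerminalSet, compile_experiment, enumerate_terminals

__all__ = [
    "FILTER_NAMES",
    "ltd_occurred",
    "evaluate_filter",
    "apply_filters",
    "reproduce_table",
]

FILTER_NAMES = (
    "ltd_of",
    "no_ltd_of",
    "finals_equal",
    "records_equal",
    "excited_by_cs",
    "not_inhibited_by_cs",
    "any_excited",
)


def _record_value(comp, state: SearchState, connection: str) -> int:
    try:
        idx = comp.record_names.index(connection)
    except ValueError:
        raise KeyError(f"{connection} is not record-tracked in this experiment") from None
    if state.records is None:
        raise ValueError("state has no records (conditioning not completed)")
    return state.records[idx]


def _final_magnitude(comp, state: SearchState, connection: str) -> int:
    return state.magnitudes[comp.circuit.connection_index[connection]]


def ltd_occurred(state: SearchState, connection: str, experiment) -> bool:
    """True iff the weight's final magnitude is strictly below its record."""
    comp = _as_comp(experiment)
    return _final_magnitude(comp, state, connection) < _record_value(comp, state, connection)


def _as_comp(experiment):
    if hasattr(experiment, "record_names"):
        return experiment
    return compile_experiment(experiment)


def _cs_response(comp, state: SearchState, element: str) -> int:
    ctx = comp.experiment.extinction_context
    return comp.circuit.cs_response(state.magnitudes, element, ctx)


def evaluate_filter(state: SearchState, spec: tuple, experiment) -> bool:
    """Evaluate one (name, *args) predicate on a terminal state."""
    comp = _as_comp(experiment)
    name, *args = spec
    if name == "ltd_of":
        return ltd_occurred(state, args[0], comp)
    if name == "no_ltd_of":
        return not ltd_occurred(state, args[0], comp)
    if name == "finals_equal":
        vals = {_final_magnitude(comp, state, a) for a in args}
        return len(vals) == 1
    if name == "records_equal":
        vals = {_record_value(comp, state, a) for a in args}
        return len(vals) == 1
    if name == "excited_by_cs":
        return _cs_response(comp, state, args[0]) > 0
    if name == "not_inhibited_by_cs":
        return _cs_response(comp, state, args[0]) >= 0
    if name == "any_excited":
        return any(_cs_response(comp, state, a) > 0 for a in args)
    raise KeyError(f"unknown filter {name!r}")


def apply_filters(terminal_set: TerminalSet, filters=None):
    """Count terminal states satisfying the conjunction of filters.

    Returns ``(count, surviving states)``.  ``filters=None`` uses the
    experiment's own registered filter chain; an empty sequence counts the
    whole terminal set.
    """
    exp = terminal_set.experiment
    if filters is None:
        filters = exp.filters
    comp = compile_experiment(exp)
    survivors = [
        s
        for s in terminal_set.states
        if all(evaluate_filter(s, f, comp) for f in filters)
    ]
    return len(survivors), survivors


def count_experiment(exp: Experiment) -> int:
    """Enumerate and filter one search condition; return its count."""
    terminals = enumerate_terminals(exp)
    count, _ = apply_filters(terminals)
    return count


def reproduce_table(model_id: int, **flags) -> pd.DataFrame:
    """Run all 13 search conditions of one model and compare with the
    published counts.  Columns: row, condition, expected, observed, pass."""
    rows = []
    for row_id, (text, expected) in registry_rows(model_id).items():
        exp = experiment(model_id, row_id, **flags)
        observed = count_experiment(exp)
        rows.append(
            {
                "model": model_id,
                "row": row_id,
                "condition": text,
                "expected": expected,
                "observed": observed,
                "pass": observed == expected,
            }
        )
    return pd.DataFrame(rows)
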