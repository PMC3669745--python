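"""Exhaustive enumeration of terminal (extinguished) weight configurations.

Learning is modeled as nondeterministic rewriting over integer weight
magnitudes.  From the initial configuration, unit LTP steps are applied one at
a time (in any order) during conditioning until the cue alone activates the
output gate; the tracked weights are then snapshotted ("records") and unit
extinction steps are applied until the cue no longer activates the gate, at
which point the state is terminal.  The enumerator performs a breadth-first
traversal of this state-transition tree with memoization on state identity
(phase, magnitudes, records) and returns the set of distinct terminal
configurations -- the quantity the count tables are built from.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

from .circuit import Circuit, Context
from .models import DECREASE, Experiment, INCREASE

__all__ = [
    "CONDITIONING",
    "EXTINGUISHING",
    "DONE",
    "SearchState",
    "Move",
    "TerminalSet",
    "compile_experiment",
    "applicable_moves",
    "step",
    "enumerate_terminals",
    "enumerate_terminals_naive",
]

CONDITIONING = "conditioning"
EXTINGUISHING = "extinguishing"
DONE = "done"

_LO, _HI = 0, 2


@dataclass(frozen=True)
class SearchState:
    """Identity of a point in the search: phase, magnitudes, records.

    ``magnitudes`` covers every connection of the circuit in declaration
    order (fixed weights simply never change).  ``records`` is None during
    conditioning and a tuple of post-conditioning magnitudes of the tracked
    weights afterwards.  Two paths reaching the same triple are the same
    configuration.
    """

    phase: str
    magnitudes: tuple[int, ...]
    records: tuple[int, ...] | None = None


@dataclass(frozen=True)
class Move:
    """A unit step: the connection slots it changes (one, or a whole tie
    group changing jointly) and the direction in magnitude space."""

    slots: tuple[int, ...]
    direction: int  # +1 magnitude increase (LTP), -1 decrease (LTD)
    label: str


class _CompiledExperiment:
    """Precomputed move units, record slots and test contexts."""

    def __init__(self, experiment: Experiment):
        self.experiment = experiment
        self.circuit: Circuit = experiment.circuit()
        circ = self.circuit
        sched = experiment.schedule

        group_of: dict[str, tuple[str, ...]] = {}
        for group in experiment.tie_groups:
            for name in group:
                group_of[name] = group

        def units(phase_moves) -> tuple[Move, ...]:
            out: list[Move] = []
            seen_groups: set[tuple[str, ...]] = set()
            for conn in circ.connections:
                moves = phase_moves.get(conn.name, frozenset())
                if not moves:
                    continue
                if conn.name in group_of:
                    g = group_of[conn.name]
                    if g in seen_groups:
                        continue
                    seen_groups.add(g)
                    slots = tuple(circ.connection_index[n] for n in g)
                    label = "=".join(g)
                else:
                    slots = (circ.connection_index[conn.name],)
                    label = conn.name
                for direction_name in sorted(moves):
                    direction = +1 if direction_name == INCREASE else -1
                    out.append(Move(slots, direction, label))
            return tuple(out)

        self.conditioning_moves = units(sched.conditioning)
        self.extinction_moves = units(sched.extinction)
        self.record_slots = tuple(
            circ.connection_index[n] for n in experiment.record_connections()
        )
        self.record_names = experiment.record_connections()
        cc, ec = experiment.conditioning_context, experiment.extinction_context
        self._cond_ctx = (cc.US, cc.CS, cc.IL)
        self._ext_ctx = (ec.US, ec.CS, ec.IL)
        self.initial_state = SearchState(CONDITIONING, circ.initial_magnitudes)

    def pag(self, magnitudes: tuple[int, ...], ctx: tuple[int, int, int]) -> bool:
        _, pag = self.circuit._evaluate(magnitudes, *ctx)
        return pag

    def pag_conditioning(self, magnitudes) -> bool:
        return self.pag(magnitudes, self._cond_ctx)

    def pag_extinction(self, magnitudes) -> bool:
        return self.pag(magnitudes, self._ext_ctx)


def compile_experiment(experiment: Experiment) -> _CompiledExperiment:
    return _CompiledExperiment(experiment)


def _as_compiled(experiment) -> _CompiledExperiment:
    if isinstance(experiment, _CompiledExperiment):
        return experiment
    return compile_experiment(experiment)


def applicable_moves(state: SearchState, experiment) -> list[Move]:
    """Moves offered in ``state``: phase-appropriate unit steps whose result
    stays within the magnitude bounds (jointly, for tied weights)."""
    comp = _as_compiled(experiment)
    if state.phase == DONE:
        return []
    pool = comp.conditioning_moves if state.phase == CONDITIONING else comp.extinction_moves
    mags = state.magnitudes
    out = []
    for move in pool:
        ok = True
        for slot in move.slots:
            nxt = mags[slot] + move.direction
            if nxt < _LO or nxt > _HI:
                ok = False
                break
        if ok:
            out.append(move)
    return out


def step(state: SearchState, move: Move, experiment) -> SearchState:
    """Apply one unit step, then run the phase-transition logic.

    Conditioning ends (records are snapshotted) the moment the cue alone
    activates the gate; extinction ends the moment it no longer does.
    """
    comp = _as_compiled(experiment)
    if move not in applicable_moves(state, comp):
        raise ValueError(f"move {move.label} not applicable in this state")
    mags = list(state.magnitudes)
    for slot in move.slots:
        mags[slot] += move.direction
    mags = tuple(mags)
    if state.phase == CONDITIONING:
        if comp.pag_conditioning(mags):
            records = tuple(mags[s] for s in comp.record_slots)
            return SearchState(EXTINGUISHING, mags, records)
        return SearchState(CONDITIONING, mags)
    # extinguishing
    if not comp.pag_extinction(mags):
        return SearchState(DONE, mags, state.records)
    return SearchState(EXTINGUISHING, mags, state.records)


@dataclass
class TerminalSet:
    """Distinct completed (extinguished) configurations plus diagnostics."""

    experiment: Experiment
    states: frozenset[SearchState]
    max_depth: int
    n_dead_ends: int
    n_states_explored: int
    naive: bool = False

    def __len__(self) -> int:
        return len(self.states)

    def __iter__(self) -> Iterator[SearchState]:
        return iter(self.states)

    def to_tsv(self) -> str:
        """One configuration per row: weight magnitudes then records."""
        comp = compile_experiment(self.experiment)
        circ = comp.circuit
        conn_names = [c.name for c in circ.connections]
        header = "\t".join(
            ["# experiment", f"model{self.experiment.model_id}", f"row{self.experiment.row_id}"]
        )
        cols = "\t".join(conn_names + [f"record:{n}" for n in comp.record_names])
        lines = [header, cols]
        for s in sorted(self.states, key=lambda s: (s.magnitudes, s.records)):
            recs = s.records or ()
            lines.append("\t".join(str(v) for v in list(s.magnitudes) + list(recs)))
        return "\n".join(lines) + "\n"


def enumerate_terminals(experiment) -> TerminalSet:
    """Memoized breadth-first enumeration of all distinct terminal states.

    Also reports the maximum traversal depth reached and the number of
    conditioning dead-ends (saturated configurations in which the cue never
    came to activate the gate); dead-ends are not terminal configurations.
    """
    comp = _as_compiled(experiment)
    init = comp.initial_state
    seen = {init}
    frontier = [init]
    terminals: set[SearchState] = set()
    depth = 0
    max_depth = 0
    dead_ends = 0
    while frontier:
        nxt: list[SearchState] = []
        for state in frontier:
            moves = applicable_moves(state, comp)
            if not moves and state.phase == CONDITIONING:
                dead_ends += 1
                continue
            for move in moves:
                child = step(state, move, comp)
                if child in seen:
                    continue
                seen.add(child)
                max_depth = depth + 1
                if child.phase == DONE:
                    terminals.add(child)
                else:
                    nxt.append(child)
        depth += 1
        frontier = nxt
    return TerminalSet(
        experiment=comp.experiment,
        states=frozenset(terminals),
        max_depth=max_depth,
        n_dead_ends=dead_ends,
        n_states_explored=len(seen),
    )


def enumerate_terminals_naive(
    experiment, depth_limit: int = 40, path_budget: int = 10_000_000
) -> TerminalSet:
    """Brute-force oracle: walk every rule-execution sequence, no memoization.

    Only tractable for small experiments; raises if the path budget is hit.
    """
    comp = _as_compiled(experiment)
    terminals: set[SearchState] = set()
    paths_taken = 0
    max_depth = 0
    dead_ends = 0

    def walk(state: SearchState, depth: int) -> None:
        nonlocal paths_taken, max_depth, dead_ends
        paths_taken += 1
        if paths_taken > path_budget:
            raise RuntimeError("naive enumeration exceeded its path budget")
        max_depth = max(max_depth, depth)
        if state.phase == DONE:
            terminals.add(state)
            return
        if depth >= depth_limit:
            return
        moves = applicable_moves(state, comp)
        if not moves and state.phase == CONDITIONING:
            dead_ends += 1
            return
        for move in moves:
            walk(step(state, move, comp), depth + 1)

    if depth_limit > 0:
        walk(comp.initial_state, 0)
    return TerminalSet(
        experiment=comp.experiment,
        states=frozenset(terminals),
        max_depth=max_depth,
        n_dead_ends=dead_ends,
        n_states_explored=paths_taken,
        naive=True,
    )
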