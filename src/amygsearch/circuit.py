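"""Linear rate-coded circuit representation and evaluation.

A circuit is a small feedforward network of neural elements (single neurons or
homogeneous neuron groups).  Each element carries a constant bias, each directed
connection a sign (+1 excitatory, -1 inhibitory) and an integer weight magnitude
in [0, 2] (signed weight = sign x magnitude).  The activity of a non-input
element is the sum of its weighted inputs plus its bias -- purely linear, no
time course.  A designated output gate (PAG) fires iff its summed input is
strictly positive; that binary event stands for the fear response.

With integer biases and magnitudes all activities are integers, so exhaustive
enumeration over weight configurations is exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx

__all__ = [
    "ElementSpec",
    "ConnectionSpec",
    "CircuitSpec",
    "Context",
    "ActivityMap",
    "Circuit",
    "validate_circuit",
    "connection_name",
    "CircuitError",
]

INPUT = "input"
INTERNAL = "internal"
OUTPUT_GATE = "output-gate"


class CircuitError(ValueError):
    """Raised for structurally invalid circuit specifications."""


def connection_name(source: str, target: str) -> str:
    """Canonical connection name, e.g. ``wCStoLA1``."""
    return f"w{source}to{target}"


@dataclass(frozen=True)
class ElementSpec:
    """A neural element: an external input, an internal unit, or the output gate."""

    name: str
    bias: int = 0
    kind: str = INTERNAL

    def __post_init__(self) -> None:
        if self.kind not in (INPUT, INTERNAL, OUTPUT_GATE):
            raise CircuitError(f"unknown element kind {self.kind!r}")
        if self.kind == INPUT and self.bias != 0:
            raise CircuitError(f"input element {self.name} must have bias 0")


@dataclass(frozen=True)
class ConnectionSpec:
    """A signed connection with an integer weight magnitude in [0, 2].

    ``modifiable`` marks weights open to plasticity; ``record_tracked`` marks
    weights whose magnitude is snapshotted at the end of conditioning (needed to
    decide later whether extinction depressed them).  ``tie_group`` names a
    group of connections constrained to share one magnitude and change jointly.
    """

    source: str
    target: str
    sign: int
    initial_magnitude: int = 1
    modifiable: bool = False
    record_tracked: bool = False
    tie_group: str | None = None

    def __post_init__(self) -> None:
        if self.sign not in (1, -1):
            raise CircuitError(f"{self.name}: sign must be +1 or -1")
        if not 0 <= self.initial_magnitude <= 2:
            raise CircuitError(f"{self.name}: initial magnitude outside [0, 2]")
        if self.record_tracked and not self.modifiable:
            raise CircuitError(f"{self.name}: record-tracked weights must be modifiable")

    @property
    def name(self) -> str:
        return connection_name(self.source, self.target)


@dataclass(frozen=True)
class Context:
    """Stimulus context: binary US (aversive input), CS (cue) and IL drive.

    IL models infralimbic prefrontal cortex, active only during extinction
    training; circuits without an IL element simply ignore it.
    """

    US: int = 0
    CS: int = 0
    IL: int = 0

    def __post_init__(self) -> None:
        for name in ("US", "CS", "IL"):
            if getattr(self, name) not in (0, 1):
                raise CircuitError(f"context value {name} must be 0 or 1")


@dataclass(frozen=True)
class CircuitSpec:
    """Declarative circuit description; compile with :func:`validate_circuit`."""

    elements: tuple[ElementSpec, ...]
    connections: tuple[ConnectionSpec, ...]

    def to_json(self) -> str:
        doc = {
            "elements": [
                {"name": e.name, "bias": e.bias, "kind": e.kind} for e in self.elements
            ],
            "connections": [
                {
                    "source": c.source,
                    "target": c.target,
                    "sign": c.sign,
                    "initial_magnitude": c.initial_magnitude,
                    "modifiable": c.modifiable,
                    "record_tracked": c.record_tracked,
                    "tie_group": c.tie_group,
                }
                for c in self.connections
            ],
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CircuitSpec":
        doc = json.loads(text)
        elements = tuple(ElementSpec(**e) for e in doc["elements"])
        connections = tuple(ConnectionSpec(**c) for c in doc["connections"])
        return cls(elements, connections)


class ActivityMap(Mapping[str, int]):
    """Element name -> activity, plus the binary output-gate flag."""

    def __init__(self, values: dict[str, int], pag_active: bool):
        self._values = values
        self.pag_active = pag_active

    def __getitem__(self, key: str) -> int:
        return self._values[key]

    def __iter__(self):
        return iter(self._values)

    def __len__(self) -> int:
        return len(self._values)

    def to_tsv_row(self, header: bool = False) -> str:
        names = list(self._values)
        if header:
            return "\t".join(names + ["pag_active"])
        cells = [str(self._values[n]) for n in names]
        return "\t".join(cells + [str(int(self.pag_active))])

    def __repr__(self) -> str:  # pragma: no cover
        return f"ActivityMap({self._values!r}, pag_active={self.pag_active})"


class Circuit:
    """A validated circuit with a fixed topological evaluation order.

    Evaluation is a single feedforward pass (both published models are acyclic;
    no iterative settling).  Activities are linear in the inputs; with
    ``rectify=True`` internal activities are floored at zero, treating them as
    firing rates.  The baseline configuration counts discriminate the two
    semantics and select the floored variant, which is therefore the default
    for the registered experiments (plain circuits stay linear unless asked).
    """

    def __init__(self, spec: CircuitSpec, *, rectify: bool = False):
        self.spec = spec
        self.rectify = rectify
        self._compile()

    # -- construction ------------------------------------------------------

    def _compile(self) -> None:
        spec = self.spec
        names = [e.name for e in spec.elements]
        if len(set(names)) != len(names):
            raise CircuitError("duplicate element names")
        self.element_index = {n: i for i, n in enumerate(names)}
        self.elements = {e.name: e for e in spec.elements}

        conn_names = [c.name for c in spec.connections]
        if len(set(conn_names)) != len(conn_names):
            raise CircuitError("duplicate connections")
        self.connections = tuple(spec.connections)
        self.connection_index = {c.name: i for i, c in enumerate(self.connections)}

        graph = nx.DiGraph()
        graph.add_nodes_from(names)
        for c in self.connections:
            for end in (c.source, c.target):
                if end not in self.elements:
                    raise CircuitError(f"connection {c.name} references unknown element {end}")
            if self.elements[c.target].kind == INPUT:
                raise CircuitError(f"input element {c.target} cannot receive connections")
            graph.add_edge(c.source, c.target)
        try:
            order = list(nx.topological_sort(graph))
        except nx.NetworkXUnfeasible as exc:
            raise CircuitError("connection graph contains a cycle") from exc
        # networkx topological order can vary between versions; make it
        # reproducible by sorting ties on declaration order via generations.
        gen_of = {}
        for gen, layer in enumerate(nx.topological_generations(graph)):
            for n in layer:
                gen_of[n] = gen
        order = sorted(names, key=lambda n: (gen_of[n], self.element_index[n]))

        groups: dict[str, list[ConnectionSpec]] = {}
        for c in self.connections:
            if c.tie_group is not None:
                groups.setdefault(c.tie_group, []).append(c)
        for label, members in groups.items():
            mags = {m.initial_magnitude for m in members}
            if len(mags) != 1:
                raise CircuitError(f"tie group {label!r} has unequal initial magnitudes")
            if not all(m.modifiable for m in members):
                raise CircuitError(f"tie group {label!r} contains a non-modifiable weight")
        self.tie_groups = {k: tuple(m.name for m in v) for k, v in groups.items()}

        gates = [e for e in spec.elements if e.kind == OUTPUT_GATE]
        if len(gates) != 1:
            raise CircuitError("exactly one output-gate element required")
        self.output_gate = gates[0].name

        # Flat evaluation plan: for each non-input element in topological
        # order, its bias and incoming (source slot, connection slot, sign).
        incoming: dict[str, list[tuple[int, int, int]]] = {n: [] for n in names}
        for ci, c in enumerate(self.connections):
            incoming[c.target].append((self.element_index[c.source], ci, c.sign))
        self._plan = []
        for n in order:
            e = self.elements[n]
            if e.kind == INPUT:
                continue
            self._plan.append(
                (self.element_index[n], e.bias, tuple(incoming[n]), e.kind == OUTPUT_GATE)
            )
        self._order = order
        self._input_slots = {
            e.name: self.element_index[e.name] for e in spec.elements if e.kind == INPUT
        }
        self.initial_magnitudes = tuple(c.initial_magnitude for c in self.connections)
        self.n_elements = len(names)

    # -- evaluation --------------------------------------------------------

    def _context_values(self, context: Context) -> dict[str, int]:
        return {"US": context.US, "CS": context.CS, "IL": context.IL}

    def _as_tuple(self, magnitudes) -> tuple[int, ...]:
        if isinstance(magnitudes, tuple) and len(magnitudes) == len(self.connections):
            mags = magnitudes
        else:
            mags = list(self.initial_magnitudes)
            for name, value in magnitudes.items():
                mags[self.connection_index[name]] = value
            mags = tuple(mags)
        for m in mags:
            if not 0 <= m <= 2:
                raise CircuitError("magnitude outside [0, 2]")
        return mags

    def _evaluate(self, mags: Sequence[int], us: int, cs: int, il: int):
        """Core feedforward pass; returns (activity list, pag_active)."""
        act = [0] * self.n_elements
        ctx = {"US": us, "CS": cs, "IL": il}
        for name, slot in self._input_slots.items():
            act[slot] = ctx.get(name, 0)
        pag = False
        for slot, bias, inputs, is_gate in self._plan:
            a = bias
            for src, ci, sign in inputs:
                a += sign * mags[ci] * act[src]
            if is_gate:
                pag = a > 0
                a = 1 if pag else 0
            elif self.rectify and a < 0:
                a = 0
            act[slot] = a
        return act, pag

    def activities(self, magnitudes, context: Context) -> ActivityMap:
        """Evaluate every element activity under the given weights and context."""
        mags = self._as_tuple(magnitudes)
        act, pag = self._evaluate(mags, context.US, context.CS, context.IL)
        values = {n: act[self.element_index[n]] for n in self._order}
        return ActivityMap(values, pag)

    def pag_active(self, magnitudes, context: Context) -> bool:
        """True iff the output gate's summed input is strictly positive."""
        mags = self._as_tuple(magnitudes)
        _, pag = self._evaluate(mags, context.US, context.CS, context.IL)
        return pag

    def cs_response(self, magnitudes, element: str, context_base: Context = Context()) -> int:
        """Activity difference of ``element`` between CS=1 and CS=0.

        US and IL are held at ``context_base`` values; by linearity the result
        does not depend on them unless rectification is enabled.
        """
        if element not in self.elements:
            raise CircuitError(f"unknown element {element}")
        if self.elements[element].kind == INPUT:
            raise CircuitError("cs_response is defined for non-input elements")
        mags = self._as_tuple(magnitudes)
        on, _ = self._evaluate(mags, context_base.US, 1, context_base.IL)
        off, _ = self._evaluate(mags, context_base.US, 0, context_base.IL)
        slot = self.element_index[element]
        return on[slot] - off[slot]

    # -- conveniences ------------------------------------------------------

    @property
    def modifiable(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.connections if c.modifiable)

    @property
    def record_tracked(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.connections if c.record_tracked)

    def connection(self, name: str) -> ConnectionSpec:
        return self.connections[self.connection_index[name]]


def validate_circuit(spec: CircuitSpec, *, rectify: bool = False) -> Circuit:
    """Check a declarative spec and return the compiled, evaluable circuit."""
    if not spec.elements:
        raise CircuitError("empty circuit")
    return Circuit(spec, rectify=rectify)
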